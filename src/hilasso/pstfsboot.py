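"""PSTFSboot: parametric statistical test for feature selection in bootstrap regression.

Each predictor j was a candidate in ``k_j`` of the procedure-2 bootstrap
draws and received a nonzero coefficient in ``d_j`` of them.  Under the
null that j is noise, a nonzero estimate is as likely for j as for the
average candidate, so ``d_j ~ Binomial(k_j, pi0)`` with the pooled null
rate ``pi0 = sum(d) / sum(k)``.  The per-predictor p-value is the exact
upper tail ``P(X >= d_j)``; predictors with ``p < alpha`` are selected.
No multiple-testing correction is applied — the p-values are exposed so
any correction can be layered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SelectionTestResult:
    """Per-predictor sampling/nonzero counts, p-values and the selected set.

    ``never_tested`` flags predictors with ``k == 0`` (never a candidate in
    procedure 2); these get p-value 1 and are never selected.
    """

    k: np.ndarray
    d: np.ndarray
    pi0: float
    pvalue: np.ndarray
    selected: np.ndarray
    alpha: float

    @property
    def never_tested(self) -> np.ndarray:
        return self.k == 0


def count_selection_events(coef2, zero_tol: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Count, per predictor, candidacies (k) and nonzero estimates (d).

    ``k_j`` is the number of non-missing entries in row j of the
    procedure-2 coefficient matrix; ``d_j`` those with ``|value| > zero_tol``.
    """
    if zero_tol < 0:
        raise ValueError("zero_tol must be >= 0")
    present = ~coef2.missing_mask
    k = present.sum(axis=1).astype(np.int64)
    with np.errstate(invalid="ignore"):
        nonzero = present & (np.abs(coef2.values) > zero_tol)
    d = nonzero.sum(axis=1).astype(np.int64)
    return k, d


def estimate_null_rate(k: np.ndarray, d: np.ndarray) -> float:
    """Pooled fraction of candidacies that yielded a nonzero estimate."""
    k = np.asarray(k)
    d = np.asarray(d)
    if np.any(d > k) or np.any(k < 0) or np.any(d < 0):
        raise ValueError("counts must satisfy 0 <= d <= k")
    total = k.sum()
    if total == 0:
        raise ValueError("no sampling occurrences: cannot estimate the null rate")
    return float(d.sum() / total)


def binomial_pvalues(k: np.ndarray, d: np.ndarray, pi0: float) -> np.ndarray:
    """Exact binomial upper-tail p-values P(X >= d_j), X ~ Binomial(k_j, pi0).

    ``k_j = 0`` yields p-value 1 (the predictor was never tested).
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    k = np.asarray(k, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(d > k):
        raise ValueError("counts must satisfy d <= k elementwise")
    # sf(d - 1) = P(X > d - 1) = P(X >= d); d = 0 gives exactly 1
    pvals = stats.binom.sf(d - 1, k, pi0)
    return np.where(k == 0, 1.0, pvals)


def select_features(pvalue: np.ndarray, alpha: float) -> np.ndarray:
    """Strict threshold: selected iff p-value < alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return np.asarray(pvalue) < alpha


def run_selection_test(coef2, alpha: float = 0.05, zero_tol: float = 0.0) -> SelectionTestResult:
    """Full PSTFSboot pipeline on a procedure-2 coefficient matrix."""
    k, d = count_selection_events(coef2, zero_tol=zero_tol)
    pi0 = estimate_null_rate(k, d)
    pvalue = binomial_pvalues(k, d, pi0)
    selected = select_features(pvalue, alpha)
    return SelectionTestResult(k=k, d=d, pi0=pi0, pvalue=pvalue, selected=selected, alpha=alpha)
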