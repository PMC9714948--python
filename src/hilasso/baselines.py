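"""Random LASSO baseline.

The original two-procedure bootstrap selector that Hi-LASSO refines.
Kept here so its two weaknesses are directly measurable against the same
bootstrap machinery: (1) averaging coefficients over all B draws with
unselected predictors counted as zeros, which shrinks every estimate by
the factor (times sampled / B); and (2) selection by the heuristic
threshold |beta| >= 1/n instead of a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CoefMatrix, compute_num_bootstraps, run_procedure
from .dataset import Dataset
from .solvers import SolverConfig

#: relative floor for the stage-2 sampling weights, as in the Hi-LASSO core
_FLOOR_EPS = 1e-10


@dataclass
class RandomLassoFit:
    beta_hat: np.ndarray  # sum over B divided by B; zeros for unselected draws
    importance_rl: np.ndarray  # |sum of signed estimates| / B
    selected: np.ndarray
    threshold: float
    B1: int
    B2: int
    q1: int
    q2: int
    coef1: CoefMatrix = None
    coef2: CoefMatrix = None


def aggregate_beta_random(coef: CoefMatrix) -> np.ndarray:
    """Random-LASSO aggregation: signed sum over draws divided by B, zeros included."""
    return np.nansum(coef.values, axis=1) / coef.B


def importance_random(coef: CoefMatrix) -> np.ndarray:
    """Random-LASSO importance: absolute value of the signed sum, over B.

    Opposite-signed estimates across draws cancel here — the effect the
    absolute-mean importance of the Hi-LASSO core avoids.
    """
    return np.abs(np.nansum(coef.values, axis=1)) / coef.B


def fit_random_lasso(
    data: Dataset,
    q1: int | None = None,
    q2: int | None = None,
    L: int = 30,
    cfg: SolverConfig | None = None,
    seed=None,
    n_jobs: int = 1,
    threshold: float | None = None,
) -> RandomLassoFit:
    """Two-procedure Random LASSO with q and B chosen as Hi-LASSO does.

    Procedure 1: uniform bootstraps, Elastic-Net fits, signed-sum
    importance.  Procedure 2: importance-weighted predictor sampling,
    plain (unweighted) LASSO fits.  Final coefficients are the sums over
    all B2 draws divided by B2, and selection applies the reciprocal-of-
    sample-size threshold (``threshold`` overrides ``1/n``).
    """
    if cfg is None:
        cfg = SolverConfig()
    q1 = min(data.n, data.p) if q1 is None else q1
    q2 = min(data.n, data.p) if q2 is None else q2
    B1 = compute_num_bootstraps(L, data.p, q1)
    coef1 = run_procedure(
        data, q1, B1, solver="elastic_net", cfg=cfg, master_seed=seed, stage=1, n_jobs=n_jobs
    )
    imp = importance_random(coef1)
    floor = _FLOOR_EPS * (imp.max() if imp.max() > 0 else 1.0)
    weights = np.where(imp > 0, imp, floor)
    probs = weights / weights.sum()
    B2 = compute_num_bootstraps(L, data.p, q2)
    coef2 = run_procedure(
        data, q2, B2, solver="lasso", probs=probs, cfg=cfg, master_seed=seed, stage=2, n_jobs=n_jobs
    )
    beta_hat = aggregate_beta_random(coef2)
    thr = 1.0 / data.n if threshold is None else threshold
    selected = np.abs(beta_hat) >= thr
    return RandomLassoFit(
        beta_hat=beta_hat,
        importance_rl=imp,
        selected=selected,
        threshold=thr,
        B1=B1,
        B2=B2,
        q1=q1,
        q2=q2,
        coef1=coef1,
        coef2=coef2,
    )
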