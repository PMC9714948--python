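"""Independent oracles used by the test suite.

Each function here is written from the defining formula, deliberately
avoiding the code paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


def cd_weighted_lasso(X, y, lam, weights, n_iter=20000, tol=1e-12):
    """Brute-force coordinate descent for the weighted LASSO.

    Minimizes (1/(2n)) ||y - X b||^2 + lam * sum_j weights_j |b_j| by
    cyclic soft-thresholding updates until the largest coefficient change
    falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    weights = np.asarray(weights, dtype=float)
    b = np.zeros(q)
    col_sq = (X**2).sum(axis=0) / n
    resid = y.copy()
    for _ in range(n_iter):
        max_delta = 0.0
        for j in range(q):
            rho = X[:, j] @ resid / n + col_sq[j] * b[j]
            thr = lam * weights[j]
            new = np.sign(rho) * max(abs(rho) - thr, 0.0) / col_sq[j]
            if new != b[j]:
                resid -= X[:, j] * (new - b[j])
                max_delta = max(max_delta, abs(new - b[j]))
                b[j] = new
        if max_delta < tol:
            break
    return b


def binom_upper_tail(k: int, d: int, pi0: float) -> float:
    """Exact P(X >= d) for X ~ Binomial(k, pi0) by direct term summation."""
    if k == 0:
        return 1.0
    return float(
        sum(math.comb(k, i) * pi0**i * (1.0 - pi0) ** (k - i) for i in range(d, k + 1))
    )


def masked_abs_mean(values: np.ndarray) -> np.ndarray:
    """Per-row mean of |value| over non-NaN entries, 0 for all-NaN rows (loop form)."""
    out = np.zeros(values.shape[0])
    for j in range(values.shape[0]):
        row = [abs(v) for v in values[j] if not np.isnan(v)]
        out[j] = sum(row) / len(row) if row else 0.0
    return out


def masked_counts(values: np.ndarray, zero_tol: float = 0.0):
    """Loop-form (k, d): candidacies and |value| > zero_tol events per row."""
    p, B = values.shape
    k = np.zeros(p, dtype=int)
    d = np.zeros(p, dtype=int)
    for j in range(p):
        for b in range(B):
            if not np.isnan(values[j, b]):
                k[j] += 1
                if abs(values[j, b]) > zero_tol:
                    d[j] += 1
    return k, d


def orthonormal_design(n: int, q: int, seed: int = 0) -> np.ndarray:
    """Columns with mean 0, population sd 1 and (1/n) X'X = I.

    Built from a QR factorization that includes the constant column, so
    the retained columns are orthogonal to it (hence zero mean).
    """
    assert q < n - 1
    rng = np.random.default_rng(seed)
    M = np.column_stack([np.ones(n), rng.standard_normal((n, q))])
    Q, _ = np.linalg.qr(M)
    return Q[:, 1 : q + 1] * np.sqrt(n)
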