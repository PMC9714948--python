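"""Penalized subproblem fits used inside every bootstrap draw.

Three pieces: column standardization with back-transformation, an
Elastic-Net fit with per-draw penalty selection by cross-validation, and
the Adaptive LASSO realized by importance-score column rescaling (per-
predictor penalty weight ``1 / importance_j``).  All coefficient vectors
are returned on the original predictor scale; "zero" means the solver's
active set excluded the predictor at the selected penalty.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (
    ElasticNet,
    ElasticNetCV,
    Lasso,
    LassoCV,
    LogisticRegression,
    LogisticRegressionCV,
)
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

REGRESSION = "regression"
LOGISTIC = "logistic"


@dataclass
class SolverConfig:
    """Configuration of the per-bootstrap penalized fits.

    mixing : Elastic-Net L1 fraction in (0, 1]; 1.0 is a plain LASSO.
    lambda_grid_size : number of penalties on the geometric CV grid.
    cv_folds : folds for per-draw penalty selection.
    max_iter, tol : coordinate-descent / saga stopping rule.
    mode : "regression" or "logistic".
    """

    mixing: float = 0.5
    lambda_grid_size: int = 30
    cv_folds: int = 5
    max_iter: int = 2000
    tol: float = 1e-4
    mode: str = REGRESSION

    def __post_init__(self) -> None:
        if not 0.0 < self.mixing <= 1.0:
            raise ValueError(f"mixing must be in (0, 1], got {self.mixing}")
        if self.lambda_grid_size < 1:
            raise ValueError("lambda_grid_size must be a positive integer")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.mode not in (REGRESSION, LOGISTIC):
            raise ValueError(f"mode must be '{REGRESSION}' or '{LOGISTIC}'")


@dataclass
class StandardizedData:
    """Column-standardized design with everything needed to undo it.

    ``X_std`` has columns of mean 0 and (population) sd 1; in regression
    mode ``y_ctr`` is mean-centered, in logistic mode it is untouched.
    """

    X_std: np.ndarray
    y_ctr: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    y_mean: float
    mode: str = REGRESSION

    @property
    def n(self) -> int:
        return self.X_std.shape[0]

    @property
    def q(self) -> int:
        return self.X_std.shape[1]


def standardize(X, y, mode: str = REGRESSION, predictor_ids=None) -> StandardizedData:
    """Standardize columns of ``X`` to mean 0 / sd 1 and center ``y``.

    Raises
    ------
    ValueError
        If ``X`` or ``y`` has non-finite entries, or a column has zero
        variance (the offending predictor is named in the message).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least two samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in X or y")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population sd; the convention used throughout
    zero = np.flatnonzero(sds == 0.0)
    if zero.size:
        if predictor_ids is not None:
            names = ", ".join(str(predictor_ids[j]) for j in zero[:5])
        else:
            names = ", ".join(f"column {j}" for j in zero[:5])
        raise ValueError(f"zero-variance predictor(s): {names}")
    X_std = (X - means) / sds
    if mode == REGRESSION:
        y_mean = float(y.mean())
        y_ctr = y - y_mean
    else:
        y_mean = 0.0
        y_ctr = y
    return StandardizedData(X_std, y_ctr, means, sds, y_mean, mode)


def destandardize_coefficients(coef_std: np.ndarray, data: StandardizedData) -> np.ndarray:
    """Map coefficients from the standardized scale back to the original one."""
    return np.asarray(coef_std, dtype=float) / data.col_sds


def _check_cv_feasible(data: StandardizedData, cfg: SolverConfig) -> None:
    n_distinct = np.unique(data.X_std, axis=0).shape[0]
    if n_distinct < cfg.cv_folds:
        raise ValueError(
            f"only {n_distinct} distinct samples but cv_folds={cfg.cv_folds}"
        )


def _warn_convergence(caught, context: str) -> None:
    n_bad = sum(issubclass(w.category, ConvergenceWarning) for w in caught)
    if n_bad:
        logger.warning("%s: %d non-converged fit(s); best iterate kept", context, n_bad)


def fit_elastic_net(
    data: StandardizedData,
    cfg: SolverConfig,
    rng_seed: int,
    penalty: float | None = None,
) -> np.ndarray:
    """Elastic-Net fit with CV-selected penalty; coefficients on the original scale.

    ``penalty`` fixes the regularization strength and skips cross-validation
    (used when the caller controls the path, e.g. in tests).
    """
    if cfg.mode == LOGISTIC:
        return _fit_logistic(data, cfg, rng_seed, weights=None, penalty=penalty)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if penalty is not None:
            model = ElasticNet(
                alpha=penalty,
                l1_ratio=cfg.mixing,
                fit_intercept=False,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
        else:
            _check_cv_feasible(data, cfg)
            folds = KFold(cfg.cv_folds, shuffle=True, random_state=int(rng_seed))
            model = ElasticNetCV(
                l1_ratio=cfg.mixing,
                alphas=cfg.lambda_grid_size,
                cv=folds,
                fit_intercept=False,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
        model.fit(data.X_std, data.y_ctr)
    _warn_convergence(caught, "elastic net")
    return destandardize_coefficients(model.coef_, data)


def fit_adaptive_lasso(
    data: StandardizedData,
    importance: np.ndarray,
    cfg: SolverConfig,
    rng_seed: int,
    penalty: float | None = None,
) -> np.ndarray:
    """Adaptive LASSO via column rescaling; coefficients on the original scale.

    Solves the L1 problem with per-predictor penalty weight
    ``1 / importance_j`` by scaling column j by ``importance_j``, fitting a
    plain LASSO (penalty by CV as in :func:`fit_elastic_net`), and scaling
    coefficient j back up.  All importance entries must be strictly
    positive — flooring is the caller's job.
    """
    importance = np.asarray(importance, dtype=float)
    if importance.shape != (data.q,):
        raise ValueError("importance length does not match number of predictors")
    if np.any(importance <= 0) or not np.all(np.isfinite(importance)):
        bad = np.flatnonzero(~(importance > 0))
        raise ValueError(f"nonpositive importance at predictor index {bad[0]}")
    w = importance / importance.max()  # scale-free: CV reselects the penalty
    X_w = data.X_std * w
    if cfg.mode == LOGISTIC:
        scaled = dataclasses.replace(data, X_std=X_w)
        coef_std = _fit_logistic(
            scaled, dataclasses.replace(cfg, mixing=1.0), rng_seed, penalty=penalty
        ) * scaled.col_sds  # back to the scaled-standardized scale
        return destandardize_coefficients(coef_std * w, data)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if penalty is not None:
            model = Lasso(
                alpha=penalty, fit_intercept=False, max_iter=cfg.max_iter, tol=cfg.tol
            )
        else:
            _check_cv_feasible(data, cfg)
            folds = KFold(cfg.cv_folds, shuffle=True, random_state=int(rng_seed))
            model = LassoCV(
                alphas=cfg.lambda_grid_size,
                cv=folds,
                fit_intercept=False,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
        model.fit(X_w, data.y_ctr)
    _warn_convergence(caught, "adaptive lasso")
    return destandardize_coefficients(model.coef_ * w, data)


def _fit_logistic(
    data: StandardizedData,
    cfg: SolverConfig,
    rng_seed: int,
    weights: np.ndarray | None = None,
    penalty: float | None = None,
) -> np.ndarray:
    """L1/elastic-net logistic fit; deviance-minimizing C by stratified CV."""
    y = data.y_ctr
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("logistic mode requires a binary response")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if penalty is not None:
            model = LogisticRegression(
                penalty="elasticnet",
                l1_ratio=cfg.mixing,
                C=1.0 / (penalty * data.n),
                solver="saga",
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
        else:
            folds = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=int(rng_seed))
            model = LogisticRegressionCV(
                Cs=cfg.lambda_grid_size,
                penalty="elasticnet",
                l1_ratios=[cfg.mixing],
                solver="saga",
                scoring="neg_log_loss",
                cv=folds,
                max_iter=cfg.max_iter,
                tol=cfg.tol,
            )
        model.fit(data.X_std, y)
    _warn_convergence(caught, "logistic")
    return destandardize_coefficients(model.coef_.ravel(), data)
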