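"""The Hi-LASSO estimator.

Hi-LASSO runs two bootstrap procedures over random subsets of ``q``
predictors.  Procedure 1 samples predictors uniformly and turns the
per-draw Elastic-Net coefficients into importance scores (mean absolute
coefficient over the draws in which the predictor was actually a
candidate).  Procedure 2 resamples predictors with probability
proportional to importance and fits an Adaptive LASSO whose penalty
weights are those same *global* importance scores.  Coefficients of
predictors that were not candidates in a draw are recorded as missing —
never as zeros — so averages run over actual occurrences only, removing
the systematic shrinkage that plain over-all-draws averaging introduces.
The final selected set comes from the PSTFSboot binomial test on the
procedure-2 nonzero counts.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .dataset import Dataset
from .pstfsboot import SelectionTestResult, run_selection_test
from .solvers import (
    LOGISTIC,
    REGRESSION,
    SolverConfig,
    fit_adaptive_lasso,
    fit_elastic_net,
    standardize,
)

logger = logging.getLogger(__name__)

#: relative floor applied to zero importance scores so every predictor
#: stays reachable in procedure 2
DEFAULT_FLOOR_EPS = 1e-10


@dataclass
class HiLassoConfig:
    """Hyper-parameters of the Hi-LASSO estimator.

    q1, q2 : number of predictors drawn per bootstrap in procedures 1 and
        2; ``None`` means "use the sample size n", the recommended default.
    L : desired average number of times each predictor is sampled; the
        bootstrap count is ``B = ceil(L * p / q)``.
    alpha : significance threshold of the PSTFSboot selection test.
    logistic : fit logistic instead of linear models.
    random_state : master seed; fixes every bootstrap draw and CV split.
    n_jobs : parallel workers for the bootstrap fits (results are
        independent of this value).
    """

    q1: int | None = None
    q2: int | None = None
    L: int = 30
    alpha: float = 0.05
    logistic: bool = False
    random_state: int | None = None
    n_jobs: int = 1
    zero_tol: float = 0.0
    floor_eps: float = DEFAULT_FLOOR_EPS
    solver: SolverConfig | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_jobs < 1:
            raise ValueError("n_jobs must be a positive integer")
        if self.zero_tol < 0:
            raise ValueError("zero_tol must be >= 0")
        if self.floor_eps <= 0:
            raise ValueError("floor_eps must be positive")

    def resolve(self, n: int, p: int) -> "HiLassoConfig":
        """Fill data-dependent defaults and validate against (n, p)."""
        q1 = min(n, p) if self.q1 is None else self.q1
        q2 = min(n, p) if self.q2 is None else self.q2
        for name, q in (("q1", q1), ("q2", q2)):
            if not 1 <= q <= p:
                raise ValueError(f"{name} must be in [1, p={p}], got {q}")
        solver = self.solver
        if solver is None:
            solver = SolverConfig(mode=LOGISTIC if self.logistic else REGRESSION)
        elif self.logistic != (solver.mode == LOGISTIC):
            raise ValueError("logistic flag and solver.mode disagree")
        return dataclasses.replace(self, q1=q1, q2=q2, solver=solver)


@dataclass
class BootstrapDraw:
    """One bootstrap draw: n row indices (with replacement) and q distinct columns."""

    row_idx: np.ndarray
    col_idx: np.ndarray
    seed: int


@dataclass
class CoefMatrix:
    """p x B per-bootstrap coefficients; NaN marks "not a candidate in this draw"."""

    values: np.ndarray  # p x B, NaN = predictor not sampled in that draw
    draws: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def B(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def validate(self) -> None:
        if len(self.draws) != self.B:
            raise ValueError("draw count does not match number of columns")
        for b, draw in enumerate(self.draws):
            sampled = np.zeros(self.p, dtype=bool)
            sampled[draw.col_idx] = True
            if np.any(np.isnan(self.values[sampled, b])):
                raise ValueError(f"missing value for a sampled predictor in draw {b}")
            if np.any(~np.isnan(self.values[~sampled, b])):
                raise ValueError(f"non-missing value for an unsampled predictor in draw {b}")


@dataclass
class ImportanceVector:
    """Nonnegative per-predictor scores and the procedure-2 sampling distribution."""

    scores: np.ndarray  # floored, strictly positive
    probs: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.scores <= 0):
            raise ValueError("importance scores must be strictly positive after flooring")
        if abs(self.probs.sum() - 1.0) > 1e-12 or np.any(self.probs <= 0):
            raise ValueError("probs must be strictly positive and sum to 1")


@dataclass
class HiLassoFit:
    """Everything the estimator produced, sufficient to reproduce the run."""

    beta_hat: np.ndarray  # NaN where the predictor was never sampled in procedure 2
    importance: ImportanceVector
    coef1: CoefMatrix
    coef2: CoefMatrix
    test: SelectionTestResult
    config: HiLassoConfig
    B1: int
    B2: int
    predictor_ids: np.ndarray = None

    @property
    def selected(self) -> np.ndarray:
        return self.test.selected

    @property
    def never_sampled(self) -> np.ndarray:
        return np.isnan(self.beta_hat)


def compute_num_bootstraps(L: int, p: int, q: int) -> int:
    """Smallest B with expected uniform q-of-p selection count >= L: ceil(L*p/q)."""
    if not 1 <= q <= p:
        raise ValueError(f"q must satisfy 1 <= q <= p, got q={q}, p={p}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return math.ceil(L * p / q)


def draw_bootstrap(n: int, p: int, q: int, probs=None, seed=None) -> BootstrapDraw:
    """Draw n rows with replacement and q distinct columns, weighted by ``probs``.

    Column sampling is probability-proportional-to-size without
    replacement via exponential keys (Efraimidis–Spirakis): the q columns
    with the smallest ``Exp(1) / probs_j`` keys are taken, so inclusion
    probability is increasing in ``probs`` and the draw is a pure
    function of ``seed``.
    """
    if not 1 <= q <= p:
        raise ValueError(f"q must satisfy 1 <= q <= p, got q={q}, p={p}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, n, size=n)
    if probs is None:
        probs = np.full(p, 1.0 / p)
    else:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (p,):
            raise ValueError("probs length must equal p")
        if np.count_nonzero(probs > 0) < q:
            raise ValueError(
                f"cannot draw {q} predictors: only "
                f"{np.count_nonzero(probs > 0)} have positive probability"
            )
    if q == p:
        cols = np.arange(p)
    else:
        keys = rng.exponential(size=p) / probs
        cols = np.sort(np.argpartition(keys, q)[:q])
    seed_int = -1 if seed is None else int(np.asarray(seed).ravel()[0]) if np.ndim(seed) else int(seed)
    return BootstrapDraw(row_idx=rows, col_idx=cols, seed=seed_int)


def _per_draw_seeds(master_seed, B: int, stage: int) -> list[tuple[int, int]]:
    """Independent (sampling, cv) seed pairs per draw index, stable across n_jobs."""
    entropy = np.random.SeedSequence(master_seed).entropy
    pairs = []
    for b in range(B):
        child = np.random.SeedSequence(entropy=entropy, spawn_key=(stage, b))
        s_draw, s_cv = child.generate_state(2)
        pairs.append((int(s_draw), int(s_cv) % (2**31)))
    return pairs


def _fit_one_draw(X, y, q, probs, solver, importance, cfg, seed_pair, b, resample_rows):
    s_draw, s_cv = seed_pair
    n, p = X.shape
    draw = draw_bootstrap(n, p, q, probs=probs, seed=s_draw)
    if not resample_rows:
        draw = dataclasses.replace(draw, row_idx=np.arange(n))
    try:
        Xb = X[np.ix_(draw.row_idx, draw.col_idx)]
        yb = y[draw.row_idx]
        sdata = standardize(Xb, yb, mode=cfg.mode, predictor_ids=draw.col_idx)
        if solver == "adaptive":
            coefs = fit_adaptive_lasso(sdata, importance[draw.col_idx], cfg, s_cv)
        elif solver == "lasso":
            coefs = fit_elastic_net(sdata, dataclasses.replace(cfg, mixing=1.0), s_cv)
        else:
            coefs = fit_elastic_net(sdata, cfg, s_cv)
    except Exception as exc:  # attach the draw index for diagnosis
        raise RuntimeError(f"solver failure in bootstrap draw {b}: {exc}") from exc
    return b, draw, coefs


def run_procedure(
    data: Dataset,
    q: int,
    B: int,
    *,
    solver: str = "elastic_net",
    probs: np.ndarray | None = None,
    importance: np.ndarray | None = None,
    cfg: SolverConfig | None = None,
    master_seed=None,
    stage: int = 1,
    n_jobs: int = 1,
    resample_rows: bool = True,
) -> CoefMatrix:
    """Run one bootstrap procedure: B draws, one penalized fit per draw.

    ``solver`` is ``"elastic_net"`` (procedure 1), ``"adaptive"``
    (procedure 2, requires the global ``importance`` vector), or
    ``"lasso"`` (Random LASSO's unweighted second procedure).  Per-draw
    seeds are derived from ``master_seed`` by (stage, draw index), so the
    result is independent of execution order and of ``n_jobs``.
    ``resample_rows=False`` replaces row resampling by the identity
    (degenerate single-draw testing hook).
    """
    if solver == "adaptive":
        if importance is None:
            raise ValueError("the adaptive stage requires an importance vector")
        importance = np.asarray(importance, dtype=float)
    if cfg is None:
        cfg = SolverConfig()
    seeds = _per_draw_seeds(master_seed, B, stage)
    tasks = (
        delayed(_fit_one_draw)(
            data.X, data.y, q, probs, solver, importance, cfg, seeds[b], b, resample_rows
        )
        for b in range(B)
    )
    results = Parallel(n_jobs=n_jobs)(tasks)
    values = np.full((data.p, B), np.nan)
    draws: list[BootstrapDraw | None] = [None] * B
    for b, draw, coefs in results:
        values[draw.col_idx, b] = coefs
        draws[b] = draw
    return CoefMatrix(values=values, draws=draws)


def importance_from_coefs(coef1: CoefMatrix, floor_eps: float = DEFAULT_FLOOR_EPS) -> ImportanceVector:
    """Importance = mean |coefficient| over the draws where the predictor was sampled.

    Missing entries are excluded from both numerator and denominator.
    Never-sampled or all-zero predictors get a floor of
    ``floor_eps * max(score)`` so they keep a positive procedure-2
    sampling probability.
    """
    if floor_eps <= 0:
        raise ValueError("floor_eps must be positive")
    mask = ~coef1.missing_mask
    counts = mask.sum(axis=1)
    if not np.any(counts):
        raise ValueError("degenerate bootstrap plan: every predictor is entirely missing")
    with np.errstate(invalid="ignore"):
        raw = np.nansum(np.abs(coef1.values), axis=1)
    raw = np.divide(raw, counts, out=np.zeros(coef1.p), where=counts > 0)
    top = raw.max()
    floor = floor_eps * (top if top > 0 else 1.0)
    scores = np.where(raw > 0, raw, floor)
    return ImportanceVector(scores=scores, probs=scores / scores.sum())


def aggregate_beta(coef2: CoefMatrix) -> np.ndarray:
    """Final coefficients: signed mean over the draws where each predictor was sampled.

    A predictor sampled in no draw gets NaN plus a logged warning, never a
    silent zero — averaging zeros over all B draws is exactly the
    systematic bias this estimator removes.
    """
    counts = (~coef2.missing_mask).sum(axis=1)
    never = np.flatnonzero(counts == 0)
    if never.size:
        logger.warning(
            "%d predictor(s) never sampled in procedure 2 (e.g. index %d); "
            "their coefficients are reported as missing",
            never.size,
            never[0],
        )
    with np.errstate(invalid="ignore"):
        sums = np.nansum(coef2.values, axis=1)
    return np.divide(sums, counts, out=np.full(coef2.p, np.nan), where=counts > 0)


def fit_hilasso(data: Dataset, config: HiLassoConfig | None = None) -> HiLassoFit:
    """Run the full Hi-LASSO estimator on a dataset.

    Procedure 1 (uniform predictor sampling, Elastic-Net fits) yields the
    importance scores; procedure 2 (importance-weighted sampling, Adaptive
    LASSO with the global scores as weights) yields the averaged
    coefficients and the PSTFSboot selected set at ``config.alpha``.
    """
    if config is None:
        config = HiLassoConfig()
    cfg = config.resolve(data.n, data.p)
    B1 = compute_num_bootstraps(cfg.L, data.p, cfg.q1)
    logger.info("procedure 1: B1=%d draws of q1=%d predictors", B1, cfg.q1)
    coef1 = run_procedure(
        data,
        cfg.q1,
        B1,
        solver="elastic_net",
        cfg=cfg.solver,
        master_seed=cfg.random_state,
        stage=1,
        n_jobs=cfg.n_jobs,
    )
    importance = importance_from_coefs(coef1, floor_eps=cfg.floor_eps)
    B2 = compute_num_bootstraps(cfg.L, data.p, cfg.q2)
    logger.info("procedure 2: B2=%d draws of q2=%d predictors", B2, cfg.q2)
    coef2 = run_procedure(
        data,
        cfg.q2,
        B2,
        solver="adaptive",
        probs=importance.probs,
        importance=importance.scores,
        cfg=cfg.solver,
        master_seed=cfg.random_state,
        stage=2,
        n_jobs=cfg.n_jobs,
    )
    beta_hat = aggregate_beta(coef2)
    test = run_selection_test(coef2, alpha=cfg.alpha, zero_tol=cfg.zero_tol)
    return HiLassoFit(
        beta_hat=beta_hat,
        importance=importance,
        coef1=coef1,
        coef2=coef2,
        test=test,
        config=cfg,
        B1=B1,
        B2=B2,
        predictor_ids=data.predictor_ids,
    )
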