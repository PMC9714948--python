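"""Synthetic-data generation for benchmarking the selectors.

Two generators.  ``make_scenario`` draws sparse linear-model data
``y = X beta + eps`` with multivariate-normal predictors under a choice
of correlation structures, at six registered (p, n) sizes spanning the
HDLSS range (p/n from 1 to 50).  ``make_semi_real`` emulates the
gene-expression setting: given any expression-like matrix and a
survival-months vector, it builds a ground-truth response by picking the
genes most correlated with survival, giving them N(4, 1)-magnitude
coefficients that preserve the correlation sign, and adding noise whose
sd equals the sd of log survival months — so a "semi-real" benchmark
with known support needs no patient data download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .dataset import Dataset

logger = logging.getLogger(__name__)

INDEPENDENT = "independent"
AR1 = "ar1"
BLOCK = "block"


@dataclass
class ScenarioConfig:
    """One synthetic sparse-regression scenario.

    correlation : "independent", "ar1" (corr(j, j') = rho^|j-j'|) or
        "block" (constant within-block correlation rho, blocks of
        ``block_size`` adjacent predictors).
    beta_magnitude : a single value, or a (low, high) range sampled
        uniformly; signs are random.
    """

    p: int
    n: int
    n_causal: int = 10
    beta_magnitude: float | tuple[float, float] = (1.0, 3.0)
    correlation: str = AR1
    rho: float = 0.5
    block_size: int = 10
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_causal > self.p:
            raise ValueError("n_causal cannot exceed p")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.correlation not in (INDEPENDENT, AR1, BLOCK):
            raise ValueError(f"unknown correlation structure: {self.correlation!r}")


@dataclass
class TrueModel:
    """Ground-truth coefficients; support = the predictors with |beta| > 0."""

    beta: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        expected = np.flatnonzero(np.abs(self.beta) > 0)
        self.support = np.asarray(self.support, dtype=int)
        if not np.array_equal(np.sort(self.support), expected):
            raise ValueError("support does not match the nonzero set of beta")

    @property
    def support_mask(self) -> np.ndarray:
        mask = np.zeros(self.beta.shape[0], dtype=bool)
        mask[self.support] = True
        return mask


def _draw_predictors(rng: np.random.Generator, cfg: ScenarioConfig) -> np.ndarray:
    """Sample X with unit-variance columns under the configured correlation."""
    n, p, rho = cfg.n, cfg.p, cfg.rho
    z = rng.standard_normal((n, p))
    if cfg.correlation == INDEPENDENT or rho == 0.0:
        return z
    if cfg.correlation == AR1:
        # column-recursive construction: x_j = rho x_{j-1} + sqrt(1-rho^2) z_j
        X = np.empty((n, p))
        X[:, 0] = z[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + scale * z[:, j]
        return X
    # block: one shared factor per block gives within-block correlation rho
    n_blocks = -(-p // cfg.block_size)
    factors = rng.standard_normal((n, n_blocks))
    block_of = np.arange(p) // cfg.block_size
    return np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * z


def make_scenario(cfg: ScenarioConfig, include_noise: bool = True) -> tuple[Dataset, TrueModel]:
    """Generate one dataset from a scenario; deterministic in ``cfg.seed``.

    ``include_noise=False`` suppresses the error term (testing hook for
    the noiseless limit y = X beta).
    """
    rng = np.random.default_rng(cfg.seed)
    X = _draw_predictors(rng, cfg)
    support = np.sort(rng.choice(cfg.p, size=cfg.n_causal, replace=False))
    if np.isscalar(cfg.beta_magnitude):
        mags = np.full(cfg.n_causal, float(cfg.beta_magnitude))
    else:
        lo, hi = cfg.beta_magnitude
        mags = rng.uniform(lo, hi, size=cfg.n_causal)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_causal)
    beta = np.zeros(cfg.p)
    beta[support] = mags * signs
    y = X @ beta
    if include_noise:
        y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.n)
    ids = np.array([f"V{j + 1}" for j in range(cfg.p)])
    return Dataset(X=X, y=y, predictor_ids=ids), TrueModel(beta=beta, support=support)


def scenario_registry() -> dict[str, ScenarioConfig]:
    """The six benchmark scenario sizes, Dataset I through Dataset VI."""
    sizes = {
        "Dataset I": (100, 50),
        "Dataset II": (100, 100),
        "Dataset III": (1000, 100),
        "Dataset IV": (1000, 200),
        "Dataset V": (10000, 200),
        "Dataset VI": (10000, 400),
    }
    return {name: ScenarioConfig(p=p, n=n) for name, (p, n) in sizes.items()}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    """Look up a registered scenario, optionally overriding fields."""
    registry = scenario_registry()
    if name not in registry:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(registry)}"
        )
    return replace(registry[name], **overrides) if overrides else registry[name]


def make_semi_real(
    expr: np.ndarray,
    survival_months: np.ndarray,
    n_causal: int = 20,
    coef_mean: float = 4.0,
    coef_sd: float = 1.0,
    seed=None,
    method: str = "pearson",
    gene_ids=None,
) -> tuple[Dataset, TrueModel]:
    """Build a known-support response on top of a real or synthetic expression matrix.

    The ``n_causal`` genes most correlated (in absolute value) with
    ``survival_months`` form the support; their coefficient magnitudes are
    drawn N(coef_mean, coef_sd^2) and carry the sign of the correlation;
    the noise sd is the sd of log survival months.  Ranking uses raw
    months (``method``: "pearson" or "spearman"); ties at the support
    boundary break by gene order and are logged.
    """
    expr = np.asarray(expr, dtype=float)
    survival_months = np.asarray(survival_months, dtype=float).ravel()
    if expr.ndim != 2 or expr.shape[0] != survival_months.shape[0]:
        raise ValueError("expr must be samples x genes with one survival value per sample")
    if np.any(survival_months <= 0):
        raise ValueError("survival months must be strictly positive (logarithm is taken)")
    n, p = expr.shape
    if p < n_causal:
        raise ValueError(f"need at least {n_causal} genes, got {p}")
    if method == "pearson":
        corr = np.array([stats.pearsonr(expr[:, j], survival_months)[0] for j in range(p)])
    elif method == "spearman":
        corr = np.array([stats.spearmanr(expr[:, j], survival_months)[0] for j in range(p)])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = np.nan_to_num(corr, nan=0.0)
    order = np.argsort(-np.abs(corr), kind="stable")  # ties break by gene order
    support = np.sort(order[:n_causal])
    if p > n_causal and np.abs(corr[order[n_causal - 1]]) == np.abs(corr[order[n_causal]]):
        logger.warning("tie in |correlation| at the support boundary; broken by gene order")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    mags = rng.normal(coef_mean, coef_sd, size=n_causal)
    beta[support] = mags * np.sign(corr[support])
    noise_sd = float(np.std(np.log(survival_months)))
    y = expr @ beta + rng.normal(0.0, noise_sd, size=n)
    if gene_ids is None:
        gene_ids = np.array([f"G{j + 1}" for j in range(p)])
    return Dataset(X=expr, y=y, predictor_ids=gene_ids), TrueModel(beta=beta, support=support)


def synthetic_expression_cohort(
    n: int = 100,
    p: int = 500,
    n_prognostic: int = 20,
    rho: float = 0.4,
    block_size: int = 25,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """A synthetic stand-in for an expression matrix plus survival months.

    Block-correlated Gaussian "expression" for n patients by p genes; the
    first ``n_prognostic`` genes drive a log-normal survival time, so a
    correlation ranking should recover them.  Returns (expr, survival_months).
    """
    cfg = ScenarioConfig(
        p=p, n=n, n_causal=n_prognostic, correlation=BLOCK, rho=rho,
        block_size=block_size, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    expr = _draw_predictors(rng, cfg)
    effects = rng.uniform(0.2, 0.5, size=n_prognostic) * rng.choice([-1.0, 1.0], size=n_prognostic)
    log_surv = 3.0 + expr[:, :n_prognostic] @ effects + rng.normal(0.0, 0.5, size=n)
    return expr, np.exp(log_surv)
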