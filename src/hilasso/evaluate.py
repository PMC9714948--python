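"""Metrics and experiment harness.

F1 on a known support (relevant = |beta| > 0 positive, |beta| = 0
negative), pairwise Kuncheva stability index, repeated-run benchmark
tables over (scenario, method) cells, and hyper-parameter sweeps over
(q, L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import fit_random_lasso
from .core import HiLassoConfig, fit_hilasso
from .simulate import ScenarioConfig, TrueModel, make_scenario

logger = logging.getLogger(__name__)


@dataclass
class SelectionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    n_nonzero: int


def f1_selection(selected: np.ndarray, truth: TrueModel) -> SelectionMetrics:
    """Confusion-matrix metrics of a selected set against the true support.

    F1 is 0 when precision + recall is 0 (e.g. an empty selection against
    a nonempty support).
    """
    selected = np.asarray(selected, dtype=bool)
    pos = truth.support_mask
    if selected.shape != pos.shape:
        raise ValueError("selected flags and truth have different lengths")
    tp = int(np.sum(selected & pos))
    fp = int(np.sum(selected & ~pos))
    fn = int(np.sum(~selected & pos))
    tn = int(np.sum(~selected & ~pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SelectionMetrics(tp, fp, fn, tn, precision, recall, f1, int(selected.sum()))


def kuncheva_index(setA, setB, p: int) -> float:
    """Chance-corrected overlap of two selected feature sets out of p.

    For equal sizes s, KI = (r*p - s^2) / (s*(p - s)) with r = |A & B|:
    1 for identical sets, ~0 for chance-level overlap.  Unequal sizes use
    the generalized form with s replaced by the geometric mean of the two
    sizes (logged as generalized).  Undefined for empty or full sets.
    """
    A, B = set(setA), set(setB)
    for s in (A, B):
        if any(not 0 <= j < p for j in s):
            raise ValueError("set elements must be indices in [0, p)")
        if len(s) == 0 or len(s) == p:
            raise ValueError("Kuncheva index undefined for empty or full sets")
    sA, sB = len(A), len(B)
    r = len(A & B)
    if sA == sB:
        s = float(sA)
    else:
        s = float(np.sqrt(sA * sB))
        logger.warning(
            "unequal set sizes (%d, %d): generalized Kuncheva index with geometric mean", sA, sB
        )
    return (r * p - s * s) / (s * (p - s))


def hilasso_method(**overrides):
    """Benchmark adapter: Hi-LASSO fit -> selected flags (+ nonzero count)."""

    def fit(dataset, seed):
        cfg = HiLassoConfig(random_state=int(seed), **overrides)
        return fit_hilasso(dataset, cfg).selected

    fit.method_name = "Hi-LASSO"
    return fit


def random_lasso_method(**overrides):
    """Benchmark adapter: Random LASSO fit -> selected flags."""

    def fit(dataset, seed):
        return fit_random_lasso(dataset, seed=int(seed), **overrides).selected

    fit.method_name = "Random LASSO"
    return fit


def builtin_methods() -> dict:
    return {"Hi-LASSO": hilasso_method(), "Random LASSO": random_lasso_method()}


@dataclass
class BenchmarkTable:
    """Mean/sd of F1 and selected-set size per (scenario, method) cell."""

    summary: pd.DataFrame  # scenario, method, f1_mean, f1_sd, nonzero_mean, nonzero_sd, repeats, seed
    records: pd.DataFrame  # one row per (scenario, method, repeat), incl. failures

    def to_csv(self, path, sep: str = "\t") -> None:
        self.summary.to_csv(path, sep=sep, index=False)


def _cell_seeds(master_seed: int, scen_idx: int, repeat: int) -> tuple[int, int]:
    """(data seed, fit seed) per repeat — the same data is shared across methods."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(scen_idx, repeat))
    a, b = ss.generate_state(2)
    return int(a) % (2**31), int(b) % (2**31)


def run_benchmark(
    scenarios: dict[str, ScenarioConfig],
    methods: dict[str, callable] | None = None,
    repeats: int = 10,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> BenchmarkTable:
    """Repeat (generate data, fit, score) per (scenario, method) cell.

    Data is regenerated per repeat with seeds derived from ``master_seed``
    and shared across methods within a repeat.  A failing (method, repeat)
    cell is recorded with status "failed", never silently dropped.  The sd
    columns hold the sample standard deviation over repeats (0 when
    repeats = 1).
    """
    if methods is None:
        methods = builtin_methods()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    for scen_idx, (scen_name, scen_cfg) in enumerate(scenarios.items()):
        for rep in range(repeats):
            data_seed, fit_seed = _cell_seeds(master_seed, scen_idx, rep)
            data, truth = make_scenario(replace(scen_cfg, seed=data_seed))
            for meth_name, method in methods.items():
                try:
                    selected = np.asarray(method(data, fit_seed), dtype=bool)
                    m = f1_selection(selected, truth)
                    rows.append(
                        dict(scenario=scen_name, method=meth_name, repeat=rep,
                             f1=m.f1, n_nonzero=m.n_nonzero, status="ok")
                    )
                except Exception as exc:
                    logger.error("%s on %s repeat %d failed: %s", meth_name, scen_name, rep, exc)
                    rows.append(
                        dict(scenario=scen_name, method=meth_name, repeat=rep,
                             f1=np.nan, n_nonzero=np.nan, status=f"failed: {exc}")
                    )
    records = pd.DataFrame(rows)
    summaries = []
    for (scen_name, meth_name), grp in records.groupby(["scenario", "method"], sort=False):
        ok = grp[grp.status == "ok"]
        def _sd(x):
            return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        summaries.append(
            dict(
                scenario=scen_name,
                method=meth_name,
                f1_mean=float(ok.f1.mean()) if len(ok) else np.nan,
                f1_sd=_sd(ok.f1),
                nonzero_mean=float(ok.n_nonzero.mean()) if len(ok) else np.nan,
                nonzero_sd=_sd(ok.n_nonzero),
                repeats=int(len(ok)),
                seed=int(master_seed),
            )
        )
    return BenchmarkTable(summary=pd.DataFrame(summaries), records=records)


def sweep_hyperparams(
    q_values,
    L_values,
    scenario: ScenarioConfig,
    repeats: int = 10,
    master_seed: int = 0,
    n_jobs: int = 1,
    **hilasso_overrides,
) -> pd.DataFrame:
    """Mean F1 over a grid of (q, L), with q applied to both q1 and q2."""
    q_values = list(q_values)
    L_values = list(L_values)
    if not q_values or not L_values:
        raise ValueError("the (q, L) grid must be nonempty")
    rows = []
    for q in q_values:
        for L in L_values:
            method = hilasso_method(q1=int(q), q2=int(q), L=int(L), n_jobs=n_jobs,
                                    **hilasso_overrides)
            table = run_benchmark(
                {"sweep": scenario}, {"Hi-LASSO": method},
                repeats=repeats, master_seed=master_seed,
            )
            cell = table.summary.iloc[0]
            rows.append(
                dict(q=int(q), L=int(L), f1_mean=cell.f1_mean, f1_sd=cell.f1_sd,
                     nonzero_mean=cell.nonzero_mean, nonzero_sd=cell.nonzero_sd,
                     repeats=int(cell.repeats))
            )
    return pd.DataFrame(rows)
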