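"""File I/O and the command-line interface.

Matrices travel as delimited text (tab or comma, auto-detected) with a
header row of predictor identifiers; vectors as one value per line.  The
CLI exposes four subcommands — fit, simulate, benchmark, sweep — as a
thin layer over the library, and every run writes a JSON manifest
(full configuration + seed + package version) sufficient to reproduce
its outputs.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import HiLassoConfig, fit_hilasso
from .dataset import Dataset
from .evaluate import builtin_methods, run_benchmark, sweep_hyperparams
from .simulate import get_scenario, make_scenario, scenario_registry

logger = logging.getLogger(__name__)


class UsageError(ValueError):
    """Invalid inputs or flags; maps to a nonzero exit with a one-line reason."""


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited numeric matrix with a header row of predictor ids.

    Returns (values, predictor_ids).  Ragged rows, non-numeric cells
    (located in the message) and duplicate identifiers raise UsageError.
    """
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
    ids, counts = np.unique(header, return_counts=True)
    dups = ids[counts > 1]
    if dups.size:
        raise UsageError(f"{path}: duplicate predictor identifiers: {', '.join(dups)}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise UsageError(f"{path}: ragged or malformed rows ({exc})") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise UsageError(f"{path}: non-numeric cell at row {bad + 2}, column {col!r}")
    values = df.to_numpy(dtype=float)
    logger.info("%s: %d samples x %d predictors", path, *values.shape)
    return values, df.columns.to_numpy(dtype=object)


def write_matrix(path, values: np.ndarray, predictor_ids, sep: str = "\t") -> None:
    pd.DataFrame(values, columns=list(predictor_ids)).to_csv(path, sep=sep, index=False)


def read_vector(path) -> np.ndarray:
    vals = np.loadtxt(path, ndmin=1)
    if vals.ndim != 1:
        raise UsageError(f"{path}: expected one value per line")
    return vals


def write_vector(path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.17g")


def load_dataset(x_path, y_path) -> Dataset:
    X, ids = read_matrix(x_path)
    y = read_vector(y_path)
    if y.shape[0] != X.shape[0]:
        raise UsageError(
            f"X has {X.shape[0]} samples but y has {y.shape[0]} values"
        )
    return Dataset(X=X, y=y, predictor_ids=ids)


def _write_manifest(out_dir: Path, command: str, config: dict) -> None:
    manifest = {"package": "hilasso", "version": __version__, "command": command,
                "config": config}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def coefficient_table(fit) -> pd.DataFrame:
    """Exportable per-predictor table; missing-flagged coefficients become 0
    with never_sampled = True so downstream tools never see a silent zero."""
    never = fit.never_sampled
    return pd.DataFrame(
        {
            "predictor_id": fit.predictor_ids,
            "beta_hat": np.where(never, 0.0, fit.beta_hat),
            "importance": fit.importance.scores,
            "k": fit.test.k,
            "d": fit.test.d,
            "pvalue": fit.test.pvalue,
            "selected": fit.test.selected.astype(int),
            "never_sampled": never.astype(int),
        }
    )


def _cmd_fit(args) -> int:
    data = load_dataset(args.x, args.y)
    if args.q1 is not None and args.q1 > data.p:
        raise UsageError(f"--q1 ({args.q1}) must not exceed the number of predictors p={data.p}")
    if args.q2 is not None and args.q2 > data.p:
        raise UsageError(f"--q2 ({args.q2}) must not exceed the number of predictors p={data.p}")
    config = HiLassoConfig(
        q1=args.q1, q2=args.q2, L=args.L, alpha=args.alpha, logistic=args.logistic,
        random_state=args.random_state, n_jobs=args.n_jobs, zero_tol=args.zero_tol,
    )
    fit = fit_hilasso(data, config)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = coefficient_table(fit)
    table.to_csv(out / "coefficients.tsv", sep="\t", index=False)
    sel = table.loc[table.selected == 1, "predictor_id"]
    (out / "selected_features.txt").write_text("".join(f"{s}\n" for s in sel))
    _write_manifest(
        out, "fit",
        dict(x=str(args.x), y=str(args.y), q1=fit.config.q1, q2=fit.config.q2,
             L=fit.config.L, alpha=fit.config.alpha, logistic=fit.config.logistic,
             random_state=fit.config.random_state, n_jobs=fit.config.n_jobs,
             zero_tol=fit.config.zero_tol, B1=fit.B1, B2=fit.B2),
    )
    print(f"selected {int(table.selected.sum())} of {data.p} predictors "
          f"(pi0={fit.test.pi0:.4f}, B1={fit.B1}, B2={fit.B2})")
    return 0


def _cmd_simulate(args) -> int:
    if args.scenario is not None:
        try:
            cfg = get_scenario(args.scenario, seed=args.seed)
        except KeyError as exc:
            raise UsageError(str(exc)) from exc
    else:
        if args.p is None or args.n is None:
            raise UsageError("provide --scenario or both --p and --n")
        cfg = get_scenario("Dataset I").__class__(p=args.p, n=args.n, seed=args.seed)
    data, truth = make_scenario(cfg)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(out / "X.tsv", data.X, data.predictor_ids)
    write_vector(out / "y.tsv", data.y)
    pd.DataFrame({"predictor_id": data.predictor_ids, "beta": truth.beta}).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
    _write_manifest(out, "simulate", dict(scenario=args.scenario, **cfg.__dict__))
    print(f"wrote X ({data.n} x {data.p}), y and truth to {out}")
    return 0


def _cmd_benchmark(args) -> int:
    scenarios = {}
    for name in args.scenario:
        try:
            scenarios[name] = get_scenario(name)
        except KeyError as exc:
            raise UsageError(str(exc)) from exc
    methods = builtin_methods()
    if args.method:
        unknown = [m for m in args.method if m not in methods]
        if unknown:
            raise UsageError(f"unknown method(s): {', '.join(unknown)}")
        methods = {m: methods[m] for m in args.method}
    table = run_benchmark(scenarios, methods, repeats=args.repeats, master_seed=args.seed)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "benchmark.tsv")
    table.records.to_csv(out / "benchmark_records.tsv", sep="\t", index=False)
    _write_manifest(out, "benchmark", dict(scenario=args.scenario, method=list(methods),
                                           repeats=args.repeats, seed=args.seed))
    print(table.summary.to_string(index=False))
    return 0


def _cmd_sweep(args) -> int:
    try:
        cfg = get_scenario(args.scenario)
    except KeyError as exc:
        raise UsageError(str(exc)) from exc
    table = sweep_hyperparams(args.q, args.L, cfg, repeats=args.repeats, master_seed=args.seed)
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "sweep.tsv", sep="\t", index=False)
    _write_manifest(out, "sweep", dict(scenario=args.scenario, q=args.q, L=args.L,
                                       repeats=args.repeats, seed=args.seed))
    print(table.to_string(index=False))
    return 0


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="hilasso",
        description="Hi-LASSO bootstrap feature selection for high-dimensional data",
    )
    parser.add_argument("--log-level", default="WARNING")
    sub = parser.add_subparsers(dest="command", required=True)

    fit = sub.add_parser("fit", help="fit Hi-LASSO on a design matrix and response")
    fit.add_argument("--x", required=True, help="design matrix (delimited, header row)")
    fit.add_argument("--y", required=True, help="response vector (one value per line)")
    fit.add_argument("--out-dir", required=True)
    fit.add_argument("--q1", type=int, default=None)
    fit.add_argument("--q2", type=int, default=None)
    fit.add_argument("--L", type=int, default=30)
    fit.add_argument("--alpha", type=float, default=0.05)
    fit.add_argument("--logistic", action="store_true")
    fit.add_argument("--random-state", type=int, default=None)
    fit.add_argument("--n-jobs", type=int, default=1)
    fit.add_argument("--zero-tol", type=float, default=0.0)
    fit.set_defaults(func=_cmd_fit)

    sim = sub.add_parser("simulate", help="write a synthetic benchmark dataset")
    sim.add_argument("--scenario", default=None, help='e.g. "Dataset I"')
    sim.add_argument("--p", type=int, default=None)
    sim.add_argument("--n", type=int, default=None)
    sim.add_argument("--seed", type=int, default=None)
    sim.add_argument("--out-dir", required=True)
    sim.set_defaults(func=_cmd_simulate)

    bench = sub.add_parser("benchmark", help="repeated-run F1 benchmark table")
    bench.add_argument("--scenario", action="append", required=True)
    bench.add_argument("--method", action="append", default=None)
    bench.add_argument("--repeats", type=int, default=10)
    bench.add_argument("--seed", type=int, default=0)
    bench.add_argument("--out-dir", required=True)
    bench.set_defaults(func=_cmd_benchmark)

    sweep = sub.add_parser("sweep", help="mean F1 over a (q, L) grid")
    sweep.add_argument("--scenario", required=True)
    sweep.add_argument("--q", type=int, action="append", required=True)
    sweep.add_argument("--L", type=int, action="append", required=True)
    sweep.add_argument("--repeats", type=int, default=10)
    sweep.add_argument("--seed", type=int, default=0)
    sweep.add_argument("--out-dir", required=True)
    sweep.set_defaults(func=_cmd_sweep)
    return parser


def run_cli(argv=None) -> int:
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    logging.basicConfig(level=getattr(logging, args.log_level.upper(), logging.WARNING))
    try:
        return args.func(args)
    except (UsageError, ValueError, FileNotFoundError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2


def main() -> None:
    sys.exit(run_cli())
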