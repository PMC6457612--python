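"""End-to-end orchestration: ingest -> filter -> encode -> frame -> fit ->
evaluate -> importance -> report, driven by one YAML config and one seed.

Every stage logs its input/output row and column counts into the run
manifest so row losses are accounted for; every output CSV carries the
config hash in a leading comment line; and the per-cell seeds are expanded
deterministically from the global seed and the (stage, outcome, interval)
labels, so outcome x interval cells are independent jobs whose results do
not depend on execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    CohortTable,
    build_missingness_basis,
    expand_dummies,
    filter_variability,
    load_cohort,
)
from .evaluation import CVPerformance, nested_cv_auc, roc_curve
from .importance import forest_importance_ranking
from .interval_framing import OVERALL, build_person_periods, support_matrix
from .superlearner import LearnerSpec, _stable_seed, default_library

logger = logging.getLogger("dynasl")


def configure_logging(level: int = logging.INFO) -> None:
    """Plain-text logging with ISO timestamps on stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """Everything a run needs; see ``from_yaml`` for the file schema."""

    outcomes: Sequence[str]
    terminal_outcome: str = "death"
    input_path: str | None = None
    input_format: str | None = None
    time_grid: Sequence[float] | None = None
    min_count: int = 50
    min_events: int = 50
    learners: Sequence[Mapping] | None = None
    V_inner: int = 10
    V_outer: int = 10
    top_k: int = 3
    seed: int = 0
    output_dir: str = "dynasl_run"
    max_levels: int = 20
    simulate: Mapping | None = None     # passed to synthetic default_config

    def library(self) -> list[LearnerSpec]:
        if self.learners is None:
            return default_library()
        specs = []
        for entry in self.learners:
            entry = dict(entry)
            family = entry.pop("family")
            specs.append(LearnerSpec(family, entry))
        return specs

    def to_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "terminal_outcome": self.terminal_outcome,
            "input_path": self.input_path,
            "input_format": self.input_format,
            "time_grid": list(self.time_grid) if self.time_grid else None,
            "min_count": self.min_count,
            "min_events": self.min_events,
            "learners": [dict(e) for e in self.learners] if self.learners else None,
            "V_inner": self.V_inner,
            "V_outer": self.V_outer,
            "top_k": self.top_k,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "max_levels": self.max_levels,
            "simulate": dict(self.simulate) if self.simulate else None,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig, table: CohortTable | None = None) -> dict:
    """Run the full analysis; returns (and writes) the run manifest.

    ``table`` short-circuits loading — used when the cohort was just
    simulated in-process.  Any stage error aborts with a stage-named
    message; partial outputs stay on disk next to a FAILED marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "results": [],
        "importance": [],
    }
    stage = "setup"
    try:
        if table is None:
            stage = "load"
            if config.input_path is None and config.simulate is not None:
                from .synthetic_cohort import default_config, generate_cohort

                sim = dict(config.simulate)
                sim.setdefault("seed", _stable_seed(config.seed, "simulate"))
                cfg = default_config(**sim)
                table, truth = generate_cohort(cfg)
                truth.to_csv(out / "ground_truth.csv")
                table.to_csv(out / "cohort.csv")
            elif config.input_path is not None:
                table = load_cohort(config.input_path, config.input_format)
            else:
                raise ValueError("no input_path and no simulate block")
        manifest["stages"]["load"] = _shape(table)

        stage = "filter_variability"
        table, report = filter_variability(table, min_count=config.min_count)
        report.to_csv(out / "filter_report.csv")
        manifest["stages"][stage] = _shape(table)

        stage = "expand_dummies"
        table = expand_dummies(table, max_levels=config.max_levels)
        manifest["stages"][stage] = _shape(table)

        stage = "missingness_basis"
        table = build_missingness_basis(table)
        manifest["stages"][stage] = _shape(table)

        stage = "support_matrix"
        support = support_matrix(
            table,
            config.outcomes,
            min_events=config.min_events,
            grid=config.time_grid,
            terminal_outcome=config.terminal_outcome,
        )
        support.to_csv(out / "support_matrix.csv")
        _write_csv(support.counts, out / "support_counts.csv", chash, index=True)
        manifest["stages"][stage] = {
            "supported_cells": int(support.supported.to_numpy().sum())
        }

        library = config.library()
        results: list[CVPerformance] = []
        pp_cache = {}
        for outcome in config.outcomes:
            stage = f"evaluate:{outcome}:overall"
            overall = build_person_periods(
                table, outcome, mode="overall", grid=config.time_grid,
                terminal_outcome=config.terminal_outcome,
            )
            perf = nested_cv_auc(
                library, overall, outer_V=config.V_outer, inner_V=config.V_inner,
                seed=_stable_seed(config.seed, "eval", outcome, "overall"),
            )
            results.append(perf)
            _write_roc(out, perf, chash)

            interval_pp = build_person_periods(
                table, outcome, mode="interval", grid=config.time_grid,
                terminal_outcome=config.terminal_outcome,
            )
            pp_cache[outcome] = interval_pp
            for j in range(1, interval_pp.n_intervals + 1):
                t_right = float(interval_pp.grid[j])
                if not support.is_supported(outcome, t_right):
                    continue
                stage = f"evaluate:{outcome}:interval{j}"
                perf = nested_cv_auc(
                    library, interval_pp, outer_V=config.V_outer,
                    inner_V=config.V_inner, interval=j,
                    seed=_stable_seed(config.seed, "eval", outcome, j),
                )
                results.append(perf)

        stage = "results_table"
        res_frame = pd.DataFrame(
            [
                {
                    "outcome": r.outcome,
                    "interval": r.interval,
                    "cv_auc": round(r.cv_auc, 6),
                    "ci_lower": round(r.ci_lower, 6),
                    "ci_upper": round(r.ci_upper, 6),
                    "n": r.n,
                    "n_events": r.n_events,
                    "high_performance": r.high_performance,
                }
                for r in results
            ]
        )
        _write_csv(res_frame, out / "results.csv", chash)
        manifest["results"] = res_frame.to_dict(orient="records")

        stage = "importance"
        imp_frames = []
        for r in results:
            if not r.high_performance or r.interval == "overall":
                continue
            pp = pp_cache[r.outcome]
            X, y, _ = pp.design(int(r.interval))
            ranking = forest_importance_ranking(
                X, y, outcome=r.outcome, timepoint=float(pp.grid[int(r.interval)]),
                k=config.top_k,
                seed=_stable_seed(config.seed, "importance", r.outcome, r.interval),
            )
            imp_frames.append(ranking.to_frame())
        if imp_frames:
            imp = pd.concat(imp_frames, ignore_index=True)
            _write_csv(imp, out / "importance_top.csv", chash)
            manifest["importance"] = imp.to_dict(orient="records")

        stage = "manifest"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _shape(table: CohortTable) -> dict:
    return {"rows": int(table.n_patients), "columns": int(len(table.meta))}


def _write_roc(out: Path, perf: CVPerformance, chash: str) -> None:
    """ROC points of the pooled held-out predictions (honest, not refit)."""
    if perf.pooled_scores is None:
        return
    curve = roc_curve(perf.pooled_scores, perf.pooled_y)
    _write_csv(curve.to_frame(), out / f"roc_{perf.outcome}_{perf.interval}.csv", chash)


def make_report(run_dir: str | Path) -> list[Path]:
    """Assemble the report artifacts from a completed run directory.

    Values are copied from the underlying CSVs, never recomputed, so the
    report cannot drift from the run.  Missing artifacts raise an error
    listing them.
    """
    run_dir = Path(run_dir)
    required = ["manifest.json", "results.csv", "support_matrix.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"run directory lacks artifacts: {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    results = pd.read_csv(run_dir / "results.csv", comment="#")
    support = pd.read_csv(run_dir / "support_matrix.csv")

    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    written = []

    auc_table = results.pivot_table(
        index="outcome", columns="interval", values="cv_auc", aggfunc="first"
    )
    path = report_dir / "auc_by_interval.csv"
    auc_table.to_csv(path)
    written.append(path)

    path = report_dir / "support_matrix.csv"
    support.to_csv(path, index=False)
    written.append(path)

    lines = [f"dynasl run report (config {manifest['config_hash']})", ""]
    overall = results[results["interval"] == "overall"]
    lines.append("Overall prediction from admission data:")
    for _, r in overall.iterrows():
        flag = " [high-performance]" if r["high_performance"] else ""
        lines.append(
            f"  {r['outcome']}: AUC {r['cv_auc']:.3f} "
            f"({r['ci_lower']:.3f}-{r['ci_upper']:.3f}), "
            f"{int(r['n_events'])}/{int(r['n'])} events{flag}"
        )
    interval_rows = results[results["interval"] != "overall"]
    if len(interval_rows):
        lines.append("")
        lines.append("Interval prediction (supported cells):")
        for _, r in interval_rows.iterrows():
            lines.append(
                f"  {r['outcome']} @ interval {r['interval']}: AUC {r['cv_auc']:.3f} "
                f"({r['ci_lower']:.3f}-{r['ci_upper']:.3f})"
            )
    else:
        lines.append("")
        lines.append("No supported interval cells (see support_matrix.csv).")
    imp_path = run_dir / "importance_top.csv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path, comment="#")
        path = report_dir / "importance_top.csv"
        imp.to_csv(path, index=False)
        written.append(path)
        lines.append("")
        lines.append(f"Top-{int(imp['rank'].max())} importance (high-performance cells):")
        for _, r in imp.iterrows():
            tag = " [missingness indicator]" if r["missingness_indicator"] else ""
            lines.append(
                f"  {r['outcome']} @ {r['timepoint']}h rank {int(r['rank'])}: "
                f"{r['variable']} ({r['score']:.4f}){tag}"
            )
    path = report_dir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
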