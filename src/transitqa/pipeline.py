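"""End-to-end study orchestration.

Generate (or load) the scenario suite, evaluate every gamma metric on every
scenario, label scenarios at the configured |PTV ΔDmean| thresholds, build a
ROC curve per (metric, threshold), and emit the report tables: the long
passing-rate table, the AUC / optimal-passing-rate table per normalization,
and the fraction of erroneous scenarios failing the tolerance passing rate
per metric. Fully deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .failure_sim import Scenario, SuiteConfig, generate_suite, export_suite
from .gamma import GammaCriterion, STUDY_DOSE_DTA, evaluate_criteria_set
from .roc_analysis import (
    LabeledScore,
    RocError,
    build_roc,
    round_half_up,
    summarize_group,
    tolerance_failure_fraction,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "report_tables"]

log = logging.getLogger("transitqa")


@dataclass
class StudyConfig:
    """Study configuration; the defaults reproduce the study shape:
    7 criteria x {global, local} = 14 metrics, 20% dose threshold, 95%
    tolerance passing rate, deviation thresholds {5, 10, 20}%."""

    criteria: tuple = tuple(STUDY_DOSE_DTA)
    normalizations: tuple = ("global", "local")
    threshold_pct: float = 20.0
    pass_limit: float = 1.0
    tolerance_pct: float = 95.0
    delta_thresholds_pct: tuple = (5.0, 10.0, 20.0)
    suite: SuiteConfig = field(default_factory=SuiteConfig)
    seed: int = 0
    output_dir: str | None = None

    def gamma_criteria(self) -> list[GammaCriterion]:
        return [
            GammaCriterion(dd, dta, norm, self.threshold_pct, self.pass_limit)
            for norm in self.normalizations
            for dd, dta in self.criteria
        ]

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        suite = SuiteConfig(**{k: _tupled(v) for k, v in raw.pop("suite", {}).items()})
        kwargs = {k: _tupled(v) for k, v in raw.items()}
        return cls(suite=suite, **kwargs)

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, default_flow_style=None)


def _tupled(v):
    if isinstance(v, list):
        return tuple(_tupled(x) for x in v)
    return v


@dataclass
class StudyReport:
    manifest: pd.DataFrame
    rates: pd.DataFrame
    roc_table: pd.DataFrame
    roc_points: pd.DataFrame
    tolerance_fractions: pd.DataFrame
    scenarios: list[Scenario]


def _evaluate_suite(scenarios: Sequence[Scenario], config: StudyConfig) -> pd.DataFrame:
    criteria = config.gamma_criteria()
    frames = []
    for sc in scenarios:
        t0 = time.perf_counter()
        df = evaluate_criteria_set(sc.reference, sc.evaluated, criteria)
        df.insert(0, "scenario_id", sc.scenario_id)
        df["failure_mode"] = sc.failure_mode
        df["delta_dmean_pct"] = sc.delta_dmean_pct
        frames.append(df)
        log.info("gamma %-32s %d metrics in %.1fs", sc.scenario_id, len(df),
                 time.perf_counter() - t0)
        bad = df[df["error"] != ""]
        for _, row in bad.iterrows():
            log.warning("scenario %s metric %s failed: %s",
                        sc.scenario_id, row["criterion"], row["error"])
    return pd.concat(frames, ignore_index=True)


def _roc_tables(rates: pd.DataFrame, config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    roc_rows = []
    point_frames = []
    key_cols = ["dose_diff_pct", "dta_mm", "normalization"]
    for keys, grp in rates.groupby(key_cols, sort=False):
        for thr in config.delta_thresholds_pct:
            ok = grp[grp["error"] == ""]
            scores = [
                LabeledScore(r.scenario_id, r.passing_rate_pct,
                             int(abs(r.delta_dmean_pct) > thr))
                for r in ok.itertuples()
            ]
            row = dict(zip(key_cols, keys))
            row["delta_threshold_pct"] = thr
            row["n_scenarios"] = len(scores)
            row["n_positive"] = sum(s.label for s in scores)
            try:
                roc = build_roc(scores)
            except RocError as exc:
                row.update(auc=np.nan, optimal_passing_rate_pct=np.nan, j_max=np.nan,
                           sens_at_opt=np.nan, spec_at_opt=np.nan, note=str(exc))
                log.warning("ROC %s @ >%g%%: %s", keys, thr, exc)
            else:
                row.update(auc=roc.auc, optimal_passing_rate_pct=roc.optimal_cutoff_pct,
                           j_max=roc.j_max, sens_at_opt=roc.sens_at_opt,
                           spec_at_opt=roc.spec_at_opt, note="")
                pts = roc.points.copy()
                for c, v in zip(key_cols, keys):
                    pts[c] = v
                pts["delta_threshold_pct"] = thr
                point_frames.append(pts)
            roc_rows.append(row)
    points = (pd.concat(point_frames, ignore_index=True)
              if point_frames else pd.DataFrame())
    return pd.DataFrame(roc_rows), points


def run_study(config: StudyConfig | None = None,
              scenarios: Sequence[Scenario] | None = None) -> StudyReport:
    """Run the full study; pass pre-built ``scenarios`` (e.g. re-loaded from
    an exported suite directory) to skip generation."""
    config = config or StudyConfig()
    t0 = time.perf_counter()
    if scenarios is None:
        scenarios = generate_suite(config.suite, config.seed)
        log.info("generated %d scenarios in %.1fs", len(scenarios),
                 time.perf_counter() - t0)

    manifest = pd.DataFrame(
        {
            "scenario_id": sc.scenario_id,
            "failure_mode": sc.failure_mode,
            "parameters": json.dumps(sc.parameters),
            "delta_dmean_pct": sc.delta_dmean_pct,
        }
        for sc in scenarios
    )
    rates = _evaluate_suite(scenarios, config)
    roc_table, roc_points = _roc_tables(rates, config)
    ok = rates[rates["error"] == ""]
    tol = tolerance_failure_fraction(ok, config.tolerance_pct,
                                     metric_cols=("criterion",)).rename("failure_fraction")
    tol = tol.reset_index()

    report = StudyReport(manifest, rates, roc_table, roc_points, tol, list(scenarios))
    if config.output_dir:
        _write_report(report, config)
    log.info("study complete in %.1fs", time.perf_counter() - t0)
    return report


def _write_report(report: StudyReport, config: StudyConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report.manifest.to_csv(os.path.join(out, "manifest.csv"), index=False)
    report.rates.to_csv(os.path.join(out, "passing_rates.csv"), index=False)
    report.roc_table.to_csv(os.path.join(out, "roc_table.csv"), index=False)
    report.roc_points.to_csv(os.path.join(out, "roc_points.csv"), index=False)
    report.tolerance_fractions.to_csv(os.path.join(out, "tolerance_failures.csv"),
                                      index=False)
    for norm, table in report_tables(report.roc_table).items():
        table.to_csv(os.path.join(out, f"summary_{norm}.csv"))
    log_payload = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "transitqa": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log_payload, fh, indent=2, default=str)


def report_tables(roc_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-normalization summary tables: one row per criterion, columns
    (AUC, optimal passing rate) per deviation threshold, AUC at 2 decimals
    and rates at 1, plus a mean-AUC row per threshold."""
    tables: dict[str, pd.DataFrame] = {}
    if roc_table.empty:
        return tables
    for norm, grp in roc_table.groupby("normalization", sort=False):
        rows: dict[str, dict[str, float]] = {}
        means: dict[str, float] = {}
        for thr, sub in grp.groupby("delta_threshold_pct", sort=True):
            defined = sub[sub["auc"].notna()]
            for r in sub.itertuples():
                label = f"{r.dose_diff_pct:g}%/{r.dta_mm:g}mm"
                rows.setdefault(label, {})
                rows[label][f"AUC >{thr:g}%"] = (
                    round_half_up(r.auc, 2) if np.isfinite(r.auc) else np.nan)
                rows[label][f"Optimal rate >{thr:g}%"] = (
                    round_half_up(r.optimal_passing_rate_pct, 1)
                    if np.isfinite(r.optimal_passing_rate_pct) else np.nan)
            if len(defined):
                means[f"AUC >{thr:g}%"] = summarize_group(
                    {i: a for i, a in enumerate(defined["auc"])})
        table = pd.DataFrame(rows).T
        if means:
            table.loc["mean"] = pd.Series(means)
        table.index.name = "criterion"
        tables[norm] = table
    return tables
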