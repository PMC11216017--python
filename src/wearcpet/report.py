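"""Pipeline orchestration, exclusion-flow accounting and reproducibility.

``run_pipeline`` executes simulate -> watch -> cpet -> associate in order,
writes every stage output as CSV under one output directory, records a
sample-flow table (who was excluded at which filter) and a JSON run manifest
with the configuration hash, seed and SHA-256 digests of every written
file.  With a fixed configuration and seed the outputs are byte-identical
across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assoc, cpet, synth, watch
from .config import AnalysisConfig

logger = logging.getLogger("wearcpet")

ALL_STAGES = ("simulate", "watch", "cpet", "associate")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run."""
    params: synth.CohortParams = field(default_factory=synth.CohortParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stages: tuple[str, ...] = ALL_STAGES
    write_inputs: bool = True

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run.  Re-running with the same
    configuration and seed reproduces byte-identical stage outputs."""
    config_hash: str
    seed: int
    stages: list[str]
    file_digests: dict[str, str]
    flow: list[dict]
    timestamps: dict | None = None   # left None so manifests are reproducible

    def to_json(self) -> str:
        return json.dumps(_jsonable(self), sort_keys=True, indent=2)


# ---------------------------------------------------------------------------
# Human-readable outputs
# ---------------------------------------------------------------------------

def format_results_table(results: pd.DataFrame,
                         analysis: str = "primary") -> str:
    """Render one analysis as a fixed-width grid: one row per exposure,
    (beta, SE, FDR p) per (outcome, model) cell."""
    sub = results[results["analysis"] == analysis]
    if len(sub) == 0:
        return f"(no rows for analysis {analysis!r})\n"
    lines = [f"Associations ({analysis}); beta per SD of exposure", ""]
    header = f"{'exposure':<24}"
    cells = sorted(sub.groupby(["outcome", "model"]).groups)
    for outcome, model in cells:
        header += f"{outcome + '/' + model:>28}"
    lines.append(header)
    for exp in sub["exposure"].unique():
        row = f"{exp:<24}"
        for outcome, model in cells:
            r = sub[(sub["exposure"] == exp) & (sub["outcome"] == outcome)
                    & (sub["model"] == model)]
            if len(r):
                r = r.iloc[0]
                p = ("<.001" if r["p_fdr"] < 0.001 else f"{r['p_fdr']:.3f}")
                row += f"{r['beta']:>12.2f} ({r['se']:.2f}) {p:>6}"
            else:
                row += f"{'-':>28}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def forest_data(results: pd.DataFrame) -> pd.DataFrame:
    """Per-fit effect estimates with 95% CIs, ready for a forest plot."""
    out = results.copy()
    out["ci_lo"] = out["beta"] - 1.96 * out["se"]
    out["ci_hi"] = out["beta"] + 1.96 * out["se"]
    return out[["analysis", "outcome", "model", "exposure",
                "beta", "ci_lo", "ci_hi", "p_fdr", "n"]]


# ---------------------------------------------------------------------------
# Exclusion flow
# ---------------------------------------------------------------------------

def exclusion_flow(covariates: pd.DataFrame,
                   watch_summary: pd.DataFrame,
                   cpet_results: pd.DataFrame | None = None,
                   rer_filter: bool = False) -> pd.DataFrame:
    """Ordered sample-flow table: (criterion, n_before, n_excluded, n_after).

    Criteria, applied sequentially: watch nonuse; fewer than 30 days of HR
    data; fewer than 30 valid step days; missing covariates or outcomes;
    optionally peak RER < 1.05.  The exclusion counts sum to
    n_start - n_final by construction.
    """
    df = covariates.merge(watch_summary, on="participant_id", how="left")
    if cpet_results is not None and len(cpet_results):
        df = df.merge(cpet_results, on="participant_id", how="left")
    for c in ("included_hr", "included_steps"):
        if c in df.columns:
            df[c] = df[c].astype("boolean").fillna(False).astype(bool)
        else:
            df[c] = False

    steps = [("watch nonuse", df["watch_user"].astype(bool)
              if "watch_user" in df.columns else pd.Series(True, index=df.index)),
             ("<30 days of HR data", df["included_hr"]),
             ("<30 valid step days", df["included_steps"])]

    lab_cols = [c for c in ("total_cholesterol", "hdl", "fasting_glucose",
                            "nonactive_hr_mean", "mean_daily_steps")
                if c in df.columns]
    keep_missing = df[lab_cols].notna().all(axis=1) if lab_cols else pd.Series(
        True, index=df.index)
    steps.append(("missing covariates or outcomes", keep_missing))
    if rer_filter and "adequate_effort" in df.columns:
        steps.append(("peak RER < 1.05",
                      df["adequate_effort"].astype("boolean")
                      .fillna(False).astype(bool)))

    rows = []
    remaining = pd.Series(True, index=df.index)
    for name, keep in steps:
        n_before = int(remaining.sum())
        remaining = remaining & keep
        n_after = int(remaining.sum())
        rows.append({"criterion": name, "n_before": n_before,
                     "n_excluded": n_before - n_after, "n_after": n_after})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class StageDependencyError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages in order and write all outputs.

    Raises :class:`StageDependencyError` when a requested stage's inputs
    were not produced by an earlier stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stages = list(config.stages)

    study = None
    labeled = days = participants = None
    cpet_results = None
    flow_rows: list[dict] = []

    if "simulate" in stages:
        logger.info("simulate: n=%d seed=%d", config.params.n_participants,
                    config.params.seed)
        study = synth.generate_study(config.params)
        if config.write_inputs:
            for name, path in synth.write_study_csvs(study, out / "inputs").items():
                written[f"inputs/{name}"] = path
        logger.info("simulate: %d HR records, %d step records",
                    len(study.hr), len(study.steps))

    if "watch" in stages:
        if study is None:
            raise StageDependencyError("watch stage requires simulate")
        labeled, days, participants = watch.process_watch(
            study.hr[synth.HR_COLUMNS], study.steps)
        days.to_csv(out / "person_days.csv", index=False)
        participants.to_csv(out / "watch_summary.csv", index=False)
        written["person_days"] = out / "person_days.csv"
        written["watch_summary"] = out / "watch_summary.csv"
        logger.info("watch: %d person-days, %d participants summarized",
                    len(days), len(participants))

    if "cpet" in stages:
        if study is None:
            raise StageDependencyError("cpet stage requires simulate")
        cpet_results = cpet.process_cpet(study.breath, study.sbp,
                                         study.covariates)
        cpet_results.to_csv(out / "cpet_results.csv", index=False)
        written["cpet_results"] = out / "cpet_results.csv"
        logger.info("cpet: %d sessions processed", len(cpet_results))

    if "associate" in stages:
        missing = [s for s, v in (("watch", participants),
                                  ("cpet", cpet_results)) if v is None]
        if missing:
            raise StageDependencyError(
                f"associate stage requires stage(s) {missing} to have run")
        table = assoc.build_analysis_table(
            study.covariates, participants, cpet_results, config.analysis)
        battery = assoc.run_battery(table, config.analysis)
        battery.results.to_csv(out / "association_results.csv", index=False)
        written["association_results"] = out / "association_results.csv"
        forest_data(battery.results).to_csv(out / "forest_data.csv", index=False)
        written["forest_data"] = out / "forest_data.csv"
        (out / "results_table.txt").write_text(
            format_results_table(battery.results))
        written["results_table"] = out / "results_table.txt"
        if len(battery.interactions):
            battery.interactions.to_csv(out / "interactions.csv", index=False)
            written["interactions"] = out / "interactions.csv"
        flow = exclusion_flow(study.covariates, participants, cpet_results,
                              rer_filter=False)
        flow.to_csv(out / "exclusion_flow.csv", index=False)
        written["exclusion_flow"] = out / "exclusion_flow.csv"
        flow_rows = flow.to_dict("records")
        n_primary = int(table["included_primary"].sum())
        logger.info("associate: %d result rows, primary sample n=%d",
                    len(battery.results), n_primary)

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.params.seed,
        stages=stages,
        file_digests={k: _digest(p) for k, p in sorted(written.items())},
        flow=flow_rows,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
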