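"""Stage-wise pipeline: simulate -> detect -> extract -> summarize -> stats.

Each stage consumes only the declared files from the output directory and
writes its own artifacts, so stages can be re-run independently; a full run
with the same configuration and seed is bit-identical.

Artifacts (all plain text inside the output directory):

* gaze.csv, phases.csv, trials.csv, ground_truth.json, manifest.json
* events.csv (fixations + tracking + saccades, AOI-labeled)
* qe.csv (the extracted quiet-eye periods)
* tables/  accuracy.csv, phase_share.csv, qe_frequency.csv,
  timing_summary.csv, location_probability.csv, dataset_report.json
* stats/   chisq_phase_share.json, permutation_*.json
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .core import FINAL_THREE, MotorPhaseSet
from .events import DetectionParams, Fixation, classify_trial
from .geometry import build_scene_layout
from .inference import chisq_gof, permutation_contrast
from .quiet_eye import extract_qe_periods
from .simulate import SimulationConfig, generate_dataset
from .summarize import (
    accuracy_from_trials,
    accuracy_table,
    location_probability,
    phase_share,
    qe_frequency,
    timing_summary,
)

log = logging.getLogger("quieteye")

STAGES = ("simulate", "detect", "extract", "summarize", "stats")


@dataclass
class PipelineConfig:
    out_dir: str = "qe_run"
    seed: int = 0
    steps: Sequence[str] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    n_permutations: int = 999

    def __post_init__(self) -> None:
        bad = set(self.steps) - set(STAGES)
        if bad:
            raise ValueError(f"unknown pipeline step(s): {sorted(bad)}")


def _out(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(config: PipelineConfig) -> None:
    out = _out(config)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    data = generate_dataset(sim)
    qio.write_gaze_recordings(data.recordings, out / "gaze.csv")
    qio.write_phase_annotations(data.phases, out / "phases.csv")
    pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in data.recordings],
            "participant": [r.participant for r in data.recordings],
            "condition": [r.condition for r in data.recordings],
            "outcome": [r.outcome for r in data.recordings],
        }
    ).to_csv(out / "trials.csv", index=False)
    gt = {
        tid: {
            "fixations": g.fixations,
            "saccades": g.saccades,
            "qe": g.qe,
            "occlusion": g.occlusion,
        }
        for tid, g in data.ground_truth.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(data.manifest, indent=1, sort_keys=True)
    )
    log.info("simulate: %d trials -> %s", len(data.recordings), out)


def stage_detect(config: PipelineConfig) -> None:
    out = _out(config)
    recordings = qio.read_gaze_recordings(out / "gaze.csv")
    layout = build_scene_layout()
    events = []
    for rec in recordings:
        fixations, saccades = classify_trial(rec, config.detection, layout)
        events.extend(fixations)
        events.extend(saccades)
    qio.write_event_table(events, out / "events.csv")
    log.info("detect: %d events over %d trials", len(events), len(recordings))


def stage_extract(config: PipelineConfig) -> None:
    out = _out(config)
    events = qio.read_event_table(out / "events.csv")
    phases = qio.read_phase_annotations(out / "phases.csv")
    qe = []
    fix_rows = events[events["event_type"].isin(["fixation", "tracking"])]
    for trial_id, g in fix_rows.groupby("trial_id", sort=False):
        if str(trial_id) not in phases:
            log.warning("extract: trial %r has no phase annotation; skipped", trial_id)
            continue
        fixations = [
            Fixation(
                onset_ms=row.onset_ms,
                offset_ms=row.offset_ms,
                centroid=(np.nan, np.nan),
                dispersion_deg=np.nan,
                location=None if pd.isna(row.location) else row.location,
                tracking=row.event_type == "tracking",
                trial_id=str(trial_id),
            )
            for row in g.itertuples()
        ]
        qe.extend(extract_qe_periods(fixations, phases[str(trial_id)]))
    qio.write_event_table(qe, out / "qe.csv")
    log.info("extract: %d QE periods", len(qe))


def _qe_frame(out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    qe = qio.read_event_table(out / "qe.csv")
    trials = pd.read_csv(out / "trials.csv")
    return qe.merge(trials, on="trial_id", how="left"), trials


def stage_summarize(config: PipelineConfig) -> None:
    out = _out(config)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    qe, trials = _qe_frame(out)
    events = qio.read_event_table(out / "events.csv")
    n_fix = int(events["event_type"].isin(["fixation", "tracking"]).sum())
    qe["location2"] = np.where(qe["location"] == "hoop_centre", "hoop_centre", "non_centre")

    acc = accuracy_table(accuracy_from_trials(trials))
    acc.to_csv(tables / "accuracy.csv")
    share = phase_share(qe, n_fixations=n_fix)
    share.table.assign(
        total_qe=share.total_qe,
        qe_share_of_fixations_pct=share.qe_share_of_fixations_pct,
    ).to_csv(tables / "phase_share.csv", index=False)
    qe_frequency(qe, trials).to_csv(tables / "qe_frequency.csv")
    timing_summary(qe).to_csv(tables / "timing_summary.csv", index=False)
    location_probability(qe).to_csv(tables / "location_probability.csv", index=False)

    recordings = qio.read_gaze_recordings(out / "gaze.csv")
    phases = qio.read_phase_annotations(out / "phases.csv")
    report = qio.validate_dataset(recordings, phases)
    (tables / "dataset_report.json").write_text(
        json.dumps(
            {
                "n_trials": report.n_trials,
                "n_hits": report.n_hits,
                "n_misses": report.n_misses,
                "n_undefended": report.n_undefended,
                "n_defended": report.n_defended,
                "problems": report.problems,
            },
            indent=1,
        )
    )
    for problem in report.problems:
        log.warning("dataset: %s", problem)
    log.info("summarize: tables -> %s", tables)


def stage_stats(config: PipelineConfig) -> None:
    out = _out(config)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    qe, trials = _qe_frame(out)

    shot = qe[qe["phase"].isin(FINAL_THREE + ("arm_preparation",))]
    counts = [int((shot["phase"] == ph).sum()) for ph in
              ("arm_preparation",) + FINAL_THREE]
    chis = chisq_gof(counts)
    (stats_dir / "chisq_phase_share.json").write_text(
        json.dumps(
            {
                "counts": dict(zip(("arm_preparation",) + FINAL_THREE, counts)),
                "hypothesis": "equal 25% per shooting phase",
                "statistic": chis.statistic,
                "df": chis.df,
                "p_value": chis.p_value,
            },
            indent=1,
        )
    )

    flex = qe[(qe["phase"] == "arm_flexion")].dropna(subset=["duration_ms"])
    contrasts = {
        "condition_on_flexion_qe_duration": ("condition", flex),
        "outcome_on_flexion_qe_duration": ("outcome", flex),
    }
    for name, (label, frame) in contrasts.items():
        if frame[label].nunique() != 2:
            log.warning("stats: contrast %s skipped (needs 2 groups)", name)
            continue
        res = permutation_contrast(
            frame["duration_ms"].to_numpy(),
            frame[label].to_numpy(),
            strata=frame["participant"].to_numpy(),
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        (stats_dir / f"permutation_{name}.json").write_text(
            json.dumps(
                {
                    "contrast": name,
                    "observed_difference_ms": res.observed_difference,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "seed": res.seed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "n_used": res.n_used,
                },
                indent=1,
            )
        )
    log.info("stats: results -> %s", stats_dir)


def run(config: PipelineConfig) -> Path:
    """Run the requested stages in canonical order; returns the output dir."""
    out = _out(config)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        for stage in STAGES:
            if stage not in config.steps:
                continue
            log.info("stage %s starting", stage)
            try:
                globals()[f"stage_{stage}"](config)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
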