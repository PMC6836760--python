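"""Tabular readers/writers and dataset validation.

All files are plain CSV (comma-separated, UTF-8, ``.`` decimal, header
required), chosen for deterministic cross-language exchange:

* gaze CSV:   trial_id, participant, condition, outcome, t_ms, x_deg, y_deg,
  valid  (+ optional ball_x_deg, ball_y_deg, target_visible)
* phase CSV:  trial_id, pass_onset_ms, arm_preparation_onset_ms,
  arm_flexion_onset_ms, arm_extension_onset_ms, ball_release_ms
  (+ optional occlusion_onset_ms, occlusion_offset_ms)
* event CSV:  trial_id, event_type, onset_ms, offset_ms, duration_ms,
  onset_pct, offset_pct, duration_pct, location, phase

Phase annotations on an absolute clock are re-based by subtracting the
pass-onset column, so every trial's clock starts at the pass release.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    ConfigurationError,
    DataError,
    GazeRecording,
    MotorPhaseSet,
    OUTCOMES,
)
from .events import Fixation, Saccade
from .quiet_eye import QEPeriod

GAZE_COLUMNS = (
    "trial_id",
    "participant",
    "condition",
    "outcome",
    "t_ms",
    "x_deg",
    "y_deg",
    "valid",
)
OPTIONAL_GAZE_COLUMNS = ("ball_x_deg", "ball_y_deg", "target_visible")

PHASE_COLUMNS = (
    "trial_id",
    "pass_onset_ms",
    "arm_preparation_onset_ms",
    "arm_flexion_onset_ms",
    "arm_extension_onset_ms",
    "ball_release_ms",
)

EVENT_COLUMNS = (
    "trial_id",
    "event_type",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "onset_pct",
    "offset_pct",
    "duration_pct",
    "location",
    "phase",
)

_TRUTHY = {"true", "1", "t", "yes"}
_FALSY = {"false", "0", "f", "no"}


def _parse_bool(series: pd.Series, column: str) -> np.ndarray:
    if series.dtype == bool:
        return series.to_numpy()
    def one(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise DataError(f"column {column!r}: cannot parse boolean value {v!r}")
    return np.array([one(v) for v in series], dtype=bool)


def read_gaze_recordings(
    path,
    format_config: Optional[Mapping[str, str]] = None,
) -> list[GazeRecording]:
    """Read one :class:`GazeRecording` per trial from a gaze CSV.

    ``format_config`` maps the canonical column names to the file's own
    (e.g. ``{"t_ms": "timestamp"}``); unmapped names are looked up as-is.
    Gaze must already be in degrees of visual angle in the scene frame —
    pixel-to-degree conversion is the caller's job.  Rows whose coordinates
    cannot back a valid sample are kept with ``valid=False`` and reported
    via a warning, never silently dropped.
    """
    colmap = {name: name for name in GAZE_COLUMNS + OPTIONAL_GAZE_COLUMNS}
    if format_config:
        colmap.update(format_config)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [colmap[c] for c in GAZE_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise ConfigurationError(f"gaze CSV {path} missing required column(s): {missing}")
    sampling = _infer_sampling_rate(df, colmap)
    recordings = []
    for trial_id, g in df.groupby(colmap["trial_id"], sort=False):
        g = g.sort_values(colmap["t_ms"], kind="stable")
        t = g[colmap["t_ms"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(
                f"trial {trial_id!r}: duplicated or non-monotone timestamps"
            )
        x = g[colmap["x_deg"]].to_numpy(dtype=float)
        y = g[colmap["y_deg"]].to_numpy(dtype=float)
        valid = _parse_bool(g[colmap["valid"]], colmap["valid"])
        bad = valid & ~(np.isfinite(x) & np.isfinite(y))
        if bad.any():
            warnings.warn(
                f"trial {trial_id!r}: {int(bad.sum())} row(s) marked valid with "
                "non-finite coordinates; re-flagged invalid"
            )
            valid = valid & ~bad
        meta = {
            k: str(g[colmap[k]].iloc[0]) for k in ("participant", "condition", "outcome")
        }
        extras = {}
        for name in ("ball_x_deg", "ball_y_deg"):
            if colmap[name] in g.columns:
                extras[name] = g[colmap[name]].to_numpy(dtype=float)
        if colmap["target_visible"] in g.columns:
            extras["target_visible"] = _parse_bool(
                g[colmap["target_visible"]], colmap["target_visible"]
            )
        recordings.append(
            GazeRecording(
                trial_id=str(trial_id),
                sampling_rate_hz=sampling,
                t_ms=t,
                x_deg=x,
                y_deg=y,
                valid=valid,
                **meta,
                **extras,
            )
        )
    return recordings


def _infer_sampling_rate(df: pd.DataFrame, colmap: Mapping[str, str]) -> float:
    t = df[colmap["t_ms"]]
    by_trial = df.groupby(colmap["trial_id"], sort=False)[colmap["t_ms"]]
    gaps = by_trial.apply(lambda s: np.median(np.diff(np.sort(s.to_numpy(dtype=float)))))
    gap = float(np.median(gaps.dropna())) if len(gaps.dropna()) else float("nan")
    if not math.isfinite(gap) or gap <= 0:
        raise DataError("cannot infer sampling rate from timestamps")
    return 1000.0 / gap


def write_gaze_recordings(recordings: Sequence[GazeRecording], path) -> None:
    frames = []
    for r in recordings:
        d = {
            "trial_id": r.trial_id,
            "participant": r.participant,
            "condition": r.condition,
            "outcome": r.outcome,
            "t_ms": r.t_ms,
            "x_deg": r.x_deg,
            "y_deg": r.y_deg,
            "valid": r.valid,
        }
        if r.ball_x_deg is not None:
            d["ball_x_deg"] = r.ball_x_deg
            d["ball_y_deg"] = r.ball_y_deg
        if r.target_visible is not None:
            d["target_visible"] = r.target_visible
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_phase_annotations(path) -> dict[str, MotorPhaseSet]:
    """Read per-trial motor-phase onsets; returns trial_id -> MotorPhaseSet.

    Annotations on an absolute clock are shifted so the pass onset is 0.
    Out-of-order onsets raise a :class:`DataError` naming the trial.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PHASE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"phase CSV {path} missing column(s): {missing}")
    out: dict[str, MotorPhaseSet] = {}
    for _, row in df.iterrows():
        trial_id = str(row["trial_id"])
        shift = float(row["pass_onset_ms"])
        occ_on = row.get("occlusion_onset_ms", np.nan)
        occ_off = row.get("occlusion_offset_ms", np.nan)
        out[trial_id] = MotorPhaseSet(
            arm_preparation_onset_ms=float(row["arm_preparation_onset_ms"]) - shift,
            arm_flexion_onset_ms=float(row["arm_flexion_onset_ms"]) - shift,
            arm_extension_onset_ms=float(row["arm_extension_onset_ms"]) - shift,
            ball_release_ms=float(row["ball_release_ms"]) - shift,
            occlusion_onset_ms=None if pd.isna(occ_on) else float(occ_on) - shift,
            occlusion_offset_ms=None if pd.isna(occ_off) else float(occ_off) - shift,
            trial_id=trial_id,
        )
    return out


def write_phase_annotations(phases: Mapping[str, MotorPhaseSet], path) -> None:
    rows = []
    for trial_id, p in phases.items():
        rows.append(
            {
                "trial_id": trial_id,
                "pass_onset_ms": p.pass_onset_ms,
                "arm_preparation_onset_ms": p.arm_preparation_onset_ms,
                "arm_flexion_onset_ms": p.arm_flexion_onset_ms,
                "arm_extension_onset_ms": p.arm_extension_onset_ms,
                "ball_release_ms": p.ball_release_ms,
                "occlusion_onset_ms": p.occlusion_onset_ms,
                "occlusion_offset_ms": p.occlusion_offset_ms,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


@dataclass
class DatasetReport:
    """Structural health report of a gaze + annotation dataset."""

    n_trials: int
    n_hits: int
    n_misses: int
    n_undefended: int
    n_defended: int
    per_participant_balance: pd.DataFrame
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_dataset(
    recordings: Sequence[GazeRecording],
    phases: Optional[Mapping[str, MotorPhaseSet]] = None,
) -> DatasetReport:
    """Count trials by outcome/condition/participant and list imbalances.

    The balanced design requires equal numbers of hits and misses per
    participant per condition; deviations, and any gaze/annotation join
    mismatches, are listed in ``problems`` (report-only, never fatal).
    """
    meta = pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in recordings],
            "participant": [r.participant for r in recordings],
            "condition": [r.condition for r in recordings],
            "outcome": [r.outcome for r in recordings],
        }
    )
    problems: list[str] = []
    if meta.empty:
        balance = pd.DataFrame(columns=["participant", "condition", "hit", "miss"])
        return DatasetReport(0, 0, 0, 0, 0, balance, ["dataset is empty"])
    counts = (
        meta.groupby(["participant", "condition", "outcome"])
        .size()
        .unstack("outcome", fill_value=0)
        .reindex(columns=list(OUTCOMES), fill_value=0)
        .reset_index()
        .sort_values(["participant", "condition"])
        .reset_index(drop=True)
    )
    for _, row in counts.iterrows():
        if row["hit"] != row["miss"]:
            problems.append(
                f"participant {row['participant']!r}, {row['condition']}: "
                f"{row['hit']} hits vs {row['miss']} misses (unbalanced cell)"
            )
    if phases is not None:
        gaze_ids = set(meta["trial_id"])
        anno_ids = set(map(str, phases))
        for tid in sorted(gaze_ids - anno_ids):
            problems.append(f"trial {tid!r}: gaze present but phase annotation missing")
        for tid in sorted(anno_ids - gaze_ids):
            problems.append(f"trial {tid!r}: phase annotation present but gaze missing")
    return DatasetReport(
        n_trials=len(meta),
        n_hits=int((meta["outcome"] == "hit").sum()),
        n_misses=int((meta["outcome"] == "miss").sum()),
        n_undefended=int((meta["condition"] == "undefended").sum()),
        n_defended=int((meta["condition"] == "defended").sum()),
        per_participant_balance=counts,
        problems=problems,
    )


Event = Union[Fixation, Saccade, QEPeriod]


def events_to_frame(events: Sequence[Event]) -> pd.DataFrame:
    rows = []
    for e in events:
        if isinstance(e, QEPeriod):
            rows.append(
                {
                    "trial_id": e.trial_id,
                    "event_type": "qe",
                    "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "duration_ms": e.duration_ms,
                    "onset_pct": e.onset_pct,
                    "offset_pct": e.offset_pct,
                    "duration_pct": e.duration_pct,
                    "location": e.location,
                    "phase": e.phase,
                }
            )
        elif isinstance(e, Fixation):
            rows.append(
                {
                    "trial_id": e.trial_id,
                    "event_type": "tracking" if e.tracking else "fixation",
                    "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "duration_ms": e.duration_ms,
                    "onset_pct": np.nan,
                    "offset_pct": np.nan,
                    "duration_pct": np.nan,
                    "location": e.location,
                    "phase": "",
                }
            )
        elif isinstance(e, Saccade):
            rows.append(
                {
                    "trial_id": e.trial_id,
                    "event_type": "saccade",
                    "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "duration_ms": e.duration_ms,
                    "onset_pct": np.nan,
                    "offset_pct": np.nan,
                    "duration_pct": np.nan,
                    "location": "",
                    "phase": "",
                }
            )
        else:  # pragma: no cover - guarded by type hints
            raise TypeError(f"unsupported event type {type(e).__name__}")
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def write_event_table(events: Sequence[Event], path) -> None:
    """Write a homogeneous list of events (or QE periods) as an event CSV."""
    kinds = {type(e) for e in events}
    if len(kinds) > 1 and kinds != {Fixation, Saccade}:
        raise ValueError("event list must be homogeneous (fixations/saccades or QE)")
    events_to_frame(events).to_csv(path, index=False, float_format="%.17g")


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"event CSV {path} missing column(s): {missing}")
    return df
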