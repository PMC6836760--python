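"""Extraction of the five phase-relative quiet-eye (QE) periods.

The QE of a motor phase is the *final* fixation (or tracking gaze) whose
onset strictly precedes the phase's reference time; its offset is where the
gaze deviates off the location beyond the dispersion threshold for at least
100 ms, which is exactly the fixation offset produced by event detection.
A fixation that is the final one for several consecutive phases would be
reported once per phase; such duplicates are removed, keeping only the
earliest phase, which is the one the fixation most immediately guides.

Reference times, per trial clock (0 = pass release):

==================  ==============================================
QE period           reference
==================  ==============================================
catch               arm-preparation onset (the annotated catch boundary)
arm_preparation     arm-preparation onset
arm_flexion         arm-flexion onset
arm_extension       arm-extension onset
ball_release        ball release; the fixation must additionally
                    onset during arm extension
==================  ==============================================

Because the catch is only annotated through the pass/arm-preparation
boundary, the catch and arm-preparation references coincide and the
arm-preparation QE is always removed as a duplicate of the catch QE —
consistent with the observed absence of arm-preparation QEs, which a
saccade to the target makes empirically inevitable anyway.

Offsets are never clipped to phase boundaries: a QE that outlives its phase
keeps its natural offset, and an occlusion offset may exceed 100% of trial
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DataError, MotorPhaseSet, PHASES, TIME_EPS_MS
from .events import Fixation


@dataclass
class QEPeriod:
    phase: str
    onset_ms: float
    offset_ms: float
    duration_ms: float
    onset_pct: float
    offset_pct: float
    duration_pct: float
    location: Optional[str]
    location2: str
    trial_id: Optional[str] = None


@dataclass
class OcclusionPeriod:
    onset_ms: float
    offset_ms: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def to_relative(value_ms: float, phases: MotorPhaseSet) -> float:
    """Express a trial time as percent of total trial time (not clamped)."""
    if phases.trial_duration_ms <= 0:
        raise ValueError("trial duration must be positive")
    return 100.0 * value_ms / phases.trial_duration_ms


def extract_qe_periods(
    fixations: Sequence[Fixation],
    phases: MotorPhaseSet,
) -> list[QEPeriod]:
    """Extract the 0-5 quiet-eye periods of one trial.

    ``fixations`` must be time-ordered and (optionally) location-labeled.
    Phases without a qualifying fixation yield no entry.
    """
    fixations = sorted(fixations, key=lambda f: f.onset_ms)
    onsets = [f.onset_ms for f in fixations]
    if len(set(onsets)) != len(onsets):
        raise DataError(
            f"trial {phases.trial_id!r}: fixations with identical onsets "
            "violate the event-partition invariant"
        )
    refs = phases.reference_times()
    used: set[int] = set()
    out: list[QEPeriod] = []
    for phase in PHASES:
        ref = refs[phase]
        candidates = [f for f in fixations if f.onset_ms < ref - TIME_EPS_MS]
        if phase == "ball_release":
            candidates = [
                f
                for f in candidates
                if f.onset_ms >= phases.arm_extension_onset_ms - TIME_EPS_MS
            ]
        if not candidates:
            continue
        fix = candidates[-1]
        if id(fix) in used:
            continue  # duplicate of an earlier QE period; keep the first
        used.add(id(fix))
        out.append(
            QEPeriod(
                phase=phase,
                onset_ms=fix.onset_ms,
                offset_ms=fix.offset_ms,
                duration_ms=fix.offset_ms - fix.onset_ms,
                onset_pct=to_relative(fix.onset_ms, phases),
                offset_pct=to_relative(fix.offset_ms, phases),
                duration_pct=to_relative(fix.offset_ms - fix.onset_ms, phases),
                location=fix.location,
                location2="hoop_centre" if fix.location == "hoop_centre" else "non_centre",
                trial_id=fix.trial_id,
            )
        )
    return out


def compute_occlusion(
    phases: MotorPhaseSet,
    visibility: Optional[np.ndarray] = None,
    t_ms: Optional[np.ndarray] = None,
) -> Optional[OcclusionPeriod]:
    """The trial's occlusion period (target hidden by the rising ball/arms).

    With a per-sample ``visibility`` channel (and its timestamps), invisible
    runs are located directly; the occlusion offset of a run that reaches
    the end of the recording is the last invisible timestamp plus nothing —
    annotation should be preferred when occlusion outlives the recording.
    Otherwise the annotated onset/offset on ``phases`` is used.  Fully
    visible trials return ``None``.  When several disjoint invisible runs
    exist, the one overlapping arm extension is kept, with a warning.
    """
    if visibility is not None:
        if t_ms is None:
            raise ValueError("t_ms is required alongside a visibility channel")
        visibility = np.asarray(visibility, dtype=bool)
        t_ms = np.asarray(t_ms, dtype=float)
        hidden = ~visibility
        if not hidden.any():
            return None
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hidden.astype(int), [0]])))
        runs = [(t_ms[a], t_ms[b - 1]) for a, b in zip(edges[::2], edges[1::2])]
        if len(runs) > 1:
            warnings.warn(
                f"trial {phases.trial_id!r}: {len(runs)} disjoint occlusion "
                "intervals; keeping the one overlapping arm extension"
            )
            ext = (phases.arm_extension_onset_ms, phases.ball_release_ms)
            overlapping = [r for r in runs if r[1] >= ext[0] and r[0] <= ext[1]]
            runs = overlapping or [max(runs, key=lambda r: r[1] - r[0])]
        onset, last = runs[0]
        return OcclusionPeriod(onset_ms=float(onset), offset_ms=float(last))
    if phases.occlusion_onset_ms is None:
        return None
    return OcclusionPeriod(
        onset_ms=phases.occlusion_onset_ms, offset_ms=phases.occlusion_offset_ms
    )
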