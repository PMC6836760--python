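"""Fixation and saccade detection from 30 Hz gaze streams.

Detection is dispersion-based (I-DT family) with a *disc* criterion: a
fixation is a maximal run of samples that all stay within the dispersion
threshold of the running centroid of the accepted samples.  Two tolerances
soften the run:

* a spatial excursion off the location that returns within the threshold in
  under ``min_deviation_ms`` does not terminate the fixation (the excursion
  samples are bridged over and excluded from the centroid);
* invalid (blink/track-loss) stretches up to ``max_gap_ms`` are bridged.

Event timestamps use a half-open convention: onset is the time of the first
included sample and offset is the time of the last included sample plus one
sample period, so a three-frame dwell at 30 Hz lasts exactly 100 ms.

Smooth pursuit of the incoming ball is handled by running the same detector
on gaze coordinates *relative to the ball's position*; a pursuit run then
registers as a tracking fixation on the ball, matching the treatment of a
tracking gaze as a fixation-equivalent event.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import GazeRecording, TIME_EPS_MS
from .geometry import SceneLayout, assign_aoi


@dataclass
class DetectionParams:
    """Thresholds for dispersion-based event detection.

    dispersion_threshold_deg
        Maximum distance of any sample from the fixation centroid (the gaze
        cursor radius criterion), default 1.25 degrees.
    min_fixation_ms
        Minimum fixation duration, default 100 ms (3 frames at 30 Hz).
    min_deviation_ms
        A deviation off the location shorter than this that returns within
        threshold does not end the fixation, default 100 ms.
    max_gap_ms
        Longest invalid (blink) stretch bridged inside an event, default 100 ms.
    """

    dispersion_threshold_deg: float = 1.25
    min_fixation_ms: float = 100.0
    min_deviation_ms: float = 100.0
    max_gap_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "dispersion_threshold_deg",
            "min_fixation_ms",
            "min_deviation_ms",
            "max_gap_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Fixation:
    onset_ms: float
    offset_ms: float
    centroid: tuple[float, float]
    dispersion_deg: float
    location: Optional[str] = None
    tracking: bool = False
    trial_id: Optional[str] = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Saccade:
    onset_ms: float
    offset_ms: float
    start: tuple[float, float]
    end: tuple[float, float]
    trial_id: Optional[str] = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def _idt_runs(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    params: DetectionParams,
    period_ms: float,
) -> list[tuple[list[int], tuple[float, float], float]]:
    """Greedy left-to-right grouping of samples into qualifying fixation runs.

    Returns, per fixation, the accepted sample indices, the final centroid
    and the dispersion (max accepted-sample distance from that centroid).
    """
    thr = params.dispersion_threshold_deg
    n = t.shape[0]
    runs: list[tuple[list[int], tuple[float, float], float]] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        accepted = [i]
        sx, sy = x[i], y[i]
        cx, cy = sx, sy
        last = i
        k = i + 1
        while k < n:
            if not valid[k]:
                j = k
                while j < n and not valid[j]:
                    j += 1
                if j < n and t[j] - t[last] <= params.max_gap_ms + TIME_EPS_MS:
                    k = j
                    continue
                break
            d = math.hypot(x[k] - cx, y[k] - cy)
            if d <= thr:
                accepted.append(k)
                sx += x[k]
                sy += y[k]
                cx, cy = sx / len(accepted), sy / len(accepted)
                last = k
                k += 1
                continue
            # Deviation episode beginning at sample k: bridge it if the gaze
            # returns within threshold of the (frozen) centroid in under
            # min_deviation_ms, otherwise the fixation ends at `last`.
            ret = None
            m = k + 1
            while m < n and t[m] - t[k] < params.min_deviation_ms - TIME_EPS_MS:
                if valid[m] and math.hypot(x[m] - cx, y[m] - cy) <= thr:
                    ret = m
                    break
                m += 1
            if ret is None:
                break
            accepted.append(ret)
            sx += x[ret]
            sy += y[ret]
            cx, cy = sx / len(accepted), sy / len(accepted)
            last = ret
            k = ret + 1
        duration = t[last] + period_ms - t[accepted[0]]
        if duration >= params.min_fixation_ms - TIME_EPS_MS:
            disp = max(
                math.hypot(x[j] - cx, y[j] - cy) for j in accepted
            )
            runs.append((accepted, (cx, cy), disp))
            i = last + 1
        else:
            i = accepted[0] + 1
    return runs


def detect_fixations(
    recording: GazeRecording,
    params: Optional[DetectionParams] = None,
    *,
    relative_to: Optional[np.ndarray] = None,
) -> list[Fixation]:
    """Detect fixations in a gaze stream.

    With ``relative_to`` (an (n, 2) array of reference positions, NaN where
    undefined) the dispersion criterion is applied to gaze minus reference,
    restricted to the samples where the reference is defined; the resulting
    events are *tracking* fixations whose reported centroid is still the mean
    absolute gaze position.
    """
    params = params or DetectionParams()
    t, x, y = recording.t_ms, recording.x_deg, recording.y_deg
    valid = recording.valid.copy()
    tracking = relative_to is not None
    if tracking:
        ref = np.asarray(relative_to, dtype=float)
        defined = np.isfinite(ref).all(axis=1)
        valid &= defined
        rx = np.where(defined, x - ref[:, 0], np.nan)
        ry = np.where(defined, y - ref[:, 1], np.nan)
        runs = _idt_runs(t, rx, ry, valid, params, recording.period_ms)
    else:
        runs = _idt_runs(t, x, y, valid, params, recording.period_ms)
    if valid.sum() < 3:
        warnings.warn(
            f"trial {recording.trial_id!r}: fewer than 3 valid samples; "
            "no events detected"
        )
        return []
    out = []
    for accepted, centroid, disp in runs:
        idx = np.asarray(accepted)
        abs_centroid = (float(x[idx].mean()), float(y[idx].mean()))
        out.append(
            Fixation(
                onset_ms=float(t[accepted[0]]),
                offset_ms=float(t[accepted[-1]] + recording.period_ms),
                centroid=abs_centroid if tracking else (float(centroid[0]), float(centroid[1])),
                dispersion_deg=float(disp),
                tracking=tracking,
                location="ball" if tracking else None,
                trial_id=recording.trial_id,
            )
        )
    return out


def detect_saccades(
    recording: GazeRecording,
    fixations: Sequence[Fixation],
    params: Optional[DetectionParams] = None,
) -> list[Saccade]:
    """Saccades between consecutive fixations.

    An inter-fixation interval is a saccade when it spans at least two
    samples and the gaze ends up farther than the dispersion threshold from
    where it started (centroid-to-centroid displacement).
    """
    params = params or DetectionParams()
    period = recording.period_ms
    out: list[Saccade] = []
    fixations = sorted(fixations, key=lambda f: f.onset_ms)
    for prev, nxt in zip(fixations, fixations[1:]):
        gap = nxt.onset_ms - prev.offset_ms
        if gap < 2.0 * period - TIME_EPS_MS:
            continue
        disp = math.hypot(
            nxt.centroid[0] - prev.centroid[0], nxt.centroid[1] - prev.centroid[1]
        )
        if disp <= params.dispersion_threshold_deg:
            continue
        out.append(
            Saccade(
                onset_ms=prev.offset_ms,
                offset_ms=nxt.onset_ms,
                start=prev.centroid,
                end=nxt.centroid,
                trial_id=recording.trial_id,
            )
        )
    return out


def label_event_locations(
    fixations: Sequence[Fixation],
    layout: SceneLayout,
    dynamic_positions: Optional[Mapping[str, tuple[float, float]]] = None,
) -> list[Fixation]:
    """Fill each fixation's AOI label via the cursor-majority rule.

    Tracking fixations keep their ``ball`` label (the pursuit criterion
    already places them within a cursor radius of the ball's path).
    """
    for f in fixations:
        if f.tracking:
            f.location = "ball"
        else:
            f.location = assign_aoi(f.centroid, layout, dynamic_positions)
    return list(fixations)


def classify_trial(
    recording: GazeRecording,
    params: Optional[DetectionParams] = None,
    layout: Optional[SceneLayout] = None,
) -> tuple[list[Fixation], list[Saccade]]:
    """Full per-trial event classification.

    If the recording carries ball-position channels, pursuit (tracking)
    fixations are detected first in ball-relative coordinates; scene-frame
    fixations are then detected on the remaining stretches of the stream,
    and saccades are filled in between events.  With a layout, fixation
    locations are labeled.
    """
    params = params or DetectionParams()
    fixations: list[Fixation] = []
    if recording.ball_x_deg is not None and recording.ball_y_deg is not None:
        ref = np.column_stack([recording.ball_x_deg, recording.ball_y_deg])
        fixations.extend(detect_fixations(recording, params, relative_to=ref))
    # Scene-frame detection outside the intervals already claimed by pursuit.
    covered = np.zeros(recording.n_samples, dtype=bool)
    for f in fixations:
        covered |= (recording.t_ms >= f.onset_ms - TIME_EPS_MS) & (
            recording.t_ms < f.offset_ms - TIME_EPS_MS
        )
    free = recording.valid & ~covered
    rec_free = GazeRecording(
        trial_id=recording.trial_id,
        participant=recording.participant,
        condition=recording.condition,
        outcome=recording.outcome,
        sampling_rate_hz=recording.sampling_rate_hz,
        t_ms=recording.t_ms,
        x_deg=recording.x_deg,
        y_deg=recording.y_deg,
        valid=free,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixations.extend(detect_fixations(rec_free, params))
    fixations.sort(key=lambda f: f.onset_ms)
    if layout is not None:
        label_event_locations(fixations, layout)
    saccades = detect_saccades(recording, fixations, params)
    return fixations, saccades
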