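"""Core containers and vocabulary shared by every pipeline stage.

Conventions used throughout the package:

* time is milliseconds on a per-trial clock whose zero is the moment the
  pass is released; the trial ends (100% of relative time) at ball release;
* gaze direction is expressed in degrees of visual angle in a scene-fixed,
  target-centred frame (the hoop centre sits at the origin);
* invalid samples (blinks, track loss) are kept in the stream with
  ``valid=False`` so that event detection can apply an explicit gap policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

CONDITIONS = ("undefended", "defended")
OUTCOMES = ("hit", "miss")

#: The seven coded scene locations.
REGIONS = (
    "passer",
    "ball",
    "hoop_centre",
    "hoop_left",
    "hoop_right",
    "net",
    "backboard",
)

#: Biomechanical phases of the catch-and-shoot action, in trial order.
PHASES = ("catch", "arm_preparation", "arm_flexion", "arm_extension", "ball_release")

#: The shooting phases proper (everything after the ball is in hand).
FINAL_THREE = ("arm_flexion", "arm_extension", "ball_release")

#: Numerical slop used when comparing times that live on a sample grid.
TIME_EPS_MS = 1e-6


class ConfigurationError(ValueError):
    """A reader or builder was given an unusable configuration."""


class DataError(ValueError):
    """Input data violate a structural invariant (the message names the culprit)."""


@dataclass(frozen=True)
class GazeSample:
    """A single time-stamped gaze-direction measurement."""

    t_ms: float
    x_deg: float
    y_deg: float
    valid: bool = True


@dataclass
class GazeRecording:
    """One trial's gaze stream plus its design metadata.

    Samples are stored as parallel numpy arrays; :meth:`samples` yields
    :class:`GazeSample` views for callers that prefer records.  The optional
    ``ball_*`` channels carry the per-sample angular position of the ball
    while it is in flight (NaN once caught); ``target_visible`` flags the
    occlusion window.
    """

    trial_id: str
    participant: str
    condition: str
    outcome: str
    sampling_rate_hz: float
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    ball_x_deg: Optional[np.ndarray] = None
    ball_y_deg: Optional[np.ndarray] = None
    target_visible: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DataError(
                f"trial {self.trial_id!r}: condition {self.condition!r} "
                f"not one of {CONDITIONS}"
            )
        if self.outcome not in OUTCOMES:
            raise DataError(
                f"trial {self.trial_id!r}: outcome {self.outcome!r} "
                f"not one of {OUTCOMES}"
            )
        if self.sampling_rate_hz <= 0:
            raise DataError(f"trial {self.trial_id!r}: non-positive sampling rate")
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.shape[0]
        for name in ("x_deg", "y_deg", "valid"):
            if getattr(self, name).shape[0] != n:
                raise DataError(f"trial {self.trial_id!r}: channel {name} length mismatch")
        for name in ("ball_x_deg", "ball_y_deg", "target_visible"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=bool if name == "target_visible" else float)
                if ch.shape[0] != n:
                    raise DataError(
                        f"trial {self.trial_id!r}: channel {name} length mismatch"
                    )
                setattr(self, name, ch)
        if n and self.t_ms[0] < 0:
            raise DataError(f"trial {self.trial_id!r}: negative timestamps")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise DataError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing "
                "(duplicate or out-of-order samples)"
            )
        bad = self.valid & ~(np.isfinite(self.x_deg) & np.isfinite(self.y_deg))
        if np.any(bad):
            raise DataError(
                f"trial {self.trial_id!r}: {int(bad.sum())} sample(s) flagged valid "
                "but with non-finite gaze coordinates"
            )

    @property
    def period_ms(self) -> float:
        """Nominal inter-sample interval (1000 / sampling rate)."""
        return 1000.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.shape[0])

    def samples(self) -> Iterator[GazeSample]:
        for t, x, y, v in zip(self.t_ms, self.x_deg, self.y_deg, self.valid):
            yield GazeSample(float(t), float(x), float(y), bool(v))


@dataclass
class MotorPhaseSet:
    """Per-trial motor-phase onsets on the trial clock (0 = pass release).

    The pass phase ends when the ball reaches the shooter's hands, which is
    also the onset of arm preparation; that shared boundary is the only
    annotated proxy for the catch.  Trial duration equals the ball-release
    time by definition of relative time.  Optional occlusion bounds record
    when the rising ball/arms hid the target; the occlusion offset may fall
    beyond ball release.
    """

    arm_preparation_onset_ms: float
    arm_flexion_onset_ms: float
    arm_extension_onset_ms: float
    ball_release_ms: float
    pass_onset_ms: float = 0.0
    occlusion_onset_ms: Optional[float] = None
    occlusion_offset_ms: Optional[float] = None
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        who = f"trial {self.trial_id!r}: " if self.trial_id else ""
        if abs(self.pass_onset_ms) > TIME_EPS_MS:
            raise DataError(who + "pass onset must be 0 on the trial clock")
        seq = [
            ("pass", self.pass_onset_ms),
            ("arm_preparation", self.arm_preparation_onset_ms),
            ("arm_flexion", self.arm_flexion_onset_ms),
            ("arm_extension", self.arm_extension_onset_ms),
            ("ball_release", self.ball_release_ms),
        ]
        for (a, ta), (b, tb) in zip(seq, seq[1:]):
            if not tb > ta:
                raise DataError(
                    who + f"phase onsets out of order: {b} ({tb} ms) does not "
                    f"follow {a} ({ta} ms)"
                )
        if (self.occlusion_onset_ms is None) != (self.occlusion_offset_ms is None):
            raise DataError(who + "occlusion onset/offset must be given together")
        if self.occlusion_onset_ms is not None:
            if not self.occlusion_offset_ms > self.occlusion_onset_ms:
                raise DataError(who + "occlusion offset must follow occlusion onset")

    @property
    def trial_duration_ms(self) -> float:
        return self.ball_release_ms

    @property
    def catch_ms(self) -> float:
        """The catch boundary (end of the pass = onset of arm preparation)."""
        return self.arm_preparation_onset_ms

    def phase_duration_ms(self, phase: str) -> float:
        durations = {
            "pass": self.arm_preparation_onset_ms - self.pass_onset_ms,
            "arm_preparation": self.arm_flexion_onset_ms - self.arm_preparation_onset_ms,
            "arm_flexion": self.arm_extension_onset_ms - self.arm_flexion_onset_ms,
            "arm_extension": self.ball_release_ms - self.arm_extension_onset_ms,
        }
        return durations[phase]

    def reference_times(self) -> dict[str, float]:
        """Reference time of each quiet-eye period, in chronological order.

        The QE of a phase is the final fixation whose onset precedes this
        reference.  The catch and arm-preparation references coincide because
        the catch is only annotated through the pass/arm-preparation boundary.
        """
        return {
            "catch": self.catch_ms,
            "arm_preparation": self.arm_preparation_onset_ms,
            "arm_flexion": self.arm_flexion_onset_ms,
            "arm_extension": self.arm_extension_onset_ms,
            "ball_release": self.ball_release_ms,
        }
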