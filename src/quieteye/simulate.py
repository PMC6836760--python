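"""Synthetic catch-and-shoot gaze trials with scripted ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without any recorded data:

* a motor timeline pass -> arm preparation -> arm flexion -> arm extension
  -> ball release, with per-condition duration distributions whose defaults
  are the study-scale means/SDs of a defended vs undefended one-time shot;
* a scanpath script per trial: smooth pursuit of the incoming ball that is
  abandoned ~100 ms before the catch, a saccade to the target, one
  quiet-eye fixation on a scripted scene location ahead of a scripted motor
  phase (flexion / extension / ball release per a mixture), and fast
  "glide" gaze travel everywhere in between, built so that no unscripted
  sample run can satisfy the fixation criterion;
* an occlusion window (target hidden by the rising ball/arms) recorded as a
  visibility channel and as annotation;
* 30 Hz sampling with additive isotropic Gaussian angular noise;
* a balanced design: an equal number of hits and misses per participant per
  condition.

Everything scripted is returned as :class:`GroundTruth`, which detection
and extraction are expected to recover exactly (up to one sample period)
at zero noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import GazeRecording, MotorPhaseSet

MOTOR_PHASES = ("pass", "arm_preparation", "arm_flexion", "arm_extension")
SHOT_PHASES = ("arm_flexion", "arm_extension", "ball_release")


def _cond(u, d):
    return {"undefended": u, "defended": d}


@dataclass
class SimulationConfig:
    """All knobs of the trial generator.

    Durations and leads are (mean, sd) of normal distributions in ms,
    truncated where noted.  Defaults reproduce the study conditions of an
    elite one-time three-point shot: 30 Hz sampling, defended trials with
    compressed motor phases and quiet-eye durations, ball tracking released
    ~109 ms (undefended) / ~89 ms (defended) before the catch, and a
    shot-phase QE mixture dominated by arm flexion.
    """

    n_participants: int = 12
    trials_per_cell: int = 10  # hits and misses each, per condition
    sampling_rate_hz: float = 30.0
    noise_sd_deg: float = 0.15
    seed: int = 0

    # Motor timeline -------------------------------------------------------
    phase_durations_ms: dict = field(
        default_factory=lambda: {
            "undefended": {
                "pass": (505.81, 43.79),
                "arm_preparation": (361.92, 146.29),
                "arm_flexion": (347.39, 171.84),
                "arm_extension": (148.26, 57.53),
            },
            "defended": {
                "pass": (439.61, 47.07),
                "arm_preparation": (322.15, 104.48),
                "arm_flexion": (313.17, 143.15),
                "arm_extension": (149.16, 65.41),
            },
        }
    )
    #: Truncation floor for motor-phase durations; 100 ms keeps every phase
    #: at least as long as a 3-frame fixation and the timeline physical.
    phase_floor_ms: float = 100.0
    #: Between-participant SD applied to the phase-duration means (random
    #: effect); 0 disables it.
    participant_sd_ms: float = 0.0

    # Scanpath script ------------------------------------------------------
    track_start_ms: tuple = (30.0, 10.0)
    #: How long before the catch pursuit is abandoned.
    track_offset_lead_ms: dict = field(
        default_factory=lambda: _cond((109.0, 20.0), (89.0, 20.0))
    )
    saccade_duration_ms: dict = field(
        default_factory=lambda: _cond((195.66, 25.0), (231.28, 25.0))
    )
    #: Probability that a trial contains a ball-tracking (QE catch) gaze.
    catch_qe_prob: float = 412.0 / 430.0
    #: Which shot phase the trial's quiet eye precedes.
    qe_phase_mixture: dict = field(
        default_factory=lambda: {
            "arm_flexion": 0.605,
            "arm_extension": 0.310,
            "ball_release": 0.085,
        }
    )
    qe_onset_lead_ms: dict = field(
        default_factory=lambda: {
            "arm_flexion": _cond((161.0, 40.0), (139.0, 40.0)),
            "arm_extension": _cond((312.0, 60.0), (253.0, 60.0)),
            "ball_release": _cond((60.0, 15.0), (60.0, 15.0)),
        }
    )
    qe_duration_ms: dict = field(
        default_factory=lambda: {
            "arm_flexion": _cond((311.10, 110.0), (237.02, 80.0)),
            "arm_extension": _cond((168.58, 50.0), (136.98, 40.0)),
            "ball_release": _cond((150.0, 30.0), (150.0, 30.0)),
        }
    )
    #: QE durations are truncated here (4 frames) so every scripted QE is
    #: detectable at 30 Hz.
    qe_duration_floor_ms: float = 135.0
    #: Probability the shot-phase QE lands on hoop centre, per phase.
    hoop_centre_prob: dict = field(
        default_factory=lambda: {
            "arm_flexion": 0.587,
            "arm_extension": 0.527,
            "ball_release": 0.527,
        }
    )
    #: Added to (hits) / subtracted from (misses) the hoop-centre probability.
    hoop_centre_outcome_shift: float = 0.0
    noncentre_weights: dict = field(
        default_factory=lambda: {
            "net": 0.35,
            "backboard": 0.30,
            "hoop_right": 0.20,
            "hoop_left": 0.15,
        }
    )
    #: Participants scripted P9-style: a flexion QE and a ball-release QE in
    #: every trial (three QE periods counting the catch).
    three_qe_participants: tuple = ()

    # Occlusion ------------------------------------------------------------
    occlusion_lead_ms: dict = field(
        default_factory=lambda: _cond((74.00, 30.0), (1.59, 30.0))
    )  # before arm-extension onset
    occlusion_beyond_release_ms: dict = field(
        default_factory=lambda: _cond((38.87, 40.0), (147.00, 40.0))
    )

    # Scene geometry of the script (target-centred frame, degrees) ---------
    passer_pos: tuple = (-10.0, -6.0)
    catch_pos: tuple = (-1.0, -9.0)
    qe_points: dict = field(
        default_factory=lambda: {
            "hoop_centre": (0.0, 0.0),
            "hoop_left": (-1.2456, 0.0),
            "hoop_right": (1.2456, 0.0),
            "net": (0.0, -2.825),
            "backboard": (0.0, 5.325),
        }
    )
    #: Inter-event gaze travel: circular glide of this radius around the
    #: upcoming (or just-left) fixation point, advancing by this chord per
    #: sample.  Both are large enough that no glide window can satisfy the
    #: 1.25 deg / 100 ms fixation criterion, in the scene frame or relative
    #: to the moving ball.
    glide_radius_deg: float = 3.0
    glide_chord_deg: float = 2.8
    blink_prob: float = 0.0

    def __post_init__(self) -> None:
        mix = sum(self.qe_phase_mixture.values())
        if abs(mix - 1.0) > 1e-6:
            raise ValueError(f"qe_phase_mixture must sum to 1, got {mix}")
        for p in (self.catch_qe_prob, self.blink_prob, *self.hoop_centre_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for cond in ("undefended", "defended"):
            for ph, (m, s) in self.phase_durations_ms[cond].items():
                if s < 0:
                    raise ValueError(f"negative sd for {cond}/{ph}")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def expected_qe_duration_ms(self, phase: str, condition: str) -> float:
        """Mean of the (floored) truncated-normal QE duration the generator
        actually draws from — the quantity recovery tests should target."""
        m, s = self.qe_duration_ms[phase][condition]
        if s == 0:
            return max(m, self.qe_duration_floor_ms)
        a = (self.qe_duration_floor_ms - m) / s
        return float(stats.truncnorm.mean(a, np.inf, loc=m, scale=s))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Everything the script decided for one trial, for recovery tests."""

    trial_id: str
    fixations: list  # dicts: kind, onset_ms, offset_ms, location
    saccades: list  # dicts: onset_ms, offset_ms
    qe: list  # dicts: phase, onset_ms, offset_ms, duration_ms, location, location2
    occlusion: Optional[tuple]  # (onset_ms, offset_ms)
    n_redraws: int = 0


@dataclass
class SimulatedDataset:
    recordings: list
    phases: dict  # trial_id -> MotorPhaseSet
    ground_truth: dict  # trial_id -> GroundTruth
    manifest: dict


def _draw_trunc(rng, mean, sd, low, counter) -> float:
    """Normal draw redrawn (truncated) to stay at or above ``low``."""
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= low:
            return float(v)
        counter[0] += 1
    return float(low)


def _glide_positions(
    n: int,
    centre: tuple[float, float],
    radius: float,
    chord: float,
    angle0: float,
    start: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Gaze travel for ``n`` inter-event samples.

    From ``start`` (if given) the gaze walks straight toward the circle of
    ``radius`` around ``centre`` in steps of ``chord``, then orbits the
    circle advancing ``chord`` per sample.  Without ``start`` it orbits from
    ``angle0``.  Step sizes >= ``chord`` guarantee no fixation can form.
    """
    out = np.empty((n, 2))
    step_angle = 2.0 * math.asin(min(1.0, chord / (2.0 * radius)))
    cx, cy = centre
    i = 0
    if start is not None:
        px, py = start
        while i < n:
            dx, dy = cx - px, cy - py
            dist = math.hypot(dx, dy)
            if dist <= radius + chord:
                break
            px += chord * dx / dist
            py += chord * dy / dist
            out[i] = (px, py)
            i += 1
        if i < n and start is not None:
            # enter the orbit at the angle facing the approach direction
            angle0 = math.atan2(py - cy, px - cx)
            angle0 += step_angle
    for j in range(i, n):
        out[j] = (
            cx + radius * math.cos(angle0),
            cy + radius * math.sin(angle0),
        )
        angle0 += step_angle
    return out


def generate_trial(
    config: SimulationConfig,
    participant: str,
    condition: str,
    outcome: str,
    rng: np.random.Generator,
    trial_id: Optional[str] = None,
    phase_mean_shift_ms: float = 0.0,
) -> tuple[GazeRecording, MotorPhaseSet, GroundTruth]:
    """Generate one trial: gaze recording, phase annotation and ground truth."""
    p = config.period_ms
    trial_id = trial_id or f"{participant}_{condition}_{outcome}"
    redraws = [0]

    # ---- motor timeline ---------------------------------------------------
    durations = {}
    for phase in MOTOR_PHASES:
        m, s = config.phase_durations_ms[condition][phase]
        durations[phase] = _draw_trunc(
            rng, m + phase_mean_shift_ms, s, config.phase_floor_ms, redraws
        )
    catch = durations["pass"]
    prep_on = catch
    flex_on = prep_on + durations["arm_preparation"]
    ext_on = flex_on + durations["arm_flexion"]
    release = ext_on + durations["arm_extension"]

    # ---- occlusion --------------------------------------------------------
    occ_lead = rng.normal(*config.occlusion_lead_ms[condition])
    occ_beyond = rng.normal(*config.occlusion_beyond_release_ms[condition])
    occ_on = ext_on - occ_lead
    occ_off = release + occ_beyond
    if occ_off <= occ_on:
        occ_off = occ_on + 50.0

    # ---- scanpath script --------------------------------------------------
    three_qe = participant in config.three_qe_participants
    has_catch = three_qe or (rng.random() < config.catch_qe_prob)
    track_start = track_end = sacc_end = None
    if has_catch:
        lead = _draw_trunc(rng, *config.track_offset_lead_ms[condition], low=p, counter=redraws)
        track_end = catch - lead
        track_start = _draw_trunc(rng, *config.track_start_ms, low=0.0, counter=redraws)
        track_start = min(track_start, track_end - (config.qe_duration_floor_ms + p))
        if track_start < 0:
            has_catch = False
        else:
            sacc = _draw_trunc(rng, *config.saccade_duration_ms[condition], low=2 * p, counter=redraws)
            # the saccade to the target completes before arm flexion begins
            sacc_end = min(track_end + sacc, flex_on - 1.5 * p)
            sacc_end = max(sacc_end, track_end + 2 * p)

    if three_qe:
        wanted = ["arm_flexion", "ball_release"]
    else:
        phases_all = list(config.qe_phase_mixture)
        probs = np.array([config.qe_phase_mixture[k] for k in phases_all])
        wanted = [phases_all[rng.choice(len(phases_all), p=probs / probs.sum())]]

    refs = {"arm_flexion": flex_on, "arm_extension": ext_on, "ball_release": release}
    lower = {"arm_flexion": prep_on, "arm_extension": flex_on, "ball_release": ext_on}
    shot_qes = []  # (phase, onset, offset, location)
    free_from = (sacc_end if has_catch else 2 * p)
    for phase in wanted:
        chain = SHOT_PHASES[SHOT_PHASES.index(phase):]
        placed = None
        for ph in chain:
            lo = max(free_from, lower[ph])
            hi = refs[ph] - 1.5 * p
            if lo > hi:
                continue
            lead = rng.normal(*config.qe_onset_lead_ms[ph][condition])
            onset = float(np.clip(refs[ph] - lead, lo, hi))
            dur = _draw_trunc(
                rng, *config.qe_duration_ms[ph][condition],
                low=config.qe_duration_floor_ms, counter=redraws,
            )
            prob = config.hoop_centre_prob[ph] + (
                config.hoop_centre_outcome_shift if outcome == "hit"
                else -config.hoop_centre_outcome_shift
            )
            if rng.random() < min(max(prob, 0.0), 1.0):
                location = "hoop_centre"
            else:
                names = list(config.noncentre_weights)
                w = np.array([config.noncentre_weights[k] for k in names])
                location = names[rng.choice(len(names), p=w / w.sum())]
            placed = (ph, onset, onset + dur, location)
            break
        if placed is not None:
            shot_qes.append(placed)
            free_from = placed[2] + 2 * p

    # ---- sample grid ------------------------------------------------------
    last_event = max([release, occ_off] + [q[2] for q in shot_qes])
    n = int(math.floor((last_event + 3 * p) / p)) + 1
    t = np.arange(n) * p

    ball = np.full((n, 2), np.nan)
    in_flight = t <= catch + 1e-9
    frac = np.clip(t[in_flight] / catch, 0.0, 1.0)
    ball[in_flight, 0] = config.passer_pos[0] + frac * (config.catch_pos[0] - config.passer_pos[0])
    ball[in_flight, 1] = config.passer_pos[1] + frac * (config.catch_pos[1] - config.passer_pos[1])

    gaze = np.empty((n, 2))
    filled = np.zeros(n, dtype=bool)

    # anchors in time order: (onset, offset, kind, point)
    anchors = []
    if has_catch:
        anchors.append((track_start, track_end, "ball", None))
    for ph, onset, offset, location in shot_qes:
        anchors.append((onset, offset, location, config.qe_points[location]))
    anchors.sort(key=lambda a: a[0])

    for onset, offset, kind, point in anchors:
        m = (t >= onset - 1e-9) & (t < offset - 1e-9)
        if kind == "ball":
            gaze[m] = ball[m]
        else:
            gaze[m] = point
        filled |= m

    # gaps: glide around the next anchor's point (the previous one for the
    # trailing gap); ahead of ball tracking, sit off the ball's path.
    angle0 = rng.uniform(0, 2 * math.pi)
    gap_idx = np.flatnonzero(~filled)
    if gap_idx.size:
        splits = np.flatnonzero(np.diff(gap_idx) > 1)
        gap_runs = np.split(gap_idx, splits + 1)
        for run in gap_runs:
            t0 = t[run[0]]
            nxt = next((a for a in anchors if a[0] > t0 + 1e-9), None)
            prev = next((a for a in reversed(anchors) if a[1] <= t0 + 1e-9), None)
            if nxt is not None and nxt[2] == "ball":
                # pre-tracking samples: hold off the ball's path
                gaze[run] = ball[run] + np.array([config.glide_radius_deg, 1.0])
                continue
            if nxt is not None:
                centre = nxt[3]
                start = None
                if prev is not None and prev[2] == "ball":
                    start = tuple(ball[run[0] - 1]) if run[0] > 0 else config.passer_pos
            elif prev is not None:
                centre = prev[3] if prev[3] is not None else (0.0, 0.0)
                start = None
            else:
                centre, start = (0.0, 0.0), None
            gaze[run] = _glide_positions(
                len(run), centre, config.glide_radius_deg,
                config.glide_chord_deg, angle0, start=start,
            )

    if config.noise_sd_deg > 0:
        gaze = gaze + rng.normal(0.0, config.noise_sd_deg, size=gaze.shape)

    valid = np.ones(n, dtype=bool)
    if config.blink_prob > 0:
        valid &= rng.random(n) >= config.blink_prob
    visible = ~((t >= occ_on) & (t <= occ_off))

    recording = GazeRecording(
        trial_id=trial_id,
        participant=participant,
        condition=condition,
        outcome=outcome,
        sampling_rate_hz=config.sampling_rate_hz,
        t_ms=t,
        x_deg=gaze[:, 0],
        y_deg=gaze[:, 1],
        valid=valid,
        ball_x_deg=ball[:, 0],
        ball_y_deg=ball[:, 1],
        target_visible=visible,
    )
    phases = MotorPhaseSet(
        arm_preparation_onset_ms=prep_on,
        arm_flexion_onset_ms=flex_on,
        arm_extension_onset_ms=ext_on,
        ball_release_ms=release,
        occlusion_onset_ms=occ_on,
        occlusion_offset_ms=occ_off,
        trial_id=trial_id,
    )

    gt_fix = []
    gt_sacc = []
    gt_qe = []
    if has_catch:
        gt_fix.append(
            {"kind": "tracking", "onset_ms": track_start, "offset_ms": track_end,
             "location": "ball"}
        )
        gt_qe.append(
            {"phase": "catch", "onset_ms": track_start, "offset_ms": track_end,
             "duration_ms": track_end - track_start, "location": "ball",
             "location2": "non_centre"}
        )
        if shot_qes:
            gt_sacc.append({"onset_ms": track_end, "offset_ms": sacc_end})
    for ph, onset, offset, location in shot_qes:
        gt_fix.append(
            {"kind": "fixation", "onset_ms": onset, "offset_ms": offset,
             "location": location}
        )
        gt_qe.append(
            {"phase": ph, "onset_ms": onset, "offset_ms": offset,
             "duration_ms": offset - onset, "location": location,
             "location2": "hoop_centre" if location == "hoop_centre" else "non_centre"}
        )
    gt = GroundTruth(
        trial_id=trial_id,
        fixations=gt_fix,
        saccades=gt_sacc,
        qe=gt_qe,
        occlusion=(occ_on, occ_off),
        n_redraws=redraws[0],
    )
    return recording, phases, gt


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full balanced design: ``trials_per_cell`` hits and misses
    per condition per participant, with a manifest recording seed and config."""
    root = np.random.SeedSequence(config.seed)
    participants = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    p_shift = {q: 0.0 for q in participants}
    if config.participant_sd_ms > 0:
        prng = np.random.default_rng(root.spawn(1)[0])
        for q in participants:
            p_shift[q] = float(prng.normal(0.0, config.participant_sd_ms))
    recordings, phases, gts = [], {}, {}
    trial_seeds = root.spawn(
        config.n_participants * 2 * 2 * config.trials_per_cell + 1
    )[1:]
    k = 0
    for participant in participants:
        for condition in ("undefended", "defended"):
            for outcome in ("hit", "miss"):
                for rep in range(config.trials_per_cell):
                    trial_id = f"{participant}_{condition}_{outcome}_{rep + 1:02d}"
                    rng = np.random.default_rng(trial_seeds[k])
                    k += 1
                    rec, ph, gt = generate_trial(
                        config, participant, condition, outcome, rng,
                        trial_id=trial_id, phase_mean_shift_ms=p_shift[participant],
                    )
                    recordings.append(rec)
                    phases[trial_id] = ph
                    gts[trial_id] = gt
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_trials": len(recordings),
        "n_redraws": int(sum(g.n_redraws for g in gts.values())),
    }
    return SimulatedDataset(
        recordings=recordings, phases=phases, ground_truth=gts, manifest=manifest
    )
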