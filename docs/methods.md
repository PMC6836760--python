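# Methods

## The analysis model

A catch-and-shoot trial lives on a per-trial clock: 0 ms when the pass
leaves the passer's hands, 100% of relative time at ball release. Between
those two moments the action passes through annotated biomechanical phases
— pass, arm preparation (the dip), arm flexion, arm extension — whose
onsets are inputs (derived from elbow-angle transitions in motor video),
never computed from gaze.

The quiet eye (QE) of a phase is the final fixation or tracking gaze whose
onset precedes that phase's reference time. Its offset is where the gaze
deviates off the fixated location by more than the dispersion threshold for
at least 100 ms — exactly the fixation offset produced by event detection,
so extraction is a selection rule over detected events, not a second
detector. A fixation that is the final one before several consecutive
phase onsets is retained only for the earliest phase (it most immediately
guides that phase); later phases then simply have no QE. Five periods are
extracted per trial at most: catch, arm preparation, arm flexion, arm
extension, ball release. The ball-release QE must additionally begin
during arm extension. Offsets are never clipped to phase boundaries, and
occlusion offsets may exceed 100% of trial time.

Because the catch is annotated only through the pass/arm-preparation
boundary, the catch and arm-preparation references coincide; the
arm-preparation QE is therefore structurally a duplicate of the catch QE
and is always removed. This matches behaviour: a saccade to the target is
in flight during arm preparation, so no fixation can begin there anyway.

## Event detection

Detection is dispersion-based (the I-DT family) with a **disc criterion**:
a fixation is a maximal greedy run of samples each within
`dispersion_threshold_deg` (default 1.25°, the gaze-cursor radius
criterion) of the running centroid of accepted samples. Two tolerances:

- a spatial excursion that returns within threshold of the (frozen)
  centroid in under `min_deviation_ms` (default 100 ms) is bridged; the
  excursion samples are excluded from the centroid;
- invalid (blink/track-loss) stretches are bridged when the next valid
  sample arrives within `max_gap_ms` (default 100 ms) of the last accepted
  one.

Timestamps are half-open: onset = first included sample, offset = last
included sample + one sample period, so a 3-frame dwell at 30 Hz lasts
exactly 100 ms and durations are multiples of the sample period. Runs
shorter than `min_fixation_ms` (default 100 ms) are discarded and the scan
restarts one sample later. Ties between fixations with identical onsets
cannot occur (runs are disjoint by construction) and are asserted against.

Smooth pursuit: when per-sample ball positions are available, the same
detector runs on gaze *minus ball position* over the ball-flight window;
qualifying runs become tracking fixations labeled `ball`. Scene-frame
detection then covers only the remaining samples. This is what lets the
pre-catch pursuit count as the QE-catch "tracking gaze".

Saccades are the inter-fixation intervals spanning at least two samples
whose bounding fixation centroids are farther apart than the dispersion
threshold (a rapid move *between locations*; drifts below threshold and
instant one-frame jumps are not saccades). The displacement floor is a
package decision surfaced in `DetectionParams`; the definition at 30 Hz
("rapid movement over two or more frames") does not state one.

Two consequences of the greedy running-centroid rule worth knowing: slow
drift between two nearby locations merges into one fixation rather than
producing a saccade, and an excursion that itself dwells ≥ 3 frames becomes
its own fixation. Both are inherent to dispersion grouping at 30 Hz.

Numerics: time comparisons use a 1e-6 ms tolerance (timestamps are
multiples of 1000/30 ms and not exactly representable); the total-fixation-
time monotonicity property in the threshold holds up to float-summation
noise (~1e-12 ms).

## AOI geometry

The scene is a flat target-centred angular frame (hoop centre at origin);
at the ≤ few-degree eccentricities involved, the flat-plane approximation
to the view sphere errs by < 0.1% and spherical corrections are ignored.
Visual angle is the exact two-sided formula 2·atan(w/2d). The hoop splits
into three abutting thirds of equal angular width (1.25° at the default
0.4572 m hoop and 7.01 m distance); the cursor diameter defaults to the
same 1.25°.

The cursor-majority rule assigns a gaze point to the region holding a
**strict** majority (> 50%) of the cursor disc's area; an exact 50/50
split has no majority and yields no label. Disc–rectangle overlap areas
are computed with shapely polygon buffers (64 segments per quarter circle,
area error ~1e-5 of the disc — far below the decision boundary); tests
verify them against an independent rasterization oracle to within 1% of
the disc area. A thin rim band (default 0.16°, a ~2 cm rim tube at 7.01 m)
surrounds the hoop; a rim majority is re-coded to backboard above hoop
mid-height and net below — the only two fallback regions the coding scheme
names. Ball and passer are dynamic regions whose positions arrive per
sample; as foreground objects they take precedence when both a dynamic and
a static region hold a majority. Net and backboard extents are regulation
geometry (1.83 × 1.07 m board, 0.45 m net) placed clear of the rim band;
they are config-overridable and claim no fidelity to any particular gym.

## The simulator

`quieteye.simulate` generates the statistical structure the analysis
assumes, with exact ground truth:

- **Design**: `trials_per_cell` hits *and* misses per condition per
  participant (default 12 × 10 → 480 trials), the balanced design in which
  outcome counts are held constant so QE timing/location are free to vary.
- **Motor timeline**: phase durations drawn per condition from normals at
  study-scale means/SDs (undefended pass 505.81 ± 43.79 ms, … arm
  extension 148.26 ± 57.53 ms; defended compressed), truncated at a 100 ms
  floor. The floor is this package's choice: with SDs near 150 ms an
  untruncated (or 1 ms-floored) draw permits sub-frame phases that no
  physical arm movement produces and that make the scanpath unschedulable.
- **Scanpath script**: pursuit of the ball (linear angular flight from
  passer to catch point) from ~30 ms after trial onset until ~109 ms
  (undefended) / ~89 ms (defended) before the catch; a saccade to the
  target that completes before arm flexion begins; one shot-phase QE per
  trial, its phase drawn from a mixture (flexion 0.605 / extension 0.310 /
  release 0.085 — the observed shot-phase shares renormalized over the
  three shooting phases); its location hoop-centre with phase-specific
  probability (0.587 flexion, 0.527 extension), otherwise a weighted
  non-centre region; onset = phase reference − a drawn lead, clamped to
  the schedulable window; duration drawn from per-phase, per-condition
  normals truncated at 135 ms (4 frames) so every scripted QE is
  detectable at 30 Hz. `expected_qe_duration_ms()` reports the analytic
  truncated-normal mean, which is the quantity recovery tests target.
- **Gaze between events**: a "glide" — straight steps of ≥ 2.8°/sample
  toward, then orbiting at 3° radius around, the upcoming fixation point.
  The step and radius are chosen so that no glide window can satisfy the
  1.25°/100 ms criterion in the scene frame *or* relative to the moving
  ball, which is what makes zero-noise ground-truth recovery exact.
- **Occlusion**: an annotation interval and a per-sample visibility flag;
  onset ~74 ms (undefended) / ~1.6 ms (defended) before arm-extension
  onset, offset ~39 / ~147 ms beyond ball release.
- **Noise**: additive isotropic Gaussian angular noise per sample (default
  0.15°, ~the 0.5° instrument class after pursuit-relative smoothing);
  optional per-sample blink probability (default 0).
- **P9-style switch**: `three_qe_participants` scripts a flexion *and* a
  ball-release QE every trial for chosen participants, reproducing the
  three-QE high-style pattern.

Determinism: all draws derive from one `SeedSequence`; a fixed seed gives a
bit-identical dataset, and the manifest records seed and config hash.

What the simulator does **not** emulate: multi-fixation search behaviour
(so simulated QE share of fixations is ~100%, against the ~87% of real
data where non-final fixations exist); between-participant differences
(off by default via `participant_sd_ms = 0`); defender kinematics beyond
the condition shift of the configured means; biomechanically coupled arm
kinematics; calibration drift. Passing recovery tests therefore shows the
*pipeline* is correct on data satisfying its assumptions, not that real
gaze streams are this clean. Two further consequences: total QE per trial
is ~1.96 (one shot QE per trial by design, below the ~2.2 of data
containing multi-QE trials), and the detected catch-offset lead is ~17 ms
(half a frame) shorter than the scripted lead because offsets snap to the
sample grid.

## Inference

The χ² goodness-of-fit is the plain Pearson statistic Σ(O−E)²/E with
df = k−1 against a hypothesized allocation (default equal shares across
the four post-catch phases); its 5% size is verified against 10⁵
multinomial null draws. For condition/outcome effects the package ships a
**stratified permutation contrast** instead of a mixed-effects ANOVA:
group labels are permuted within participant strata, which respects the
repeated-measures structure without modeling variance components;
two-sided p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), never zero, and
strata containing a single label are excluded with a warning. Uniformity
of null p-values and power against a 75 ms condition gap at n = 200 trials
are part of the test suite.

## Numerical and format choices

- CSV everywhere (UTF-8, comma, `.` decimal, header); floats written with
  `%.17g` and read with round-trip parsing, so write→read is bit-lossless
  and pipeline reruns are checksum-identical.
- Accuracy percents round half-up to integers; phase-share percents to
  1 d.p.; standard errors are across trials within group (the grouping
  basis is recorded in the output).
- Grand means in the frequency table are weighted by trial counts, so the
  `All` row can exceed the unweighted participant mean.
- Readers fail loudly naming the trial/column (duplicated timestamps,
  out-of-order phase onsets, missing columns); rows that cannot back a
  valid sample are kept `valid=False` with a warning, never dropped.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use 200 random streams for
detector/oracle equivalence, 500 zero-noise trials for recovery, 200 noisy
trials for duration recovery, a 480-trial simulated study for the summary
and inference outputs, 10⁵ multinomial draws for χ² calibration and 400
replicate datasets for permutation uniformity — sizes at which the
binomial/KS tolerances in the tests are meaningful while the whole suite
runs in well under a minute.

## Known limitations

- 30 Hz sampling quantizes all event boundaries to 33.3 ms; onset/offset
  recovery is only ever exact "up to one sample period".
- The dispersion detector has no velocity criterion; very slow drifts
  merge into fixations (documented above), and saccade *durations* at
  30 Hz are gap lengths, not kinematic estimates.
- The arm-preparation QE cannot be observed under this annotation scheme
  (shared catch boundary); users with a separate catch annotation can pass
  it by adjusting the phase table before extraction.
- Occlusion computed from a visibility channel cannot report an offset
  beyond the recording; annotation-based occlusion should be preferred
  when the target stays hidden past ball release.
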