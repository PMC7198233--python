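# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `flyopto`. It is written for users who want to judge
what the synthetic validation does — and does not — establish about real
data.

## Coordinate conventions

Two frames coexist. Pixel coordinates (calibration, stimulus masks) are
0-based with pixel centers on integers, origin top-left, x rightward,
y downward — the image-processing standard. Pose analysis works in mm in a
right-handed plane: heading is measured counterclockwise from +x, the fly's
left is at heading + 90°, and positive yaw (vr) and lateral (v⊥) velocities
point leftward. Patch centers convert between the frames by the camera
scale (0.043 mm/px by default). Because every analysis stage uses the same
convention, the handedness choice does not affect any recovered quantity;
only the reporting step ("toward/away from the activated side") depends on
signs, and that mapping is confined to `hitdetect.symmetrize`: left-side
events already satisfy "+ = toward the side" and pass through, right-side
events are sign-flipped.

## Camera↔projector calibration (`coordmap`)

The quadratic map is fit by SVD-based least squares, never by normal
equations: quadratic Vandermonde matrices with pixel coordinates in the
hundreds-to-thousands are badly conditioned, and the relative
singular-value cutoff (1e-10) doubles as the degeneracy test — collinear
reference points raise `DegenerateCalibrationError` rather than silently
producing a rank-deficient fit. By default coordinates are centered and
scaled before fitting and the normalization is folded back into `T`
analytically (a 6×6 change-of-basis matrix), so the stored transform always
acts on raw pixels. The homogeneous column of `Y` is *fitted* rather than
fixed; with exact homogeneous targets the fitted first output column
reproduces 1 to ~1e-14, which the tests verify. Six non-degenerate points
determine the map exactly (interpolation regime, residual ≈ 0); more points
overdetermine it and the RMS residual is reported in projector pixels.

## Stimulus generation (`stimgen`)

Patch counts are Poisson(λ) per *pulse* and constant across the projector
frames within a pulse; resampling per projector frame is the other
reasonable reading of a per-frame Poisson parameter, and the choice is
isolated in `build_schedule` should anyone need it. Defaults are λ = 35,
radius 5 px (0.215 mm), 30 ms pulses, 500 ms interleaves, 1440 Hz
projector, over a 640×512 px (27.5×22 mm) arena. Centers are uniform over
the full arena rectangle; patches may overlap each other and the arena
edge (the edge clips the rasterized disc but not the sampling
distribution). Pulse onsets sit on the projector frame grid and durations
round *down* to whole frames with a floor of one frame; a 1e-9 s epsilon
protects exact multiples from float truncation. One RNG stream drives a
schedule, so a seed reproduces the stimulus bit-for-bit — the property that
makes post hoc analysis of "random" stimuli possible at all.

## Synthetic flies (`synthetic_fly`)

The generator is a *statistical emulator* of tracked pose data, not a
biomechanical model. Its components:

- **Forward speed**: Ornstein–Uhlenbeck process, mean 10 mm/s, stationary
  s.d. 3 mm/s, relaxation time 1 s, clipped at 0. The s.d. is chosen so the
  3 mm/s pre-stimulus filter has realistic work to do (~1–2% of events).
- **Yaw**: zero-mean OU process (s.d. 0.5 rad/s, τ = 0.5 s). Near the
  arena boundary a smooth steering torque (up to ~6 rad/s, growing if the
  fly overshoots) turns the fly toward the center. Steering keeps heading
  continuous — a hard reflection would violate the no-jump-greater-than-π
  contract on headings — at the cost of brief excursions (~1–2 mm) past
  the imaged bounds, which real flies also make.
- **Gait**: fixed tripod phasing (L1/R2/L3 against R1/L2/R3), step period
  125 ms, duty factor 0.6. Stance feet are planted in the *ground* frame
  (exactly stationary however the body moves); swing feet travel to a
  touchdown target half a step ahead of their body-frame rest offset along
  a smoothstep profile that completes at the last swing frame. This makes
  the generated duty factor exactly recoverable by a speed-threshold
  classifier, which is the point of the fixture.
- **Body geometry**: length 2.5 mm, width 1 mm, head/thorax/abdomen at
  25/35/40% of the body axis. No measured partition exists for this
  method, so these are plausible config-exposed values that all downstream
  code reads from the same place.

Injected effects multiply forward speed by
`1 + (g−1)·exp(−(t−t₀−L)/τ)` after latency L = 20 ms with decay τ =
100 ms, and add yaw/lateral velocity with the same envelope, signed toward
or away from the struck side; overlapping effect windows superpose
additively. The closed-form window-mean of that envelope
(`expected_fold_change`) is the ground truth that end-to-end recovery is
judged against: for the 100 ms analysis window it equals
`1 + (g−1)(τ/W)(1 − e^{−(W−L)/τ})`, e.g. 0.725 for g = 0.5.

The pipeline injects effects at the events detected on the *unperturbed*
trajectory and then re-integrates it. Effects are therefore applied at
exactly the analyzed events (self-consistent recovery), but the
perturbation's feedback on later hit geometry is not modeled — this is an
open-loop emulation of a closed-loop physical process. Limb positions are
carried through re-integration in body-frame coordinates, so stance feet
are no longer perfectly ground-planted after injection; the deviation is
second-order in the injected gains.

## Hit detection (`hitdetect`)

Limb hits use exact disc–segment geometry: the centroid→tip segment is
clipped to its portion outside the body ellipse (closed form, since the
centroid is inside), and the patch hits if the clipped segment passes
within the patch radius (closest-point projection with endpoint clamping).
A dense-sampling brute-force oracle (0.01 mm steps along the unclipped
segment, with an independent per-sample inside-ellipse test) agrees with
the geometric test on ≥ 99.9% of random configurations; the residual
disagreements sit at boundary distances below the sampling resolution.

Conventions where the method leaves freedom:

- Hits are evaluated at the pulse *onset* frame only. Multi-frame pulses
  during fast motion are an acknowledged approximation; at 30 ms and
  10 mm/s the fly moves 0.3 mm during a pulse, comparable to the patch
  diameter.
- The exclusion zone is the body ellipse (half length × half width).
- Ties (a patch within radius of two limbs) count as multi-limb and are
  excluded — the conservative reading of the exclusion rules.
- Several on-body patches in one pulse: the event takes the region and
  side of the patch nearest the centroid (no exclusion category exists for
  multi-body stimulation).
- Midline band ±0.05 mm: body hits within it are "midline", retained for
  speed analyses and excluded from signed turning/lateral analyses by the
  symmetrization step (they carry no side).
- Wings are not modelled, so wing co-stimulation is not excluded.

## Kinematics (`kinematics`)

Velocities use central differences (one-sided at track edges) on the
centroid and the unwrapped heading at 150 fps; no smoothing is applied by
default. Swing/stance classification instead uses *backward* differences
(displacement over the preceding inter-frame interval): central
differences blend the fast swing motion into the frames bordering each
touchdown and liftoff and bias the stance fraction low by ~1 frame per
transition. A limb is in stance when its tip's ground speed falls below
max(1 mm/s, 25% of body speed), with runs shorter than 2 frames merged
into their predecessor to suppress label chatter. The fold-change horizon
is 0.5 s post-onset; windows quantize to whole frames (the 250 ms pre
window is 38 frames at 150 fps).

## Response statistics (`responsestats`)

The resampling unit is the activation event, matching bootstrap
distributions over activations; fly-level clustering is a known limitation
(events from one fly are not independent, so intervals are mildly
anti-conservative). BCa intervals follow the standard construction — bias
correction z₀ from the bootstrap CDF at the point estimate, acceleration
from jackknife skewness — and degenerate bootstrap distributions fall back
to the percentile interval with a warning. Endpoints match
`scipy.stats.bootstrap(method="BCa")` on identical data (the tests
cross-check this), and empirical 95% coverage is 94–95% for samples of
n = 100. Like every percentile-type bootstrap, BCa undercovers for small
samples (~91% at n = 20); the calibration study is therefore run in the
asymptotic regime.

The baseline test is a paired permutation test: the statistic is
mean(post − pre) over events and the null is built by randomly exchanging
each event's pre/post labels (equivalently, sign-flipping its paired
difference), two-sided, with the +1 correction
p = (1 + #{|T*| ≥ |T|})/(n_perm + 1). A bootstrap-of-differences is the
other reading of "bootstrap permutation test"; label exchange was chosen
because it is exact under the null. Defaults: 10,000 bootstrap resamples,
10,000 permutations, seeds recorded in the output tables.

**Sampling bias and baselines.** Conditioning on a hit selects poses that
expose the struck side — a fly turning away from its left sweeps its left
limbs outward and offers them to patches — so raw signed yaw/lateral
window means are biased identically before and after onset. Group
summaries therefore report signed signals as the per-event post-minus-pre
*change* from baseline (fold-change is already normalized per event). The
permutation test is immune to the shared bias by construction. This is the
synthetic analogue of the phase-dependent hit biases expected whenever
stimulus interception depends on posture.

Somatic maps bin body-frame hit locations at 0.1 mm and mask bins with
fewer than 5 events; bin counts over the map extent sum to the ensemble
size.

## Problem sizes

The validation suite uses: 10,000 random configurations for the
hit-detection oracle, 10,000 pulses for stimulus statistics, 1,000
simulations each for CI coverage and permutation type-I error, and
20 flies × 180 s (one fly-hour, ~130–170 analyzed events per limb class)
for end-to-end recovery plus an equal-sized no-effect control. At these
sizes the injected ±30°/s turn clears the per-event yaw noise
(s.d. ≈ 1.3 rad/s) by ~3 standard errors per class. The "control run shows
no significant classes" property is intrinsically stochastic: with six
class×signal tests at nominal p < 0.01 a perfectly calibrated analysis
still flags one occasionally.

## What passing tests do not show

Synthetic flies have stationary gait parameters, no grooming, stopping,
or wall-following states, no tracking noise or identity swaps, no
inter-fly interactions, and effects injected exactly per the assumed
latency/decay model. Real-data properties such as behavioral adaptation to
stimulation, arena-region avoidance, driver-dependent response shapes, and
tracking-error robustness are outside what this package's validation can
establish.
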