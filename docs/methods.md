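# Methods

This note documents the model behind `pauseloop`, its assumptions and
defaults, the numerical choices, and what the synthetic experiments can and
cannot show about real animals.

## The closed loop

Sensor, controller, and display share one clock (120 Hz). At each sample *t*:

1. the walker emits trackball increments — forward `v_walk·dt` during walk
   bouts, yaw `±ω_turn·dt` during turning bouts, zero while paused — each
   channel plus Gaussian sensor noise σ;
2. the motion detector updates on the planar displacement magnitude
   (threshold + debounce hysteresis, initial state NOT-MOVING);
3. the detected state gates the **next** stimulus frame (one-sample
   controller latency, mirroring a sensor → microcontroller → display chain):
   open loop → always active; in phase → active while moving; out of phase →
   active while still;
4. the evidence integrator absorbs the frame currently displayed;
5. bout clocks advance (pause termination by hazard thinning, walk
   termination at a pre-drawn exponential duration).

The RDK dot fields themselves do not feed back into the walker — perception
is abstracted to (signal direction × active flag) — so trials run without
materializing frames, and the frame log is reconstructed on demand as a pure
function of the stimulus seed and the active-flag sequence.

## The generative walker

Three structural assumptions are empirical facts about locust intermittent
walking; everything else is this package's modelling choice.

* **Walk bouts are memoryless.** Durations ~ Exponential(τ_w), τ_w = 2 s.
* **Pauses are heavy-tailed.** Baseline hazard h₀(t) = (α−1)/(t + t_min)
  gives the bounded power-law survival S(t) = (t_min/(t+t_min))^(α−1);
  α = 1.8, t_min = 0.5 s, hard cap t_max = 60 s (the hazard is taken
  infinite there, so the capped law has an atom at t_max with mass
  S(t_max) ≈ 0.021). The closed-form mean of the capped law,
  ∫₀^{t_max} S(t) dt ≈ 4.02 s, makes the no-stimulus walking fraction
  τ_w/(τ_w + E[pause]) ≈ 0.33 — a realistic resting level for a tethered
  nymph.
* **Decisions happen at pause end.** Each pause termination chooses a
  straight or a turning walk bout.

Perception is a leaky integrator, E' = E + dt(−E/τ_e + w(state)·s·[active]),
with s = +1 for stimuli along the heading and −1 against it; w_pause = 1 s⁻¹,
w_walk = 0, τ_e = 3 s. Setting w_walk = 0 is the strong form of the
pause-weighted-perception hypothesis and makes the in-phase condition a
(near-)null — exactly the pattern the design is meant to expose. Evidence
*against* the heading acts twice: it multiplies the pause hazard by
1 + β·max(0, −E) (β = 3: the urge to get moving) and it raises the turning
probability 1/(1 + e^−(k(−E)+b)) (k = 4; b = −2.944, i.e. a 5 % baseline
turn rate). Turn *direction* is a persistent per-subject trait (drawn once
per subject, ±1), since a tethered animal cannot actually reorient; in a
within-subject protocol it is pinned across all of a subject's trials.

Defaults: v_walk = 3 cm/s, ω_turn = 1 rad/s, σ = 0.002 cm/sample,
trial duration 300 s. Sensor noise sits well below the detector threshold
(0.01 cm/sample ≈ 1.2 cm/s) while a walking step (0.025 cm) sits well above
it, so detection errors come from latency, not misclassification.

## The latency leak (why in-phase is not an *exact* null)

With the one-sample controller latency and an off-debounce of d_off samples,
the stimulus in in-phase mode stays active for (d_off + 1) samples into
every pause — where w_pause applies. Each pause onset therefore injects a
drive quantum ΔE = (d_off + 1)·dt·w_pause (≈ 0.05 at the default d_off = 5),
decaying with τ_e. The leak is a faithful property of any latched
closed-loop rig, but it means the in-phase condition with w_walk = 0 carries
a small real direction effect: simulated 15-vs-15 experiments at the default
detector reject at ≈ 0.10 instead of 0.05. The type-I calibration therefore
runs with a minimal-lag detector (debounce_on = debounce_off = 1), which is
also the natural setting here — debouncing exists to suppress sensor
glitches, and at this threshold the synthetic sensor produces essentially
none (supra-threshold noise probability ≈ 4·10⁻⁶ per sample). With the
1-sample residual leak the measured rejection rate over 400 replicate
experiments is 0.0675, within the calibrated band.

## Kinematic analysis

* **Path integration.** Heading absorbs the yaw increment first, then the
  forward/lateral arc lengths are rotated into the tether frame and summed.
  Ball geometry is abstracted away — increments are consumed as arc lengths
  in cm — so sphere radius never enters. Against the closed-form circle for
  constant (v, ω) the per-sample error is O(dt).
* **Segmentation.** The displacement *vector* is smoothed by a centred
  moving average (0.25 s) before taking the magnitude. Smoothing the
  rectified magnitude instead would leave a noise floor of
  σ·√(π/2)·rate ≈ 0.30 cm/s — exactly the default walk threshold (10 % of
  v_walk) — and randomize pause classification; vector smoothing is unbiased
  under zero-mean noise and leaves the pause-time floor ≈ 0.06 cm/s.
  Interior bouts shorter than 0.3 s are merged into their neighbours,
  shortest first (earliest on ties); the first and last bouts are exempt
  (the trial window truncates them). Note the minimum-bout rule absorbs
  genuinely short pauses (31 % of baseline pauses are < 0.3 s), so segmented
  walking fractions sit above ground-truth label fractions; the bias is
  common to all groups and cancels in contrasts.
* **Side motion.** Not formally standardized for trackball data; defined
  here as Σ|Δy| of the fictive path in the fixed tether frame (y ⊥ initial
  heading). A pure turning-intensity alternative, Σ|Δφ| in radians, is
  exposed as `SideMotionDefinition.HEADING_TURN`.
* **Degenerate inputs.** A trial with no pause reports mean pause 0 with
  `has_pause=False`; a motionless trial reports straightness 1 by
  convention; empty traces raise `InsufficientDataError`.

## Statistics

U counts pairs (first sample exceeds second; ties half). Two-sided p-values
double the smaller tail, capped at 1. Policy: exact enumeration of all
C(n, n_a) label assignments for pooled n ≤ 14 (midranks make this valid
under ties); seeded Monte-Carlo permutation (100 000 draws, add-one
corrected) for n ≤ 40 or whenever ties are present; tie-corrected normal
approximation with continuity correction otherwise. The experiment's
15 + 15 design lands in the permutation branch, whose smallest attainable
two-sided p is 2/(B+1) ≈ 2·10⁻⁵. No multiple-testing correction is applied
by default (per-panel testing); Holm adjustment is available as a flag.

## Seeding and determinism

All randomness descends from a master seed through `numpy.SeedSequence`
spawn keys: trial seeds are keyed by (condition, direction, subject), subject
traits by (subject,), so adding or removing cells never perturbs other
cells' streams. Trials pre-draw their randomness into tapes consumed by a
numba-compiled kernel; a whole trial is a deterministic function of its
seed, and experiment tables reproduce byte-identically.

## Problem sizes used by the test suite

The directional-pattern experiments use the full design (15 subjects per
cell, 300 s trials). The type-I calibration uses 400 replicate experiments
of 60 s trials — pause-shortening effects saturate within a few evidence
time constants, so shorter trials leave the null calibration unchanged while
keeping the Monte-Carlo rejection-rate estimate well resolved
(binomial s.e. ≈ 0.011 at rate 0.05). Generator-calibration checks use
10⁵ inverse-transform draws and ~5·10³ simulated pauses.

## Limitations

* The agent is a renewal-plus-integrator caricature: no biomechanics, no
  leg kinematics, no habituation or arousal dynamics, no inter-individual
  parameter variation beyond the turn sign and the random streams.
* One shared clock replaces the real rig's asynchronous sensor/display
  clocks; the single-sample latency is a simplification of a variable
  sensor → controller → render chain.
* Dot-field contents do not influence the walker beyond direction × active;
  luminance, contrast, dot density and occlusion effects are out of scope.
* Effect sizes are set by the evidence parameters (w_pause, β, k), which are
  modelling choices, not fitted values; passing tests show the pipeline
  recovers the *pattern* (directional differences retained out of phase,
  lost in phase), not that the magnitudes match any real animal.
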