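# Methods

This note documents the models, algorithms and numerical choices behind
`hapticstrokes`, in the order the pipeline runs.

## Stimuli and visual priors

Haptic stimuli are disc-shaped sinusoidal gratings of diameter 90.7 mm;
the height profile along the axis orthogonal to the ridges is
z(x) = (A/2)·sin(2πx/P) + c with amplitude A = 0.3 mm and period P in
millimetres.  The additive offset c (default 0.5) only shifts the baseline
and is exposed as a parameter because no analysis quantity depends on it.
Discrimination pairs use adjacent periods from {1.524, 2.032, 2.540,
3.048} mm; the demand manipulation replaces these with pairs ~2 Weber
fractions apart (low demand) or ~1 Weber fraction apart (high demand).

A visual prior is a disc of 100 short line segments; its quality q is the
fraction of segments aligned with the upcoming grating's orientation,
with exactly round(q·n) aligned segments (half-up rounding so ties like
q·n = 12.5 are reproducible) and the rest uniform on [0°, 180°).  Segment
centres are rejection-sampled in the disc with a 4 mm minimum spacing so
the 8 × 1 mm segments do not overlap visually; the placement rule is a
package choice, as is the decision that the 0% condition contains zero
aligned segments rather than chance-level alignment (the distinction is
unobservable in expectation but affects exact counts).  `prior_readout`
(axial mean and resultant length of the segment orientations) verifies
that the quality manipulation monotonically strengthens the orientation
signal.

## Trial designs

Experiment 1: 5 qualities × 6 orientations × 3 pairs × 2 stimulus
locations × 2 start locations = 360 trials, each cell exactly once, fully
randomized.  Experiments 2 and 3: 3 qualities × 6 orientations × 2 pairs
× 2 × 2 = 144 trials per demand level, 288 total, presented as four
alternating demand blocks of 72 (ABAB), the starting demand
counterbalanced across participants.  Trial lists are exact factorial
covers; randomization is seeded and reproducible.

## Generative model of an exploration

The study implies that prior usage grows with prior quality but does not
formalise a movement model, so the generator is a deliberately simple
stand-in whose ground truth the pipeline must recover:

* **Initial stroke direction** (relative to the texture): with probability
  w(q) an axial von Mises draw centred at 90° with concentration
  κ_initial; otherwise axial-uniform.  Sampling doubles the angles, draws
  from the circular von Mises, and halves.
* **Later strokes** use a fixed high weight (0.9) and κ_late = 8,
  emulating the well-established orthogonal drift after sensory contact.
* **Defaults**: w(q) = min(1, 0.2 + 0.9q) and κ_initial = 2 were chosen
  once so that simulated orthogonal-initial percentages rise from somewhat
  above chance at q = 0 to roughly 35–45% at q = 0.5, the scale of the
  observed effects (an axial von Mises with κ = 2 puts ~49% of its mass in
  the ± 15° window, so w = 0.65 lands at ~38%); they claim qualitative
  realism only.  An optional
  w(q, session-progress) hook emulates gradual learning; it defaults to
  constant because the pipeline, not the learning process, is the object
  under test.
* **Kinematics**: strokes are straight constant-speed chords (100 mm/s)
  through the touched disc, truncated at the border (never an error);
  stroke count per trial is 1 + Poisson(mean − 1) truncated at ≥ 2 with
  mean 6.6, side switches Poisson(mean 1.7) capped at count − 1.  Between
  strokes the force stays below 0.05 N for at least 0.3 s, so each stroke
  forms its own supra-threshold contact episode; within strokes the normal
  force sits at 1 N.  Gaussian position noise (default 0.05 mm) and force
  noise (0.01 N) are added; forces are clipped at zero.
* **Sampling rate**: one common 500 Hz clock.  Real rigs sample position
  and force at different rates; mixed-rate data are linearly interpolated
  onto the position clock at read time rather than inside the
  segmentation.
* **Responses** are Bernoulli with a per-experiment accuracy parameter
  (defaults 0.911/0.902/0.871), independent of movement — the generator
  does not model perception.
* **Reproducibility**: one master seed; participant p uses the stream
  seeded with master + 7919·p, so any participant can be re-simulated
  independently and full datasets round-trip byte-identically.

What the generator does **not** emulate: biomechanical dynamics (curved
strokes, speed profiles), per-participant idiosyncratic direction biases,
force tuning, and any coupling between movement and discrimination
accuracy.  Passing tests therefore show that the pipeline recovers the
statistics it is supposed to recover, not that recorded human data meet
the generator's assumptions.

## Stroke segmentation

1. **Contact gating**: maximal runs with force ≥ 0.1 N *and* position
   inside a stimulus disc, kept if strictly longer than 200 ms.  Negative
   forces beyond a 0.02 N tolerance trigger a data-quality warning and
   are clipped to zero.
2. **Boundaries**: the position series is smoothed with a centred moving
   average (25 ms default; raw derivatives of noisy positions produce
   spurious crossings), differentiated, and smoothed again.  A sign change
   of either the x- or the z-derivative marks a movement turn.  Because a
   derivative hovering near zero (e.g. the x-velocity of a near-vertical
   stroke) flickers in sign under noise, a change only registers after the
   derivative has exceeded a speed deadband on the other side
   (`min_turn_speed_mm_s`, default 25 mm/s — about 3 standard deviations
   of the smoothed derivative noise at 0.1 mm position noise and 500 Hz,
   and far below genuine stroke speeds).  A genuine reversal swings both
   derivatives far beyond the deadband.  Texture-border crossings add
   boundaries; a `dominant` mode restricted to the higher-energy axis is
   available as a sensitivity check.
3. **Cleanup**: boundaries closer than 50 ms merge (first kept); segments
   displacing less than 5 mm merge into their successor (predecessor for a
   trailing fragment).  The merge window, displacement floor, smoothing
   window and deadband are documented package choices — the original rule
   set leaves them open — and all sit in `SegmentationConfig`.
4. **Direction**: axial orientation of the segment's start-to-end line in
   the horizontal x–z plane, on [0°, 180°); the vertical axis never enters.
   Indices are half-open [start, end), 0-based internally.
5. **Roles**: chronologically first = initial, final = last; the middle
   stroke is the later of the two central candidates when the count is
   even; a single stroke is both initial and last and the middle is
   undefined (excluded from middle-stroke analyses).

Against ground truth, segmentation is exact (counts and directions) on
noise-free simulations and recovers exact counts in ≥ 95% of trials with a
median direction error well under 2° at 0.1 mm position noise.

## Axial circular statistics

Directions are axial: θ and θ + 180° are the same movement line.  The
default treatment doubles the angles, computes circular statistics on the
full circle, and halves angular results; a `raw` mode that treats [0°,
180°) as ordinary circular support exists for sensitivity analyses, since
the original toolbox convention is not fully determined.  Provided:

* axial mean and mean resultant length, with a degenerate flag when
  R̄ ≈ 0 (mean undefined — never silently defaulted);
* the V-test toward μ = 90° with the one-sided normal approximation for
  u = V√(2/n), plus a Monte-Carlo null simulation alternative for small
  samples (the normal approximation's type-I error at n = 16 is calibrated
  at 0.05 ± 0.02 in the test suite);
* a confidence interval for the mean direction from the classical
  chi-square bound on the resultant length, computed on the doubled scale
  and halved, flagged degenerate (whole axis) when dispersion is too high;
* 10°-binned histograms with half-open bins (90° falls in [90°, 100°));
* Bonferroni adjustment with an explicit family size.

Estimators for the generative parameters: the von Mises concentration by
inverting the exact Bessel ratio A(κ) = I₁/I₀ with bisection (no series
approximation), and the mixture weight by projecting the doubled mean
vector onto the expected direction and dividing by A(κ) — unbiased under
the mixture model because the uniform component contributes zero in
expectation.

## Condition-level analyses

The condition table aggregates strokes per participant × quality
(× demand × order) × role (× session quarter), carrying the orthogonal
percentage (window 90° ± 15°, closed interval by default with an
open-interval flag; a ± 10° alternative is one argument away), the
participant's axial mean direction, cell stroke counts, and percent
correct.  Condition-level V-tests run on the participant mean directions.
Participants lacking a cell are dropped listwise from the affected ANOVA
with a logged count; quarters are contiguous chronological blocks
(n divisible by 4 enforced).

Percentages of correct responses are arcsine-square-root transformed
before their ANOVA.  One-way repeated-measures ANOVAs (pingouin) apply the
Greenhouse–Geisser correction when Mauchly's test rejects sphericity at
α = 0.05 — the gate itself is a package choice since "when violated" is
otherwise undefined.  The three-way mixed design (two within factors, one
between) is computed from scratch for balanced within-cells data via
orthonormal within-cell transforms and a between-subjects least-squares
model (type III, effect coding), giving each within-involving term its own
error stratum, ε, and Mauchly gate; it is validated in the test suite
against `car::Anova` in R (exact agreement of F, dfs and ε, including
unequal group sizes) and against pingouin on the one-within-one-between
case.  Effect sizes: partial η² for ANOVAs, Cohen's d (SD of differences)
for paired tests, Hedges' g with the exact gamma-function small-sample
correction for Welch comparisons.  The contingency comparison runs one
Welch test per shared quality level on participant-level orthogonal
percentages, Bonferroni m = 2.

Degenerate inputs are handled by convention rather than exception where a
convention exists: a dv constant across levels yields F = 0, a stratum
with zero residual variance yields F = 0 or ∞ depending on whether the
effect variance is also zero, and two zero-variance groups with equal
means give t = 0, p = 1.

## Contingency replication experiment

`simulate_contingency_pattern` replicates the high- versus low-contingency
comparison at the level of initial-stroke directions: per replicate, one
18-participant session set with mixture weight 0.5 at the 50% prior and
one 14-participant set with weight 0.1, w(0) = 0 in both, 48 initial
strokes per quality × demand cell, κ = 2.  V-tests on participant mean
directions per cell are Bonferroni-corrected for the six initial-stroke
cells of a session.  The replicated pattern requires: both 50% cells
significant in the high-contingency set; no 0% cell significant anywhere;
at most one significant 50% cell in the low-contingency set (reduced
adjustment — the reference pattern itself contains exactly one); and a
higher mean orthogonal-initial percentage in the high-contingency set.
The experiment runs at the direction level rather than through full
trajectory synthesis because 200 replicates × 32 sessions × 288 trials of
trajectory segmentation is computationally out of proportion to what it
would add: segmentation fidelity is established separately by the
ground-truth round-trip, and the pattern is a property of the direction
statistics.

## Problem sizes and determinism

The acceptance script simulates the full 16-participant, 360-trial session
once, 2 × 500 trials for the segmentation round-trip, 20,000 replicates
for the V-test calibration, 100 replicates of n = 1000 for κ recovery, and
200 replicate pairs for the contingency pattern; the whole run takes on
the order of half a minute.  All randomness flows from explicit seeds;
identical seeds reproduce datasets and result files byte for byte (CSV
written with fixed float formatting and provenance headers).

## Known limitations

* The generator's parameters (w(q), κ, stroke counts, speeds, accuracies)
  are stand-ins; no claim is made that they fit recorded kinematics.
* The mixed ANOVA requires one observation per subject per within cell
  (aggregate first) and balanced within-cell structure.
* The V-test p-value is asymptotic; for n < 10 prefer the simulation
  method.
* The deadband turn detector can, by construction, miss genuinely slow
  movement turns (< 25 mm/s); lower `min_turn_speed_mm_s` for slow-motion
  protocols.
* Axial-mode `raw` changes V statistics but not the qualitative ordering
  of conditions in any scenario exercised by the test suite.
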