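# hapticstrokes

Analysis pipeline for haptic texture-exploration kinematics: from raw
finger-trajectory time series to stroke segmentation, axial circular
statistics of movement direction, and factorial condition-level analyses.

## The problem

When people stroke a grooved texture to judge its spatial frequency, moving
**orthogonal** to the ridges maximises the temporal modulation at the
fingertip and thus the sensory information gained per stroke.  If a visual
cue shown before touch indicates the upcoming texture's orientation, do
people use it to pre-orient their very first stroke — and does that depend
on the cue's quality and on task demands?  This package implements the
complete analysis chain for that question, for experimenters working with
tracked finger position (x, z in the table plane) and normal-force
recordings over two disc-shaped gratings, in a two-interval frequency
discrimination design.

## Method core

**Stroke segmentation.**  Contact episodes are maximal runs with normal
force ≥ 0.1 N over a stimulus disc, lasting > 200 ms.  Within a contact,
stroke boundaries are zero crossings of the smoothed first derivatives of
the x- or z-position (movement turns) and texture-border crossings;
boundaries closer than 50 ms merge and segments displacing < 5 mm are
absorbed.  A stroke's direction is the orientation of the line connecting
its start and end point, treated as **axial** data on [0°, 180°).

**Axial statistics.**  All circular statistics use the doubling transform:
angles are doubled, analysed on the full circle, and angular results
halved.  With sample size n, mean resultant length R̄ and mean direction
θ̄, concentration toward the expected direction μ = 90° (orthogonal to the
ridges, after aligning all texture orientations to 0°) is tested with the
V-test,

    V = n · R̄ · cos(θ̄ − μ),     u = V · √(2/n),

with a one-sided p-value from the standard normal upper tail.  The index
of prior usage is the percentage of strokes within 90° ± 15°; under a
uniform axial distribution its chance level is 100·30/180 = 16.67%.

**Condition-level inference.**  Per-participant percentages enter
repeated-measures ANOVAs (one within factor) or a three-way mixed ANOVA
(Quality × Demand within, Order between) with Greenhouse–Geisser
correction gated by Mauchly's test, a linear polynomial contrast across
quality levels, paired t-tests for demand effects, and Welch tests with
Hedges' g for between-experiment contingency comparisons.

**Synthetic data.**  A generative stand-in produces multi-stroke
trajectories with known ground truth: initial-stroke directions are drawn
from a quality-weighted mixture of an axial von Mises component centred at
90° and an axial uniform component; later strokes are more concentrated;
force drops to near zero between strokes.  Every stage of the pipeline is
testable against these annotations without any recorded data.

## Worked example

```python
from hapticstrokes import (SimParams, simulate_experiment, segment_dataset,
                           run_standard_analysis)

params = SimParams(weight_fn=lambda q: q)   # mixture weight equal to prior quality
ds = simulate_experiment(experiment_id=1, n_participants=6, params=params, seed=42)
strokes, summaries = segment_dataset(ds.trajectories)
res = run_standard_analysis(strokes, ds.design, ds.responses, summaries)
```

Printing the initial-stroke V-tests per quality condition and the headline
statistics gives:

```
 quality_fraction  n      V  p_raw
             0.00  6 -1.924  0.867
             0.15  6  1.545  0.186
             0.25  6  5.478  0.001
             0.35  6  5.439  0.001
             0.50  6  5.838  0.000
Quality ANOVA (initial strokes): F(4,20) = 7.41, p = 0.0008, eta_p^2 = 0.60
Linear quality trend: F(1,5) = 18.27, p = 0.0079
Strokes/trial = 6.67, switches/trial = 1.66, correct = 91.2%
```

With the mixture weight set equal to prior quality, first-stroke directions
are at chance for the 0% and 15% priors (V-tests non-significant) and
increasingly concentrated toward 90° from 25% quality upward; the
repeated-measures ANOVA and the linear trend pick up the quality gradient,
while response accuracy and general movement measures stay flat across
conditions.

There is also a command-line interface:

```
hapticstrokes simulate --experiment 1 --participants 2 --seed 7 --out dataset
hapticstrokes segment  --data dataset --out segmented
hapticstrokes analyze  --data dataset --out results
hapticstrokes report   --results results
hapticstrokes selftest
```

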