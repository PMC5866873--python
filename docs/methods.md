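# Methods

This note records the modelling choices behind `neurotap`: the generative
model of the synthetic cohort, the capacity regressor and its training
scheme, the fuzzy staging system, and the numerical decisions that are not
visible from the API.

## Tap-test data model

One record is a single attempt: target centre `(x, y)`, touch point
`(xt, yt)`, the number of on-screen circles `nC ∈ {2, 3, 5}`, the reaction
time `rt > 0` in seconds, a subject id and a disease flag. The two derived
features are `rt` itself and the touch error
`delta = √((x − xt)² + (y − yt)²)` in pixels. `delta` is recomputed from
coordinates whenever records are read; a stored `delta` column is only
validated (mismatches beyond 0.01 px are logged, not fatal, since printed
tables occasionally carry typos) and the recomputed value is authoritative.

Both features are strongly right-skewed, so modelling happens on the log
scale. The transform is `ln(value + 1e-3)`: the additive floor keeps a
perfect touch (`delta = 0`) representable and is negligible at the
second/pixel scales involved. Near-normality on the log scale is screened
with the large-sample rule: for n > 300, |skewness| < 2 and |Pearson
kurtosis| < 7 count as acceptable. The Pearson (non-excess) kurtosis
convention is used throughout — a normal sample scores ≈ 3 — because the
threshold of 7 and typical reported values near 4–5 only make sense on that
scale.

Feature discriminative power is measured as the Kullback–Leibler divergence
D(healthy ‖ sick) in bits between class-conditional histograms within each
object-count stratum: 20 equal-width bins spanning the pooled range,
additive smoothing α = 0.5 per bin. The estimator is deliberately the
plain histogram plug-in — deterministic, configurable, and standard in
feature-selection practice. A symmetrized (Jeffreys) variant is available
since the divergence direction is a convention.

## Synthetic cohort generator

No dataset of this kind is publicly deposited, so the generator is a
first-class, tested component rather than a test fixture. It emulates a
20-subject study (10 healthy, 10 HD patients) with 51 attempts per mode per
subject — 3060 records.

* **Severity.** Each subject has a latent severity s: healthy ~ U(0, 0.1),
  patients ~ U(0.3, 1.0), plus per-subject random effects (sd 0.15 on both
  log scales) so subjects are not exchangeable.
* **Layouts.** Circle centres (radius 60 px on a 1080×1920 screen) are
  rejection-sampled until all pairwise distances exceed one diameter and
  every circle is fully on screen; 10 000 consecutive rejections raise an
  infeasibility error.
* **Reaction time.** `log rt ~ N(−0.7 + 1.2·s + 0.10·(nC − 2), 0.55²)`:
  slower with severity (bradykinesia) and mildly with more objects (visual
  search). Healthy medians ≈ 0.5 s; severe patients reach several seconds
  with a lognormal tail to ~10 s.
* **Touch error.** The touch point scatters around the target centre with
  isotropic Gaussian sd `4.5 · exp(2.5·s)` px, so `delta` is
  Rayleigh-distributed per subject — lognormal-ish in aggregate. Healthy
  touches land within a few pixels; severe tremor produces errors of tens
  to ~250 px.
* **Capacity label.** `tfc = clip(10 − 1.0·z(log rt) − 2.0·z(log delta) + ε,
  0, 10)` with ε ~ N(0, 0.2) and z-scores against *fixed* reference moments
  (log rt: −1.0/0.65; log delta: 1.3/0.8) stored in the config — so every
  label is exactly recomputable from its own record, and the label function
  is identical across subjects. The touch-error coefficient is twice the
  reaction-time coefficient by construction, making `delta` the stronger
  predictor; the KL ranking reproduces that ordering in every stratum.

The slopes and reference moments were fixed once so that (a) healthy
subjects average ≈ 8 on the label scale and severe patients ≈ 1–3 with
modest clipping at the ends, (b) the raw features fail the normality screen
while their logs pass it, and (c) the generated feature ranges bracket
realistic tap data (rt ≈ 0.1–10 s, delta up to a few hundred px).

What the generator does **not** emulate: oscillatory tremor trajectories,
device/OS latency effects, learning/fatigue across attempts, and
longitudinal within-subject progression other than an explicit severity
parameter. Passing tests on this cohort therefore demonstrate that the
pipeline recovers a capacity signal of this *shape* — monotone in log-time
and log-error with subject-level heterogeneity — not that it would reach
the same accuracy on clinical data.

## Capacity regressor

Architecture: 2 inputs, 10 log-sigmoid hidden units, 1 linear output —
(2+1)·10 + (10+1)·1 = 41 weights; the cascade-forward variant (direct
input→output connections, 43 weights) is described for parameter counting
but not trained. Inputs are the log features standardized by the *training
partition's* moments; the standardization is stored in the model so
inference is self-contained. Predictions used for staging are clipped to
[0, 10]; the raw forward pass is left unclipped.

Training is full-batch gradient descent on the MSE with an adaptive
learning rate: each epoch proposes one gradient step; if the resulting
training error exceeds the previous one by more than 4% the step is
rejected and the rate shrinks ×0.7, otherwise it is accepted and the rate
grows ×1.05 (initial rate 0.01). Early stopping monitors validation MSE
every epoch (counting both accepted and rejected epochs) and halts after
300 consecutive epochs without a new validation minimum, up to 20 000
epochs, returning the weights at the validation minimum.

The patience and epoch budget deserve a note: with full-batch descent an
"epoch" is a single cheap gradient evaluation (~0.1 ms at n ≈ 2000), and
the adaptive-rate dynamics produce validation plateaus hundreds of epochs
long that later resolve. Small-patience settings borrowed from minibatch
practice halt on those plateaus at roughly twice the achievable error; the
defaults here let a benchmark training run finish in 5–15 s while reaching
the label-noise floor (test MSE ≈ 0.04 against a noise variance of 0.2² =
0.04). Weight initialization is uniform on [−0.5, 0.5] from the run seed;
the same seed reproduces the full weight trajectory.

Splits are by subject — all attempts of a subject land in exactly one of
train/validation/test — because the clinical question is generalization to
unseen people. Subjects are shuffled with the split seed and apportioned
70/15/15 by largest-remainder rounding (20 subjects → 14/3/3); a 40/30/30
preset exists as an alternative. With only three held-out subjects the test
metrics are noticeably split-dependent: across ten independent replicates
of the whole study, nine of ten reach R ≥ 0.98 with MSE ≤ 0.08, the
remaining one showing a genuine subject-composition generalization gap
(test MSE ≈ 0.084 with training error already at the floor).

## Fuzzy reaction staging

The three inputs AVG1–AVG3 are the per-mode means of clipped predictions
for the 2-, 3- and 5-object modes; an empty mode is an error (a session
must cover all modes). Membership functions are pure triangles with the
parameters listed in the README; inference is standard Mamdani Type-1:
rule strength = min of antecedent memberships, implication = clipping the
consequent at the strength, aggregation = pointwise max, defuzzification =
centroid on a uniform grid over [0, 10] with step 0.005 (2001 points) —
the step was chosen so the grid centroid agrees with an exact
piecewise-linear (trapezoid) centroid to 1e−3.

Only five of the 27 rules are conventionally written out
(L,L,L → ADVANCED; L,L,H → LATE; A,A,A → AVERAGE; H,L,H → EARLY;
H,H,H → HEALTHY/PRECLINICAL). The base is completed by the ordinal-sum
policy — score LOW = 0, AVERAGE = 1, HIGH = 2, and the sum s of the three
antecedent scores maps 0 → ADVANCED, 1–2 → LATE, 3 → AVERAGE, 4–5 → EARLY,
6 → HEALTHY/PRECLINICAL — the unique simple monotone completion consistent
with all five written rules. Alternative rule bases load from YAML/JSON.

Numerical edge cases: inputs outside [0, 10] are clipped with a warning;
inputs exactly at 0 or 10 have zero membership in every pure triangle, so
they are nudged one grid step into the open interval (with a warning)
rather than silently reshaping the membership functions into shoulders.
If no rule fires (possible only with user-supplied incomplete rule bases),
defuzzification raises a no-rule-fired error instead of inventing a value.

A known property worth stating: the **crisp** centroid score is not exactly
monotone in the inputs. The centroid of a clipped asymmetric triangle is
non-monotone in the clip height (each output term's centroid varies within
a ≈ 0.08 band as its activation changes), and shifting mass between terms
can lower the score by up to ≈ 0.17 when an input rises past a membership
peak. The **ordinal stage** — the output term with maximal activation, and
the only quantity the decision module consumes — is monotone under
single-input raises (zero violations over 20 000 random sweeps). The
two-session verdict therefore compares stages ordinally (ADVANCED < LATE <
AVERAGE < EARLY < HEALTHY/PRECLINICAL): a drop is "impaired", equality
"stable", a rise "improved". An optional crisp-score margin can refine
equal-stage comparisons; its default is 0 so defuzzification jitter can
never flip a verdict.

## Problem sizes

The default study is 3060 attempts from 20 subjects; a full
generate-split-train-evaluate benchmark runs in well under a minute, and
the property suites (1000-seed split checks, 1000-triple monotonicity
sweeps, 100 random defuzzification activations, ten training replicates)
complete in a few minutes on one CPU.

## Known limitations

* The capacity label of the synthetic cohort is a noisy monotone function
  of the two features only; real TFC ratings depend on much more than tap
  performance, so the reported R/MSE characterize recoverability of the
  simulated signal, not clinical accuracy.
* The clinical TFC scale spans 0–13, while the regressor's output and the
  fuzzy input domain live on [0, 10]; the stage-band mapping
  (`tfc_to_stage`) accepts 0–13, but the pipeline's capacity level is
  defined on [0, 10] and no mapping between the two widths is assumed.
* The fuzzy system's membership parameters and rule completion are fixed
  domain engineering, not fitted to data; only the regressor learns.
* Two-session comparison is ordinal; it does not model measurement
  uncertainty of a stage or longitudinal trajectories over many sessions.
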