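# Methods

This note documents the models and procedures `rmkpredict` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Kinematic metrics

A movement is a timestamped sequence of planar end-effector positions
(metres, origin at the central target) with optional velocities.  The four
directions A–D are defined in a frame aligned with the lesion side
(A = +y away from the body, C = −y toward it, D = +x lateral, B = −x
medial); recordings from left-affected patients are mirrored in x before
extraction so identical labels describe identical shoulder/elbow synergies.
This axis assignment is a declared convention: it makes the path-error
definition (|y| for D, |x| for A and C) exact, and identifies direction C
with the elbow-flexion/shoulder-extension movement that flexor synergy
disrupts most.

**Movement Path Error (MPE)** is the mean point-to-line distance from the
straight centre-to-target line.  With axis-aligned targets this reduces to
the mean absolute off-axis coordinate, which is also mirror-invariant, so
the metric itself is insensitive to the side transform.  It is defined for
directions A, C and D; direction B contributes only the speed metric.
**Mean Speed (MS)** is the time-average of the resultant velocity
magnitude.  Recorded velocities are used when present; otherwise they are
derived by central differences on the actual timestamps (one-sided at the
endpoints — exact for linear signals, second-order otherwise).  Whether a
robot logs velocities or only positions varies by device, so both paths
are first-class and tested.

Repetitions within a direction are averaged arithmetically.  A speed-peak
count (local maxima with prominence ≥ 5% of peak speed, configurable) is
kept in the exploratory panel but is not among the selected predictors.

## Outcome models and validation

For each outcome (Motricity Index elbow-flexion and shoulder-abduction
sub-items, 0–33; upper-limb total, 1–100) the model is ordinary least
squares on the standardized kinematic metrics (`mpe_a`, `mpe_c`, `mpe_d`,
`ms_b`) adjusted for age, sex (0/1 indicator), stroke-onset days and the
admission score of the same outcome — eight predictors.  Age, onset time
and the kinematic metrics are z-scored with the sample (n−1) standard
deviation; the transform is stored so new cases can be projected.  By
default the transform is estimated once on the full cohort before any
modelling; `standardize_scope="train"`/`"fold"` re-estimates it inside the
split or fold for a strictly leakage-free variant.  The default follows
the procedure order of standardizing before modelling; the caveat is that
held-out records then contribute to the scaling constants — a negligible
but nonzero information flow, which is why the stricter option exists.

**Predictor selection** is backward elimination at α = 0.05: refit,
drop the least-significant kinematic predictor with p above the threshold,
repeat.  The clinical covariates are kept by default (they encode the
adjustment, not the hypothesis); `eliminable` widens the search if desired.
The route from an adjusted multi-predictor fit to a single-predictor final
model is not uniquely determined by the reported end points; backward
elimination is the declared convention here.

**Split-sample validation** draws a uniform random 75/25 partition
(training size rounded half up: 66 → 50/16).  Exchangeability of the two
sets is checked per variable — chi-square for categorical variables
(Fisher's exact test when a 2×2 expected cell count falls below one; empty
levels dropped), and for continuous variables ANOVA when both sets pass a
Shapiro-Wilk normality pre-test at α = 0.05, otherwise Mann-Whitney — plus
a four-group battery: the cohort is split into random quarters and every
pair of quarters is compared by Kruskal-Wallis with Bonferroni correction
(raw p × 6 pairs, capped at 1).  The choice of Shapiro-Wilk as the
normality gate is a convention and is recorded in the report table.

**Leave-one-out cross-validation** fits the fixed eight-predictor design n
times, each fit predicting its held-out record; the evaluation panel is
computed on the n pooled out-of-fold predictions (adjusted R² uses p = 8).
The deployable `final_model` is the full-data fit reduced by backward
elimination.  Keeping the design fixed across folds makes the procedure
exactly equivalent to the hat-matrix identity
`e_loo,i = e_i / (1 − h_ii)`, which the tests exploit as an independent
oracle.

## Evaluation panel

RMSE and MAE in score points; `RMSE_n = 100·RMSE/(scale range)`;
`MAE_n = 100·MAE/denominator` with the denominator selectable between the
mean observed discharge score (default) and the scale range — the two
conventions answer different questions ("error relative to typical score"
vs "error relative to scale") and both appear in practice, so the choice
is explicit and recorded.  R² is 1 − SSE/SST around the observed mean
(negative values are possible and meaningful on held-out data);
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).

Because therapists can only award discrete scores, continuous predictions
are corrected to the nearest attainable score before rank correlation:
sub-item classes {0, 9, 14, 19, 25, 33} (the standard Motricity Index
values; configurable in `MIScale`), totals the attainable sums plus one.
Exact ties snap to the lower score so the correction never inflates
predicted recovery.  The error metrics are computed on the uncorrected
predictions; only the Spearman stage uses the snapped ones.  Spearman uses
mid-ranks for ties with the t-approximation p-value; when every snapped
prediction collapses to one class, the correlation is undefined and
reported as NaN rather than a number.  The strength rubric is
|r| ≤ 0.3 very weak, ≤ 0.5 weak, ≤ 0.7 moderate, ≤ 1 strong (the nominal
0.30–0.31 gap in the conventional rubric closes upward).

Reported normalized RMSE values are rounded half-up to integers for
sub-items and to one decimal for the total, matching the finer scale.

## Synthetic cohort generator

The generator's role is to realize the statistical structure the analysis
assumes, not to simulate robotic therapy.  Each patient carries a latent
impairment `u ~ Uniform(0, 1)`:

* **Baseline scores**: ability `1 − u` is quantile-binned into the six
  sub-item classes after adding Gaussian misclassification jitter
  (`class_noise`, default SD 0.08 on the latent scale — roughly "one
  class boundary in three patients"); the total adds an independently
  binned pinch sub-item plus one.  At `class_noise = 0` the extremes map
  exactly: `u = 0` → 33 per sub-item (total 100), `u = 1` → 0 (total 1).
* **Kinematic metrics**: each direction receives its own jittered latent
  (`direction_noise`, SD 0.15), mapped linearly to a path error in
  `mpe_range = (0.005, 0.040)` m (rising with impairment) and a mean speed
  in `ms_range = (0.06, 0.30)` m/s (falling), then multiplied by
  log-normal measurement noise (`metric_noise`, SD 0.10).  The per-direction
  jitter keeps the four metrics correlated through the shared impairment
  (pairwise r ≈ 0.8) without being collinear, matching how kinematic
  panels behave in practice.
* **Discharge scores**: the path error toward the body is standardized
  across the cohort and fed through each outcome's linear relation
  (defaults: the published coefficients) plus Gaussian noise
  (`noise_sd`, defaults ELBOW 3.0 / SHOULDER 3.5 / UL 7.0 points, chosen
  so the fitted models explain roughly 60–75% of discharge variance, the
  regime this method operates in), clamped to the scale range and snapped
  to the nearest attainable score.  Snapping makes the correction and
  rank-correlation stages of the pipeline meaningful on synthetic data.

Demographics (age 64.97 ± 12.75 y clipped to 18–95, 66.7% male, 59.1%
right-affected, onset 15.27 ± 18.07 d floored at 1, 71.2% ischemic) mirror
the reference population's marginals.

**Trajectories** realize the prescribed metrics analytically.  The chord
progress follows a minimum-jerk profile (the standard point-to-point
reaching model); the lateral deviation is a half-sine *in time* with
amplitude `a = π·MPE/2`, because the time-average of `|a sin(πt/T)|` is
exactly `2a/π` — the prescribed path error.  The duration is set from a
dense quadrature of the speed profile so the time-averaged speed equals
the prescribed mean speed.  Samples are placed at interval midpoints (the
recorder's clock is not phase-locked to the movement), which keeps the
discrete time-averages within O(n⁻²) of their integrals; with
endpoint-inclusive sampling the zero-speed rest points would bias the
mean speed by a factor (n−1)/n, a 1.8% error at the shortest movements.
Target distance defaults to 0.14 m (typical of planar centre-out
protocols; the value scales the metrics but not the structure).
Generation is deterministic given its parameters; cohort-level randomness
comes from one master seed via spawned, order-stable child streams, so
identical configurations are bitwise-reproducible.

What the generator does **not** emulate: robot assistance forces, 3D or
multi-joint kinematics, submovement segmentation, session-to-session
learning, score ceilings induced by comorbidity, or any dependence of
discharge scores on variables other than `MPE_C`.  Passing tests therefore
demonstrate that the pipeline's procedures are correct and recover known
structure — not that real cohorts satisfy the single-predictor model.

## Numerical choices, degenerate inputs, limitations

* Standardization refuses constant (zero-SD) variables by name; splits
  need n ≥ 4, LOOCV n ≥ 3; OLS requires more observations than parameters
  and raises on rank-deficient designs, listing the collinear columns.
* Sub-item recovery at very low residual noise is biased: with residual SD
  ≈ 1 point, snapping the generated means onto the six-class grid (gaps of
  5–9 points) attenuates the fitted slope by ≈ 0.3–0.5 points, more than
  two standard errors.  At residual scales of ≈ 5 points — where the
  models' reported errors actually live — the quantization dithers away
  and coefficients are recovered unbiasedly.  The fine-grained total scale
  is essentially free of this effect.  This is a property of discretized
  linear generation, worth keeping in mind when simulating ordinal scales.
* ANOVA on numerically identical groups can produce a floating-point
  negative F and an undefined p; the balance battery reports p = 1 there.
* The four-group Kruskal-Wallis battery interprets "no difference between
  any combination of groups" as all pairwise comparisons; the grouping is
  seeded and reported.
* Problem sizes in the test suite (cohorts of 66, 100 replicate cohorts
  per recovery setting, 30 for the bias check, a 5×5×4×2 trajectory grid)
  are chosen to estimate the statistical properties tightly while keeping
  the default suite in the minutes range.
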