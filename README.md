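# rmkpredict

Predicting discharge upper-limb muscle strength in subacute stroke from
**baseline robot-measured kinematics**.

After a stroke, most patients show pathological flexor synergy: elbow
flexion couples with shoulder movements, degrading goal-directed reaching.
Planar end-effector rehabilitation robots record every point-to-point
movement a patient makes, and the quality of those baseline movements
carries prognostic information.  `rmkpredict` implements a complete,
testable pipeline for that analysis, aimed at rehabilitation researchers
working with robot-recorded reaching data:

* **Kinematic metrics.** Each movement runs from a central target to a
  peripheral target on the axes of a lesion-side-aligned frame (direction
  A away from the body, C toward it, D lateral, B medial; left-affected
  recordings are mirrored in x).  Two metrics summarise a movement of
  N samples:

  - Movement Path Error, the mean distance from the ideal straight line —
    `MPE = (1/N) Σ |y[k]|` for direction D and `(1/N) Σ |x[k]|` for A and C;
  - mean Movement Speed, `MS = (1/N) Σ sqrt(vx[k]² + vy[k]²)`.

  The selected predictor panel is `MPE_A`, `MPE_C`, `MPE_D`, `MS_B`;
  `MPE_C` — the error of the movement toward the body, the one most
  affected by flexor synergy — is the clinically decisive one.

* **Outcome models.** Least-squares linear regression of the discharge
  Motricity Index (elbow-flexion and shoulder-abduction sub-items on 0–33;
  upper-limb total on 1–100) on the standardized kinematic metrics,
  adjusted for age, sex, stroke-onset time and the admission score.
  Validation by a 75/25 split-sample procedure (with a chi-square /
  ANOVA / Mann-Whitney / Kruskal-Wallis balance-test battery) and by
  leave-one-out cross-validation.  Non-significant kinematic predictors are
  removed by backward elimination at α = 0.05.

* **Discrete-scale evaluation.** RMSE / MAE with normalized percentages,
  R² / adjusted R², nearest-neighbour snapping of continuous predictions to
  the attainable Motricity scores (sub-item classes {0, 9, 14, 19, 25, 33};
  total = sub-items + 1), and Spearman correlation with a verbal strength
  rubric.

* **Synthetic cohorts.** Because clinical trajectory data are rarely
  shareable, a generator produces cohorts with the same statistical
  structure — demographics, six-class baseline scores, trajectories whose
  path error and speed are prescribed, and discharge scores following the
  published single-predictor relations — so the entire pipeline is testable
  end to end from a seed.

The published final models encoded in the package (score points per SD of
baseline `MPE_C`):

```
MI_ELBOW(T2)    = 12.99 −  4.89 · MPE_C(T1)
MI_SHOULDER(T2) = 13.70 −  4.26 · MPE_C(T1)
MI_UL(T2)       = 32.50 − 11.99 · MPE_C(T1)
```

## Worked example

Simulate a 66-patient cohort and run both validation procedures:

```bash
$ rmkpredict simulate --out wk/data --seed 7
simulate: wrote 66 patients (264 trajectories) to wk/data [seed=7, config=81dbc7a5be26a648]

$ rmkpredict run --data wk/data --out wk/report --mode both --seed 7
SSV ELBOW: RMSE=3.605 RMSE_n=11% R2=0.548 r=0.800 (strong)
SSV SHOULDER: RMSE=4.790 RMSE_n=15% R2=0.446 r=0.764 (strong)
SSV UL: RMSE=6.604 RMSE_n=6.7% R2=0.720 r=0.890 (strong)
LOOCV ELBOW: RMSE=3.752 RMSE_n=11% R2=0.555 r=0.742 (strong)
LOOCV SHOULDER: RMSE=4.230 RMSE_n=13% R2=0.412 r=0.688 (moderate)
LOOCV UL: RMSE=6.623 RMSE_n=6.7% R2=0.726 r=0.870 (strong)
```

Each line is one outcome on one validation set: the prediction error in
score points (RMSE) and as a percentage of the scale range (RMSE_n), the
variance explained (R²), and the Spearman correlation between the
therapist-assigned discharge scores and the model predictions snapped to
the attainable discrete scores, with its strength label.  `wk/report/`
then contains `report.json` (full metric panels, fitted coefficients,
split membership, balance tests) and `report.md`, whose final table
compares the refitted models against the published coefficients — here the
fit on the simulated cohort recovers them closely:

```
| Outcome | Intercept (fitted / published) | MPE_C slope (fitted / published) |
|---|---|---|
| ELBOW | 13.10 / 12.99 | -4.77 / -4.89 |
| SHOULDER | 13.13 / 13.70 | -3.81 / -4.26 |
| UL | 31.73 / 32.50 | -11.19 / -11.99 |
```

The same pipeline is available as a library (`generate_cohort`,
`extract_features`, `run_ssv`, `run_loocv`, `evaluate_predictions`, …); see
`docs/methods.md` for the modelling details and design choices.

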