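# dmdwalk

Individualized prognosis of ambulatory decline in Duchenne muscular dystrophy
(DMD). The package models the **annualized 1-year change in six-minute walk
distance** (Δ6MWD, m/year) from routinely collected clinic measures — age,
baseline 6MWD, steroid exposure, height/weight/BMI and the three timed
function tests (rise from supine, 10 m walk/run, 4-stair climb) — and
quantifies how much a composite prognostic score shrinks the unexplained
outcome variance that plagues DMD trial design.

It is written for biostatisticians and trialists working with longitudinal
natural-history data: visit-level tables in, fitted models, validated
predictive performance, risk strata and sample-size implications out.

## The model

For patient *i* with follow-up intervals *j* (all visit pairs 8–16 months
apart, baseline 6MWD > 0, baseline measures complete):

```
Δ6MWD_ij = (6MWD at follow-up − 6MWD at baseline) / elapsed years
Δ6MWD_ij = x_ij' β + ε_ij
```

estimated by **generalized estimating equations** with an exchangeable
working correlation (any two intervals of the same boy share correlation ρ),
scale φ estimated by moments, and robust (sandwich) covariance `A⁻¹BA⁻¹` for
inference. Timed tests enter as two parts: an ability indicator, plus the
time in seconds set to 0 when the test cannot be completed.

Predictive value is reported as `RMSE` (the SD of observed − predicted
Δ6MWD) and `R² = 1 − (RMSE / SD(Δ6MWD))²`, estimated honestly by repeated
80/20 **patient-level** cross-validation (all intervals of a boy stay on one
side of the split) with percentile confidence limits from bootstrapping
patients with replacement. A two-arm power formula
`n = 2σ²(z_{1−α/2}+z_{power})²/δ²` translates residual SD into trial size.

Because the underlying clinical dataset is not public, the package ships a
calibrated synthetic cohort generator (`dmdwalk.cohort`) reproducing the
published natural-history profile: ~39 boys, visits every ~6 months over
2–5 years, mean Δ6MWD ≈ −37 m/year (SD ≈ 94), ~12–13 % of intervals ending
in loss of ambulation.

## Worked example

```python
from dmdwalk import (SimConfig, simulate_cohort, build_intervals, MODEL2,
                     ExchangeableGEE, evaluate, cross_validate, bootstrap_cv_ci)

visits, _ = simulate_cohort(SimConfig(seed=1))          # 39 simulated boys
intervals = build_intervals(visits)                      # 198 usable intervals
res = ExchangeableGEE.from_intervals(intervals, MODEL2).fit()
print(res.summary())
cv = cross_validate(intervals, MODEL2, n_splits=200, seed=1)
ci = bootstrap_cv_ci(intervals, MODEL2, n_boot=200, n_splits_inner=25, seed=1)
```

prints (abridged):

```
Model 2: linear GEE, exchangeable working correlation
  clusters: 34   observations: 198
  rho = 0.1412   scale = 1496.27   iterations = 10   converged = True
                 estimate  robust_se   ci_lower   ci_upper    p_value
baseline_6mwd     -0.6331     0.1046    -0.8381    -0.4282     0.0000  ***
tft_able_rise    168.9848    26.3943   117.2529   220.7168     0.0000  ***
tft_time_rise    -18.4816     3.2901   -24.9301   -12.0331     0.0000  ***
tft_able_4sc     208.9512    38.8944   132.7195   285.1828     0.0000  ***
tft_time_4sc     -12.5691     4.2882   -20.9738    -4.1644     0.0034   **
...
in-sample RMSE = 37.6 m, R2 = 0.66
cross-validated RMSE = 42.2 m (95% CI 29.8-51.5), R2 = 0.57
```

Read: on this simulated cohort the broad model explains about two thirds of
the outcome variance in-sample and 57 % after patient-level cross-validation;
being unable to rise or climb stairs, slower completion times, and (given
the other covariates) a higher baseline 6MWD all predict faster decline —
the same qualitative picture as the conventional-factors-only model cannot
reach (R² ≈ 0.16 here).

## Command line

```
dmdwalk simulate --seed 1 --n-patients 39 --outdir out
dmdwalk fit out/visits.csv --model model2
dmdwalk validate out/visits.csv --seed 1
dmdwalk stratify out/visits.csv
dmdwalk ledger out/visits.csv
dmdwalk power --sigma 60 --sigma 80
dmdwalk run --seed 1 --outdir out        # full pipeline + manifest
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch at the given seed — simulation,
interval construction, the three model fits, 200-split cross-validation, the
reduced bootstrap (200 × 25), stratification, ledger and power curve — and
writes the results JSON; pipeline artifacts land under
`scratch/acceptance_run_seed<seed>/`.

## Layout

| module | contents |
| --- | --- |
| `dmdwalk.cohort` | synthetic cohort generator (mechanistic + linear-truth modes) |
| `dmdwalk.intervals` | 8–16 month interval construction, annualized outcome |
| `dmdwalk.design` | model specs, two-part TFT encoding, design matrices |
| `dmdwalk.gee` | `ExchangeableGEE` / `GEEResults` (the estimator) |
| `dmdwalk.evaluation` | RMSE/R², patient-level CV, bootstrap-of-CV |
| `dmdwalk.descriptives` | Pearson correlation report, variable ledger |
| `dmdwalk.strata` | quartile stratification of predicted Δ6MWD |
| `dmdwalk.power` | sample-size curves vs residual SD |
| `dmdwalk.pipeline` / `dmdwalk.cli` | end-to-end runs, artifacts, CLI |

See `docs/methods.md` for modelling assumptions, numerical conventions and
the limits of what the synthetic cohort can establish.
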