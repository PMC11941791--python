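# fdmort

Age-specific mortality forecasting with functional demographic models.

National statistical offices publish death rates m_{x,t} for abridged age
groups x (0, 1–4, 5–9, …, 80–84, 85+) and calendar years t.  Forecasting
that surface a decade ahead underpins health-system planning, pension
actuarial work and epidemiological projections.  `fdmort` is aimed at
biostatisticians and demographers who need those forecasts from short
(20–35 year) national series, where long-run trends differ sharply between
child and adult ages.

## Models

**Lee–Carter** — the log-bilinear baseline

    log m_{x,t} = a_x + b_x k_t + ε_{x,t}

with a_x the age profile, b_x age sensitivities and k_t a single period
index, estimated by SVD of the centered log-rate matrix (identification
Σb_x = 1, Σk_t = 0) and extrapolated by automatic ARIMA.

**Functional data model (Hyndman–Ullah style)** — the K-component extension

    log m(x, t) = μ(x) + Σ_{k≤K} β_k(x) κ_{k,t} + ε(x, t)

via functional principal component analysis with a selectable smoothing
basis (data-driven, B-spline, Fourier, natural cubic spline).  Scores
κ_{k,t} are forecast by any of five univariate methods — auto-ARIMA, ETS,
linear regression (LR), linear regression plus ARIMA residuals (LR+A), or
a penalized-spline GAM — or regressed on exogenous covariates (two-step
functional principal component regression with LMG contribution shares and
case-resampling bootstrap).

**Subpopulation pipeline** — child groups (0, 1–4, 5–9, 10–14) follow
near-linear log declines while adult trends are nonlinear, so a joint
functional fit blends the two sources and extrapolates poorly.  The
pipeline models the adult block functionally, selects a forecaster per
child group by held-out mean APE, merges the forecasts and scores them
with APE/MAPE accuracy tables.

A seeded synthetic-data module generates mortality surfaces with exactly
this structure (plus pandemic-style outlier years and macro covariates),
so every stage is testable without external downloads.

## Worked example

```python
import numpy as np
import fdmort as fm

years = np.arange(1991, 2024)                      # 33-year surface
surface, exog = fm.study_scenario(years, seed=1)   # 19 age groups
cfg = fm.PipelineConfig(seed=1, horizon=10)
res = fm.run_pipeline(cfg, surface=surface)

print("train MAPE %.2f%%  test MAPE %.2f%%"
      % (res.accuracy_train.overall, res.accuracy_test.overall))
print("variance explained (%):",
      [round(p, 1) for _, p in res.run_log["variance_table"]])
for lab, sel in res.child_selections.items():
    print(f"  child {lab}: {sel['method']} "
          f"(test MAPE {sel['candidate_mape'][sel['method']]:.2f}%)")
print("2033 infant rate forecast: %.5f" % res.forecast_future.rates[0, -1])
print("2023 actual infant rate:   %.5f" % surface.rates[0, -1])
```

Output:

```
train MAPE 1.57%  test MAPE 14.20%
variance explained (%): [96.6, 0.7, 0.6]
  child 0: gam (test MAPE 5.96%)
  child 1-4: lr (test MAPE 6.77%)
  child 5-9: gam (test MAPE 3.71%)
  child 10-14: lr (test MAPE 8.48%)
2033 infant rate forecast: 0.00713
2023 actual infant rate:   0.01037
```

Reading it: the adult functional fit reproduces the training frame to
1.6% mean absolute percentage error, with the first principal component
carrying 96.6% of the variance in the adult block.  On the 2014–2023
hold-out the merged forecast averages 14.2% error across the 19 groups —
the child groups, handled by per-group linear/GAM models, sit well below
that.  The 10-year projection continues the child decline: the infant
rate falls from 0.0104 in 2023 to a forecast 0.0071 in 2033.

The same workflow runs from the shell:

```
fdmort simulate --outdir data --seed 1
fdmort fit-lc data/rates.csv --outdir out --horizon 10
fdmort fit-hu data/rates.csv --components 3 --outdir out
fdmort run --config config.yaml     # full split pipeline
```

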