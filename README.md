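# mpalss

Limited sampling strategies (LSS) for estimating mycophenolic acid (MPA)
exposure — the area under the serum concentration-time curve over one
12-hour dosing interval, AUC(0-12) — in renal-transplant recipients on
twice-daily mycophenolate mofetil (MMF).

Full AUC monitoring needs nine blood samples and a 12-h hospital stay.  An
LSS replaces it with an affine estimator on a few early samples,

    AUC_est = b0 + b1*C(t1) + ... + b4*C(t4),      t_j <= 6 h post-dose,

fitted by least squares against the measured trapezoidal AUC.  Because MPA
clearance falls over the weeks after transplantation, a single pooled
equation ("Method A") competes here against a pair of equations stratified
by postoperative day, POD < 31 vs POD >= 31 ("Method B").  The package
provides:

* non-compartmental AUC(0-12) (linear trapezoid), oral clearance CL/F, and
  POD classification (`mpalss.nca`, `mpalss.profiles`);
* a calibrated steady-state PK simulator with enterohepatic recirculation
  and POD-dependent disposition, standing in for the unavailable clinical
  cohort (`mpalss.simulate`);
* exhaustive and stepwise sampling-scheme searches with OLS equation
  fitting, plus the published equations as a fixed registry (`mpalss.lss`);
* validation metrics — RMSE, R^2 with the estimated-on-measured fit line,
  Spearman rank correlation, leave-one-out q^2/PRESS, delta-AUC — and the
  nonparametric group tests (Wilcoxon signed-rank, Kruskal-Wallis with
  Holm-adjusted pairwise comparisons) (`mpalss.metrics`);
* a statsmodels-style `LimitedSamplingModel` / `LimitedSamplingResults`
  interface, a one-command study pipeline, and the `lss` CLI
  (`mpalss.model`, `mpalss.study`, `mpalss.cli`).

See `docs/methods.md` for the model, its assumptions and its limitations.

## Worked example

```python
from mpalss import LimitedSamplingModel, default_config, simulate_cohort

cfg = default_config()
profiles = (simulate_cohort(39, "LT31", cfg, seed=42)    # POD < 31 arm
            + simulate_cohort(61, "GE31", cfg, seed=42)) # POD >= 31 arm

model = LimitedSamplingModel(profiles, stratify="pod31")
results = model.fit()          # exhaustive search over all 35 four-point schemes
print(results.summary())
```

```
Limited sampling strategy fit (method=exhaustive, criterion=max_r2, k=4, stratify=pod31)
          n         times_h                                              equation  RMSE     R2     q2  median dAUC
stratum
GE31     61  {0.5, 2, 3, 4}  3.58 + 9.38*C0.5h + 1.31*C2h + -8.39*C3h + 14.91*C4h  6.82  0.760  0.709         4.74
LT31     39    {0, 1, 3, 6}   17.71 + -9.16*C0h + 14.10*C1h + 0.79*C3h + 7.61*C6h  4.40  0.943  0.906         3.26
```

Each row is one POD stratum: the selected four sampling times, the fitted
equation, the root-mean-square error and R^2 of its in-sample estimates
(ug.h/mL and unitless), the leave-one-out q^2 (reliability: how well the
scheme predicts held-out profiles), and the median absolute estimation
error.  The early-POD stratum keeps the pre-dose trough and the 6-h sample;
the late stratum is harder to estimate here because the simulated
recirculation peak falls after the 6-h sampling horizon.

The full study comparison — pooled vs stratified on the same cohort:

```python
from mpalss.study import run_study
report = run_study(config=cfg, seed=42)
d = report.delta_comparison
print(f"median |dAUC|  A: {d['method_a']['median']:.2f}  "
      f"B: {d['method_b']['median']:.2f}  p = {d['wilcoxon_p']:.4f}")
```

```
median |dAUC|  A: 5.02  B: 4.19  p = 0.0101
```

POD stratification lowers the median absolute AUC estimation error from
5.0 to 4.2 ug.h/mL on this cohort, and the paired Wilcoxon test calls the
per-profile improvement significant.

The same pipeline from the shell:

```bash
lss simulate --n-lt31 39 --n-ge31 61 --seed 42 --out cohort.csv
lss develop  --input cohort.csv --stratify pod31 --out equations.json
lss run      --simulate --seed 42 --out report.json
lss eval-published --input cohort.csv --out published.json
```

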