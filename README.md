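# lcmort

Stochastic mortality modelling and life-expectancy projection for
populations with **limited death data** — sparse age×year death counts,
old-age observations available only in census years, occasional zero or
missing cells.  The package is aimed at demographers, actuaries and
longevity-risk analysts who need a complete, reproducible pipeline from a
raw deaths/exposures matrix to projected age-specific mortality and period
life expectancy.

## The model

Central death rates m(x, t) = D(x, t)/N(x, t) follow the single-factor
Lee-Carter model

    ln m(x, t) = α(x) + β(x)·κ(t),      Σₓ β(x) = 1,  Σₜ κ(t) = 0,

with α the age profile of log mortality, β the age-specific sensitivity to
the period index κ.  Because sparse data defeat the classical SVD estimator
(missing and zero cells have no logarithm), deaths are modelled as

    D(x, t) ~ Poisson( N(x, t) · exp(α(x) + β(x)·κ(t)) ),

and the weighted log-likelihood Σ w(x, t)·[D·(α+βκ) − N·e^{α+βκ}] is
maximised by cyclic Newton (Fisher-scoring) sweeps over the β, κ, α blocks,
with 0/1 cell weights w carrying the missing-data structure.  Around the
fitter sit four standard stages:

* **Gap-filling** — natural cubic splines of log rate against age, per
  calendar year, fill interior missing/zero cells;
* **Old-age extension** — the Kannisto logistic hazard
  u(x) = a·e^{bx}/(1 + a·e^{bx}), fitted on ages 60–89 by exact
  logit-linearisation, extends mortality to age 100 (conversions
  u = −ln(1−q), q = m/(1+0.5m));
* **Forecasting** — κ(t) is modelled as ARIMA(p, d, q) by exact Gaussian
  maximum likelihood and extrapolated (default order (1, 2, 1), no
  constant); future rates are exp(α + β·κ̂);
* **Life tables** — q = m/(1+0.5m), closure q = 1 at the final age, and
  period life expectancy eₓ = Σₖ ₖpₓ + ½ with ₖpₓ = Π(1−q).

A synthetic-data generator with known ground truth (bathtub baseline,
drifting random-walk κ, Poisson counts, census-style missingness) makes
every stage testable without any external data, and the bundled published
period-index series for China 1997–2019 verifies the forecasting stage.

## Worked example

```python
from lcmort import (SyntheticSpec, MissingnessSpec, generate_lc_surface,
                    apply_missingness, PipelineConfig, run_pipeline)

# a sparse surface shaped like the limited-data setting: 100 ages x 23
# years, ages 90+ observed only in four census years, 2% random dropout
spec = SyntheticSpec(n_ages=100, n_years=23, first_year=1997, seed=1,
                     missingness=MissingnessSpec(
                         oldage_start=90,
                         census_years=(2000, 2005, 2010, 2015),
                         random_missing_frac=0.02))
surface, truth, _ = generate_lc_surface(spec)
surface = apply_missingness(surface, spec)

cfg = PipelineConfig(out_dir="demo_out", horizon=20, holdout_years=3)
summary = run_pipeline(cfg, surfaces={"male": surface})
info = summary["sexes"]["male"]
print("kappa 2019:", round(info["kappa_last_fitted"], 2))
print("kappa 2039 forecast:", round(info["kappa_forecast_final"], 2))
print("e0 1997 / 2019 / 2039:",
      [round(info["life_expectancy"][y], 2) for y in (1997, 2019, 2039)])
print("holdout MAPE:", round(info["evaluation"]["holdout"]["mape"], 4))
```

prints

```
kappa 2019: -29.76
kappa 2039 forecast: -78.19
e0 1997 / 2019 / 2039: [65.45, 72.46, 77.49]
holdout MAPE: 0.0274
```

The period index falls by ~2.4/year and is extrapolated a further 20 years
by ARIMA(1,2,1); life expectancy at birth rises from 65.5 to 72.5 over the
fitted 1997–2019 window and to 77.5 by 2039; a 3-year holdout forecast of
age-specific rates is off by 2.7% on average.  `demo_out/` contains the
filled surfaces, α/β/κ tables with forecast intervals, projected rates,
life expectancies and the evaluation report.

The same pipeline runs from the shell on CSV inputs:

```bash
lcmort simulate --seed 1 --n-ages 100 --n-years 23 --oldage-start 90 \
    --census-years 2000,2005 --missing-frac 0.02 --out data/
lcmort run --config config.yaml --out results/
```

(`lcmort fill`, `extend`, `fit`, `forecast`, `lifetable`, `evaluate` expose
the individual stages.)

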