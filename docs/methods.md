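# Methods

## Data model

The pipeline operates on an age×year grid of death counts D and exposures
N (mid-year population standing in for person-years at risk), with a
boolean observation mask and a separate "imputed" mask for cells filled by
interpolation or model-based extension.  Counts are real-valued: source
scaling (census counts divided by 1000, 1%-sample counts by 10, optional
renormalisation of each year's total exposure to a fixed base such as one
million) produces non-integer deaths, and the Poisson machinery is simply
evaluated at those values.  Scaling a year's deaths and exposures by the
same factor leaves every central rate m = D/N unchanged, which is asserted
in the tests at 1e-12 relative.

## Gap-filling

Missing and zero-death cells are filled by a natural cubic spline of log
rate against age, fitted independently within each calendar year through
the observed positive cells.  Choices made here, and why:

* **Axis** — interpolation runs across ages within a year (a `fill_axis`
  option flips it) because whole old-age blocks are missing by year, so
  within-age series are the ones with structural holes.
* **Scale** — log rates, since mortality is positive and close to
  log-linear in age over most of the range.
* **Boundary** — only interior holes are splined.  Missing cells below the
  observed span take the nearest knot's value (constant extension, logged);
  cells above it are left for the old-age model, because a cubic
  extrapolated beyond age 89 is meaningless.
* **Spline** — natural (zero second derivative) boundary conditions: least
  oscillation, no extra parameters.  At least 4 knots per year are
  required; fewer is an error naming the year.

Zero-death cells are treated as missing for interpolation but remain
legitimate observations for the Poisson fit itself when left unfilled.

## Lee-Carter estimation

The log-likelihood (up to a constant) is
ℓ = Σ w·[D·(α+βκ) − N·e^{α+βκ}] with w ∈ {0,1}.  Starting from the
closed-form values α = weighted row mean of log rates, κ = weighted column
sum of centred log rates, β uniform, each sweep applies one Newton
(Fisher-scoring) step per block in the order β, κ, α, recomputing fitted
deaths D̂ = N·e^{α+βκ} after every block:

    β ← β + Σₜ w(D−D̂)κ / Σₜ w D̂ κ²
    κ ← κ + Σₓ w(D−D̂)β / Σₓ w D̂ β²
    α ← α + Σₜ w(D−D̂) / Σₜ w D̂

Each block's conditional likelihood is strictly concave, so a damped step
always decreases the total weighted Poisson deviance
2Σw·[D ln(D/D̂) − (D−D̂)]; the implementation halves a block's step until
it does, making the deviance trace provably non-increasing (raw steps can
overflow when an age's β overshoots — observed in practice on extended
surfaces).  After every sweep the identifiability constraints Σβ = 1,
Σκ = 0 are re-imposed by the exact reparameterisation
β′ = β/s, κ′ = s(κ−κ̄), α′ = α + βκ̄ (s = Σβ), which leaves fitted rates
bit-identical but removes a nearly flat translation/scale direction that
otherwise slows coordinate convergence by three orders of magnitude.
Convergence is declared when the deviance decrease per sweep falls below
`tol` (default 1e-6, absolute); `max_iter` defaults to 10000.  Typical
fits on 100×23 surfaces converge in 10–50 sweeps.

Degenerate inputs: an age row or year column with no weighted cells is
rejected (the corresponding parameter is unidentifiable); zero-death cells
in the initialisation are excluded from the closed-form means only.

## Old-age extension

The Kannisto hazard u(x) = a·e^{bx}/(1+a·e^{bx}) is logit-linear in age,
so a and b are estimated by ordinary least squares of logit(u) on x over
ages 60–89 — closed form, deterministic, and exact on model-generated data
(asserted at 1e-8 relative).  `x` is the actual age, not an offset, which
affects only the reported level.  An optional nonlinear least-squares
refinement on the q scale is available but not the default.  One fit is
made per calendar year; missing cells from age 90 to 100 are filled with
model values, observed old-age cells (census years) are kept by default
(`replace_all` overrides).  By default the extension is applied to the
data surface *before* Lee-Carter fitting (data completion); a
post-projection placement — extend each projected year's rate column
instead — is available, since the natural ordering is genuinely open.
Because the fitter needs counts, exposures for extended cells are
extrapolated log-linearly in age from the year's last ten observed
cohorts and deaths set to m·N; such cells are flagged imputed, and the
`use_imputed` policy (default: include) decides whether they carry weight.

## Period-index forecasting

κ̂ is fitted by exact Gaussian maximum likelihood (statespace
representation, via statsmodels) — deterministic given series and order.
A constant is included by default only for d ≤ 1, where it acts as a
drift; under d = 2 a constant would force an accelerating quadratic trend,
whereas published extrapolations of this kind settle to a constant yearly
decrement, which is the d = 2, no-constant signature.  Model selection,
when requested, screens p, q ∈ {0,1,2}, d ∈ {1,2}: candidates whose every
coefficient passes a two-sided t-test at the 5% level are ranked by AIC
(ties: fewer parameters, then lower d); if none passes, the best AIC among
converged fits is used.  The pipeline default is the fixed order (1, 2, 1).
Projected rates are exp(α + β·κ̂); no jump-off correction is applied, so a
forecast that repeats the last fitted κ reproduces the last fitted column
exactly.

## Life tables

q = m/(1+0.5m) (uniform deaths over the year; the algebraically identical
form 2m/(2+m) appears in some sources), table closure q = 1 at age 100,
and period life expectancy eₓ = Σₖ ₖpₓ + ½.  Life expectancy is a pure
function of one calendar year's rate column; no cohort tables, no open age
interval beyond the closure age, no fractional-age assumption beyond the
half-year term.

## Evaluation

MAPE = mean |actual − predicted|/actual over the supplied evaluation
cells, reported as a fraction; the evaluation window is a configuration
(the pipeline's default holdout refits on the first T−h years, forecasts
κ over the last h, and scores projected against observed rates).
Log-scale residual surfaces (observed − fitted) support the visual
randomness check.

## Synthetic data

The generator emulates the limited-data study design: default 90 (or 100)
single ages × 23 years; baseline log mortality is a bathtub — infant rate
0.005 falling log-linearly to a minimum of 5e-4 at age 8, then rising at
0.072/year (m(89) ≈ 0.17); β decays geometrically with age
(∝ e^{−x/30} + 0.3, normalised); κ is a random walk with drift −2.5/year
and innovation sd 2.0, centred after simulation so the returned truth is
normalised; exposures decline with age as 4·10⁶·e^{−x/40} + 10⁵ (order of
magnitude of large-country single-age cohorts; every cell ≥ 10⁵).  Deaths
are Poisson draws, optionally with log-normal overdispersion on the rate.
Missingness mimics census designs: ages ≥ 90 observed only in census
years, random cell dropout, zeroing of the lowest-count cells.  All
randomness flows from one integer seed; same seed, same surface.

What the generator does *not* emulate: age heaping and digit preference,
under-reporting that varies with age and sex, migration, cohort effects,
and sampling-design clustering.  Passing recovery tests therefore show
the estimator is correct under its own assumptions on realistically sized
data — not that real yearbook data meet those assumptions.

## Problem sizes and numerical tolerances in the test suite

The oracle-equivalence tests compare the Newton fitter's constrained
log-likelihood with an independent quasi-Newton maximiser over a free
parametrisation on 5×4 surfaces (where the 12-parameter problem is easy
for a generic optimiser), at 1e-6.  Recovery tests use the full 90×23
design with 20% dropout over 5 seeds.  Exact identities (conversion
round-trips, normalisation invariance, closed-form life expectancies) are
asserted at 1e-12; noiseless-data recoveries at 1e-6–1e-8.  The pipeline's
noiseless pass-through oracle (linear κ, exact Poisson means) uses a
tightened fit tolerance of 1e-13 because its 1e-8 life-expectancy
comparison propagates parameter error.

## Known limitations

* A single period factor: no cohort effects, no second age-period term,
  no multi-population coherence.
* The WLS/SVD estimator is deliberately not implemented; the Poisson MLE
  is the estimator of record here.
* Kannisto fits are independent across years; no smoothing of the level
  and slope paths over time.
* ARIMA on ~23 annual points estimates at most a handful of parameters
  reliably; forecast intervals are conditional on the chosen order and
  ignore model-selection uncertainty.
* Period life expectancy only; closure at age 100 slightly understates
  e₀ for populations with substantial survival past 100.
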