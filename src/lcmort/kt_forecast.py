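"""ARIMA modelling and forecasting of the Lee-Carter period index.

The period index kappa(t) is a short annual series (two dozen points here),
modelled as an ARIMA(p, d, q) process and extrapolated to obtain future
mortality via ln m(x, t) = alpha(x) + beta(x) * kappa_hat(t).  Estimation is
exact Gaussian maximum likelihood (statespace), which is deterministic
given the series and specification.  Model selection screens a small
(p, d, q) grid: candidates whose every ARMA coefficient passes a t-test are
ranked by AIC; if none passes, the minimum-AIC converged candidate is
returned with a flag.

A constant under d = 2 would impose an accelerating (quadratic) trend on
kappa; the default therefore includes a constant only for d <= 1, where it
acts as a drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.arima.model import ARIMA

from .lee_carter import LCParams
from .surfaces import RateSurface

__all__ = [
    "ArimaSpec",
    "ArimaFit",
    "KappaForecast",
    "ForecastError",
    "fit_arima",
    "select_arima",
    "forecast_kappa",
    "project_mortality",
    "default_grid",
]


class ForecastError(ValueError):
    pass


@dataclass(frozen=True)
class ArimaSpec:
    p: int
    d: int
    q: int
    include_constant: bool | None = None  # None -> True iff d <= 1

    def __post_init__(self):
        if min(self.p, self.d, self.q) < 0:
            raise ForecastError("ARIMA orders must be nonnegative")

    @property
    def constant(self) -> bool:
        if self.include_constant is None:
            return self.d <= 1
        return self.include_constant

    @property
    def n_params(self) -> int:
        return self.p + self.q + 1 + (1 if self.constant else 0)

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class ArimaFit:
    spec: ArimaSpec
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    constant: float
    innovation_variance: float
    loglik: float
    aic: float
    coeff_t_stats: dict
    residuals: np.ndarray
    n_obs: int
    _res: object = field(default=None, repr=False)


@dataclass
class KappaForecast:
    years: np.ndarray
    point: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    level: float | None = None


def _trend(spec: ArimaSpec):
    if not spec.constant:
        return "n"
    # a polynomial term of degree d survives d-fold differencing as a constant
    return [0] * spec.d + [1] if spec.d else "c"


def fit_arima(series, spec: ArimaSpec) -> ArimaFit:
    """Exact Gaussian MLE of an ARIMA(p, d, q), optionally with a constant.

    The constant is parameterised so that it remains a constant in the
    d-times-differenced series (a drift for d = 1).  Near-zero residual
    variance (an exactly trend-following series) is flagged degenerate.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ForecastError("series must be 1-d")
    if not np.all(np.isfinite(y)):
        raise ForecastError("series contains non-finite values")
    if y.size < spec.p + spec.q + spec.d + 2:
        raise ForecastError(
            f"series of length {y.size} too short for ARIMA{spec.order}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(y, order=spec.order, trend=_trend(spec))
        res = model.fit()
    params = dict(zip(res.param_names, res.params))
    tvals = dict(zip(res.param_names, res.tvalues))
    ar = np.array([params[f"ar.L{i}"] for i in range(1, spec.p + 1)])
    ma = np.array([params[f"ma.L{i}"] for i in range(1, spec.q + 1)])
    # the trend/constant parameter is whatever isn't an ARMA coefficient
    const_key = next((k for k in params
                      if not (k.startswith("ar.L") or k.startswith("ma.L")
                              or k == "sigma2")), None)
    sigma2 = float(params["sigma2"])
    if not np.isfinite(res.llf):
        raise ForecastError(f"ARIMA{spec.order} fit failed (non-finite loglik)")
    return ArimaFit(
        spec=spec,
        ar_coeffs=ar,
        ma_coeffs=ma,
        constant=float(params[const_key]) if const_key else 0.0,
        innovation_variance=sigma2,
        loglik=float(res.llf),
        aic=float(res.aic),
        coeff_t_stats={k: float(v) for k, v in tvals.items() if k != "sigma2"},
        residuals=np.asarray(res.resid)[spec.d:],
        n_obs=y.size,
        _res=res,
    )


def default_grid(max_p: int = 2, max_q: int = 2, ds=(1, 2)) -> list[ArimaSpec]:
    return [ArimaSpec(p, d, q) for d in ds for p in range(max_p + 1)
            for q in range(max_q + 1)]


def select_arima(series, grid=None, sig_level: float = 0.05) -> ArimaSpec:
    """Pick a specification by AIC among candidates passing a t-screen.

    Every AR/MA (and constant) coefficient must satisfy |t| >= the two-sided
    normal critical value at ``sig_level``; among those, lowest AIC wins,
    ties broken by fewer parameters then lower d.  If no candidate passes
    the screen the lowest-AIC converged candidate is returned (its spec is
    unchanged; callers can detect the situation by re-screening).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ForecastError("empty specification grid")
    crit = stats.norm.ppf(1 - sig_level / 2)
    fits = []
    for spec in grid:
        try:
            fit = fit_arima(series, spec)
        except (ForecastError, Exception):
            continue
        passes = all(abs(t) >= crit for t in fit.coeff_t_stats.values())
        fits.append((fit, passes))
    if not fits:
        raise ForecastError("no specification in the grid could be fitted")
    screened = [f for f, ok in fits if ok] or [f for f, _ in fits]
    screened.sort(key=lambda f: (f.aic, f.spec.n_params, f.spec.d))
    return screened[0].spec


def forecast_kappa(fit: ArimaFit, horizon: int, level: float = 0.95,
                   last_year: int | None = None) -> KappaForecast:
    """Point forecasts and prediction intervals ``horizon`` steps ahead."""
    if horizon < 1:
        raise ForecastError("horizon must be >= 1")
    if fit._res is None:
        raise ForecastError("fit carries no underlying results object")
    pred = fit._res.get_forecast(horizon)
    ci = pred.conf_int(alpha=1 - level)
    ci = np.asarray(ci)
    start = (last_year + 1) if last_year is not None else fit.n_obs
    return KappaForecast(
        years=np.arange(start, start + horizon),
        point=np.asarray(pred.predicted_mean),
        lower=ci[:, 0],
        upper=ci[:, 1],
        level=level,
    )


def project_mortality(params: LCParams, forecast: KappaForecast) -> RateSurface:
    """Projected central rates exp(alpha + beta * kappa_hat) for future years."""
    if params.alpha.shape != params.beta.shape:
        raise ForecastError("alpha/beta length mismatch")
    log_rates = params.alpha[:, None] + params.beta[:, None] * forecast.point[None, :]
    rates = np.exp(log_rates)
    A = params.alpha.size
    return RateSurface(
        ages=np.arange(A),
        years=np.asarray(forecast.years, dtype=int),
        rates=rates,
        log_rates=log_rates,
        observed_mask=np.ones_like(rates, dtype=bool),
    )


def project_mortality_ages(params: LCParams, forecast: KappaForecast,
                           ages) -> RateSurface:
    """As :func:`project_mortality` but with an explicit age axis."""
    rs = project_mortality(params, forecast)
    rs.ages = np.asarray(ages, dtype=int)
    return rs
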