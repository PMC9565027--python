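"""Weighted Poisson maximum-likelihood fitting of the Lee-Carter model.

The model is ``ln m(x, t) = alpha(x) + beta(x) * kappa(t)``: an age-specific
level, an age-specific sensitivity, and a single period index capturing the
common time trend of mortality.  Death counts are treated as Poisson,
``D(x, t) ~ Poisson(N(x, t) * exp(alpha + beta * kappa))``, and the
log-likelihood is maximised by cyclic Newton (Fisher-scoring) sweeps over
the three parameter blocks.  A 0/1 cell weight matrix carries the
missing-data structure: cells with weight 0 contribute nothing to the
likelihood, which is what makes the estimator usable on sparse survey data
where the classical SVD approach breaks down (missing or zero cells have no
logarithm).

Identifiability is imposed by the usual constraints sum(beta) = 1,
sum(kappa) = 0; any fit can be renormalised without changing the fitted
rate surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .surfaces import MortalitySurface, RateSurface, central_rates

__all__ = [
    "LCParams",
    "LCFit",
    "FitWeights",
    "LCFitError",
    "weights_from_mask",
    "init_lc",
    "poisson_deviance",
    "fit_lc_poisson",
    "normalize_lc",
    "fitted_log_rates",
]


class LCFitError(ValueError):
    pass


@dataclass
class LCParams:
    """Lee-Carter parameter vectors: alpha, beta over ages; kappa over years."""

    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.alpha.shape != self.beta.shape:
            raise LCFitError("alpha and beta must have equal length")

    def copy(self) -> "LCParams":
        return LCParams(self.alpha.copy(), self.beta.copy(), self.kappa.copy())


@dataclass
class LCFit:
    params: LCParams
    fitted_deaths: np.ndarray
    deviance: float
    deviance_trace: np.ndarray
    iterations: int
    converged: bool


@dataclass
class FitWeights:
    """0/1 cell weights; 1 = cell enters the likelihood, 0 = excluded."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if not np.all((self.w == 0) | (self.w == 1)):
            raise LCFitError("weights must be 0 or 1")


def weights_from_mask(surface: MortalitySurface, use_imputed: bool = False) -> FitWeights:
    """Weights from the surface's observation structure.

    Observed cells get weight 1; imputed (gap-filled) cells get weight 1
    only if ``use_imputed``; structurally missing cells get 0.  Every age
    row and year column must retain at least one weighted cell, otherwise
    the corresponding parameter is unidentifiable.
    """
    w = surface.observed_mask.astype(float)
    if use_imputed:
        w = np.maximum(w, surface.imputed_mask.astype(float))
    _check_identifiable(w, surface)
    return FitWeights(w)


def _check_identifiable(w: np.ndarray, surface: MortalitySurface | None = None):
    empty_rows = np.flatnonzero(w.sum(axis=1) == 0)
    empty_cols = np.flatnonzero(w.sum(axis=0) == 0)
    if empty_rows.size or empty_cols.size:
        ages = surface.ages[empty_rows] if surface is not None else empty_rows
        years = surface.years[empty_cols] if surface is not None else empty_cols
        raise LCFitError(
            "unidentifiable fit: no weighted cells for ages "
            f"{[int(a) for a in ages]} / years {[int(y) for y in years]}"
        )


def init_lc(rate_surface: RateSurface, weights: FitWeights) -> LCParams:
    """Closed-form starting values: alpha = weighted row mean of log rates,
    kappa = weighted column sum of (log rate - alpha), beta uniform 1/A;
    the result is returned in normalised form."""
    w = weights.w
    logm = rate_surface.log_rates
    if np.any(~np.isfinite(logm[w > 0])):
        raise LCFitError("non-finite log rate at a weighted cell")
    lw = np.where(w > 0, logm, 0.0)
    alpha = lw.sum(axis=1) / w.sum(axis=1)
    kappa = ((lw - np.where(w > 0, alpha[:, None], 0.0)) * 1.0).sum(axis=0)
    A = alpha.size
    beta = np.full(A, 1.0 / A)
    return normalize_lc(LCParams(alpha, beta, kappa))


def poisson_deviance(D: np.ndarray, Dhat: np.ndarray, weights: FitWeights) -> float:
    """Total weighted Poisson deviance 2*sum w*[D ln(D/Dhat) - (D - Dhat)].

    The D = 0 cell term reduces to 2*w*Dhat.  Zero iff D = Dhat on every
    weighted cell.
    """
    w = weights.w
    D = np.asarray(D, dtype=float)
    Dhat = np.asarray(Dhat, dtype=float)
    if np.any(Dhat[w > 0] <= 0):
        raise LCFitError("fitted deaths must be positive on weighted cells")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(D, D) - xlogy(D, Dhat) - (D - Dhat)
    return float(2.0 * np.sum(w * np.where(w > 0, terms, 0.0)))


def log_likelihood(D, N, params: LCParams, weights: FitWeights) -> float:
    """Weighted Poisson log-likelihood sum w*[D*eta - N*exp(eta)], eta =
    alpha + beta*kappa (the additive constant independent of the parameters
    is omitted)."""
    eta = fitted_log_rates(params)
    w = weights.w
    return float(np.sum(w * (np.asarray(D) * eta - np.asarray(N) * np.exp(eta))))


def _fitted_deaths(N, params: LCParams) -> np.ndarray:
    return N * np.exp(fitted_log_rates(params))


def fit_lc_poisson(surface: MortalitySurface, weights: FitWeights,
                   tol: float = 1e-6, max_iter: int = 10000) -> LCFit:
    """Fit by cyclic one-step Newton updates of beta, kappa, alpha.

    Each sweep updates one block at a time with a Fisher-scoring step,
    recomputing the fitted deaths Dhat = N*exp(alpha + beta*kappa) after
    every block; iteration stops when the decrease in total weighted
    deviance falls below ``tol``.  If a sweep would increase the deviance
    the step is geometrically damped, keeping the trace non-increasing.
    The returned parameters are normalised (sum beta = 1, sum kappa = 0),
    which leaves the fitted surface unchanged.
    """
    if tol <= 0 or max_iter <= 0:
        raise LCFitError("tol and max_iter must be positive")
    w = weights.w
    if w.shape != surface.shape:
        raise LCFitError("weights shape does not match surface")
    _check_identifiable(w, surface)
    D = surface.deaths
    N = surface.exposures
    if np.any(N[w > 0] <= 0):
        raise LCFitError("non-positive exposure at a weighted cell")

    params = _robust_init(surface, weights)
    trace = [poisson_deviance(D, _fitted_deaths(N, params), weights)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dev = _sweep(D, N, weights, params, trace[-1])
        if not (np.all(np.isfinite(params.alpha)) and np.all(np.isfinite(params.beta))
                and np.all(np.isfinite(params.kappa))):
            raise LCFitError(f"fit diverged (non-finite parameter) at iteration {it}")
        # re-imposing the constraints each sweep removes the flat
        # translation/scale directions without changing fitted rates
        if params.beta.sum() != 0:
            renorm = normalize_lc(params)
            params.alpha, params.beta, params.kappa = (
                renorm.alpha, renorm.beta, renorm.kappa)
            dev = min(dev, _safe_deviance(D, N, params, weights))
        trace.append(dev)
        if trace[-2] - trace[-1] < tol:
            converged = True
            break

    params = normalize_lc(params)
    dhat = _fitted_deaths(N, params)
    return LCFit(
        params=params,
        fitted_deaths=dhat,
        deviance=poisson_deviance(D, dhat, weights),
        deviance_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
    )


def _robust_init(surface: MortalitySurface, weights: FitWeights) -> LCParams:
    """Starting values; zero-death weighted cells (log undefined) are
    dropped from the closed-form averages only, not from the fit."""
    rates = central_rates(surface)
    w0 = weights.w * np.isfinite(rates.log_rates)
    try:
        _check_identifiable(w0, surface)
    except LCFitError:
        # a row/column is all zero-deaths: fall back to a global floor
        logm = np.where(np.isfinite(rates.log_rates), rates.log_rates, 0.0)
        floor = logm[w0 > 0].min() if np.any(w0 > 0) else -10.0
        rates.log_rates = np.where(np.isfinite(rates.log_rates), rates.log_rates, floor)
        w0 = weights.w
    rs = RateSurface(rates.ages, rates.years, rates.rates, rates.log_rates,
                     rates.observed_mask)
    return init_lc(rs, FitWeights(w0))


def _safe_deviance(D, N, params: LCParams, weights: FitWeights) -> float:
    """Deviance, or +inf when the candidate parameters over/underflow."""
    with np.errstate(over="ignore", under="ignore"):
        dhat = _fitted_deaths(N, params)
    if np.any(~np.isfinite(dhat[weights.w > 0])) or np.any(dhat[weights.w > 0] <= 0):
        return np.inf
    return poisson_deviance(D, dhat, weights)


def _block_step(D, N, weights, params: LCParams, attr: str, step: np.ndarray,
                dev: float, max_halvings: int = 60) -> float:
    """Apply one block's Newton step with geometric damping.

    Each block's conditional log-likelihood is concave, so a sufficiently
    damped Newton step always decreases the deviance; the raw step is tried
    first and halved until it does (keeping the trace monotone even when
    the undamped step would overflow)."""
    base = getattr(params, attr)
    scale = 1.0
    for _ in range(max_halvings):
        setattr(params, attr, base + scale * step)
        cand = _safe_deviance(D, N, params, weights)
        if cand <= dev + 1e-12:
            return cand
        scale *= 0.5
    setattr(params, attr, base)
    return dev


def _sweep(D, N, weights: FitWeights, params: LCParams, dev: float) -> float:
    """One cyclic Newton sweep (beta, kappa, alpha blocks), in place."""
    w = weights.w

    dhat = _fitted_deaths(N, params)
    resid = w * (D - dhat)
    den = (w * dhat * params.kappa[None, :] ** 2).sum(axis=1)
    num = (resid * params.kappa[None, :]).sum(axis=1)
    step = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    dev = _block_step(D, N, weights, params, "beta", step, dev)

    dhat = _fitted_deaths(N, params)
    resid = w * (D - dhat)
    den = (w * dhat * params.beta[:, None] ** 2).sum(axis=0)
    num = (resid * params.beta[:, None]).sum(axis=0)
    step = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    dev = _block_step(D, N, weights, params, "kappa", step, dev)

    dhat = _fitted_deaths(N, params)
    den = (w * dhat).sum(axis=1)
    num = (w * (D - dhat)).sum(axis=1)
    step = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return _block_step(D, N, weights, params, "alpha", step, dev)


def normalize_lc(params: LCParams) -> LCParams:
    """Re-impose sum(beta) = 1, sum(kappa) = 0 without changing fitted rates.

    With s = sum(beta) and kbar = mean(kappa): beta' = beta/s,
    kappa' = s*(kappa - kbar), alpha' = alpha + beta*kbar.
    """
    s = params.beta.sum()
    if s == 0:
        raise LCFitError("sum(beta) = 0: normalisation degenerate")
    kbar = params.kappa.mean()
    return LCParams(
        alpha=params.alpha + params.beta * kbar,
        beta=params.beta / s,
        kappa=s * (params.kappa - kbar),
    )


def fitted_log_rates(params: LCParams) -> np.ndarray:
    """The A x T matrix alpha[x] + beta[x] * kappa[t]."""
    return params.alpha[:, None] + params.beta[:, None] * params.kappa[None, :]
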