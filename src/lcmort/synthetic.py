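"""Synthetic mortality surfaces with known ground truth.

The generator emulates the data situation of a limited-data national
mortality analysis: ~90-100 single ages by ~23 calendar years, Poisson
death counts over a Lee-Carter log-mortality surface with declining period
index, old-age cells (90+) observed only in census years, and occasional
missing or zero cells elsewhere.  Ground-truth parameters are returned in
normalised form so recovery can be measured directly.

Baseline log mortality follows a "bathtub": high infant mortality falling
log-linearly to a childhood minimum, then rising log-linearly through the
senescent ages.  Exposures decline with age, as population cohorts do.
Defaults are documented, realistic orders of magnitude for a large national
population — not estimates for any particular country.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lee_carter import LCParams, normalize_lc
from .surfaces import MortalitySurface

__all__ = ["SyntheticSpec", "MissingnessSpec", "SyntheticError",
           "generate_lc_surface", "apply_missingness",
           "bathtub_alpha", "default_beta", "default_exposures"]


class SyntheticError(ValueError):
    pass


@dataclass
class MissingnessSpec:
    """Old-age truncation plus random cell dropout.

    Ages >= ``oldage_start`` are masked except in ``census_years`` (calendar
    years whose observation extends to the full age range); then a fraction
    of the remaining observed cells is masked at random, and a fraction of
    the lowest-count cells has its deaths zeroed (zero counts are real
    observations that nonetheless defeat log-scale estimation).
    """

    oldage_start: int = 90
    census_years: tuple = ()
    random_missing_frac: float = 0.0
    zero_inflation_frac: float = 0.0

    def __post_init__(self):
        for f in (self.random_missing_frac, self.zero_inflation_frac):
            if not (0.0 <= f <= 1.0):
                raise SyntheticError("missingness fractions must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic surface.

    alpha_shape = (infant m, childhood-minimum m, childhood-minimum age,
    senescent log-slope per year).  kappa follows a random walk with drift,
    centred after simulation so the truth satisfies the identifiability
    constraints.  extra_noise_sd adds optional log-normal overdispersion on
    top of Poisson sampling.
    """

    n_ages: int = 90
    n_years: int = 23
    first_year: int = 1997
    alpha_shape: tuple = (0.005, 5e-4, 8, 0.072)
    beta_shape: np.ndarray | None = None
    kappa_drift: float = -2.5
    kappa_sd: float = 2.0
    extra_noise_sd: float = 0.0
    exposure_level: np.ndarray | float | None = None
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_ages < 2 or self.n_years < 2:
            raise SyntheticError("need at least 2 ages and 2 years")
        if self.kappa_sd < 0 or self.extra_noise_sd < 0:
            raise SyntheticError("noise standard deviations must be nonnegative")


def bathtub_alpha(ages, infant=0.005, child_min=5e-4, child_age=8,
                  slope=0.072) -> np.ndarray:
    """Piecewise log-linear baseline: infant level falling to a childhood
    minimum at ``child_age``, then rising at ``slope`` per year of age."""
    x = np.asarray(ages, dtype=float)
    log_infant, log_min = np.log(infant), np.log(child_min)
    young = log_infant + (log_min - log_infant) * np.minimum(x, child_age) / child_age
    old = log_min + slope * np.maximum(x - child_age, 0.0)
    return np.where(x <= child_age, young, old)


def default_beta(n_ages: int) -> np.ndarray:
    """Age sensitivity: larger at young ages, decaying with age, sum 1."""
    x = np.arange(n_ages, dtype=float)
    b = np.exp(-x / 30.0) + 0.3
    return b / b.sum()


def default_exposures(ages) -> np.ndarray:
    """Cohort sizes declining with age: ~4e6 newborns to ~5e5 at age 89."""
    x = np.asarray(ages, dtype=float)
    return 4e6 * np.exp(-x / 40.0) + 1e5


def generate_lc_surface(spec: SyntheticSpec):
    """Simulate (surface, true LCParams, true future kappa path).

    kappa is a drifted random walk, centred to sum 0; beta is normalised to
    sum 1; deaths are Poisson with mean N * exp(alpha + beta*kappa [+ eps])
    where eps is optional N(0, extra_noise_sd^2) overdispersion.  A further
    20-step continuation of the same random walk is returned as the true
    future kappa path.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ages = np.arange(spec.n_ages)
    years = np.arange(spec.first_year, spec.first_year + spec.n_years)

    infant, child_min, child_age, slope = spec.alpha_shape
    alpha = bathtub_alpha(ages, infant, child_min, child_age, slope)
    beta = spec.beta_shape if spec.beta_shape is not None else default_beta(spec.n_ages)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.n_ages,) or np.any(beta < 0):
        raise SyntheticError("beta_shape must be a nonnegative vector over ages")
    beta = beta / beta.sum()

    steps = spec.kappa_drift + spec.kappa_sd * rng.standard_normal(
        spec.n_years + 20 - 1)
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    kappa, kappa_future = walk[: spec.n_years], walk[spec.n_years:]
    shift = kappa.mean()
    kappa = kappa - shift
    kappa_future = kappa_future - shift
    truth = normalize_lc(LCParams(alpha, beta, kappa))

    if spec.exposure_level is None:
        N = np.tile(default_exposures(ages)[:, None], (1, spec.n_years))
    else:
        N = np.broadcast_to(np.asarray(spec.exposure_level, dtype=float),
                            (spec.n_ages, spec.n_years)).copy()
        if np.any(N <= 0):
            raise SyntheticError("exposures must be positive")

    eta = truth.alpha[:, None] + truth.beta[:, None] * truth.kappa[None, :]
    if spec.extra_noise_sd > 0:
        eta = eta + spec.extra_noise_sd * rng.standard_normal(eta.shape)
    deaths = rng.poisson(N * np.exp(eta)).astype(float)

    surface = MortalitySurface(
        ages=ages, years=years, deaths=deaths, exposures=N,
        observed_mask=np.ones_like(deaths, dtype=bool), sex="total",
        provenance=[f"synthetic (seed {spec.seed})"],
    )
    return surface, truth, kappa_future


def apply_missingness(surface: MortalitySurface, spec: SyntheticSpec) -> MortalitySurface:
    """Impose the spec's observation pattern on a fully observed surface.

    Seeded by ``spec.seed`` (offset so the draw is independent of the count
    simulation).  Raises if the pattern would empty an entire age row or
    year column of observations, which would make fixtures unidentifiable.
    """
    ms = spec.missingness
    rng = np.random.default_rng(spec.seed + 1_000_003)
    out = surface.copy()
    mask = out.observed_mask

    old = out.ages >= ms.oldage_start
    if old.any():
        not_census = ~np.isin(out.years, list(ms.census_years))
        mask[np.ix_(old, not_census)] = False

    if ms.random_missing_frac > 0:
        drop = rng.random(mask.shape) < ms.random_missing_frac
        mask &= ~drop

    if ms.zero_inflation_frac > 0:
        obs_idx = np.argwhere(mask)
        counts = out.deaths[mask]
        k = int(round(ms.zero_inflation_frac * obs_idx.shape[0]))
        if k > 0:
            lowest = obs_idx[np.argsort(counts)[:k]]
            out.deaths[lowest[:, 0], lowest[:, 1]] = 0.0

    if np.any(mask.sum(axis=1) == 0) or np.any(mask.sum(axis=0) == 0):
        raise SyntheticError(
            "missingness pattern empties an entire age row or year column"
        )
    out.observed_mask = mask
    out.provenance.append(
        f"missingness: oldage_start={ms.oldage_start}, census={list(ms.census_years)}, "
        f"random={ms.random_missing_frac}, zeros={ms.zero_inflation_frac}"
    )
    return out
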