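"""Kannisto logistic-hazard extrapolation of old-age mortality.

Survey data rarely observes single-age mortality beyond age 89 outside
census years, and what is observed there is noisy and under-reported.  The
Kannisto model caps the force of mortality with a logistic curve,

    u(x) = level * exp(slope * x) / (1 + level * exp(slope * x)),

which rises in age but stays below 1 — empirically the best-behaved of the
classical old-age laws.  Fitted to ages 60-89, it extends the mortality
curve to age 100.

The conversion chain between the one-year death probability q, the hazard
u, and the central rate m is::

    u = -ln(1 - q)          q = 1 - exp(-u)
    q = m / (1 + 0.5 m)     m = q / (1 - 0.5 q)

(the q <-> m pair is the uniform-distribution-of-deaths approximation).
Because ``logit(u) = ln(level) + slope * x`` exactly under the model, the
parameters are estimated by ordinary least squares of logit(u) on age —
closed-form, deterministic, and exact on model-generated data.  An optional
nonlinear least-squares refinement on the q scale is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KannistoParams",
    "KannistoError",
    "hazard_from_q",
    "q_from_hazard",
    "q_from_m",
    "m_from_q",
    "kannisto_hazard",
    "fit_kannisto",
    "extend_curve",
]


class KannistoError(ValueError):
    pass


@dataclass
class KannistoParams:
    level: float      # hazard odds at age 0 (alpha of the logistic law)
    slope: float      # log-odds increase per year of age
    fit_ages: tuple = (60, 89)
    slope_warning: bool = False

    def __post_init__(self):
        if not (self.level > 0):
            raise KannistoError("level must be positive")


def hazard_from_q(q):
    """One-year hazard u = -ln(1 - q) from a death probability q in [0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise KannistoError("q must lie in [0, 1)")
    out = -np.log1p(-q)
    return float(out) if out.ndim == 0 else out


def q_from_hazard(u):
    """Inverse of :func:`hazard_from_q`: q = 1 - exp(-u)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise KannistoError("hazard must be nonnegative")
    out = -np.expm1(-u)
    return float(out) if out.ndim == 0 else out


def q_from_m(m):
    """Death probability from central rate: q = m / (1 + 0.5 m), valid q < 1
    (i.e. m < 2)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise KannistoError("central rate must be nonnegative")
    if np.any(m >= 2):
        raise KannistoError("central rate >= 2 maps outside the valid range q < 1")
    out = m / (1.0 + 0.5 * m)
    return float(out) if out.ndim == 0 else out


def m_from_q(q):
    """Central rate from death probability: m = q / (1 - 0.5 q)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise KannistoError("q must lie in [0, 1)")
    out = q / (1.0 - 0.5 * q)
    return float(out) if out.ndim == 0 else out


def kannisto_hazard(ages, params: KannistoParams):
    """Model hazard u(x) at the given ages."""
    x = np.asarray(ages, dtype=float)
    z = params.level * np.exp(params.slope * x)
    out = z / (1.0 + z)
    return float(out) if out.ndim == 0 else out


def fit_kannisto(ages, q, fit_range=(60, 89), refine: bool = False) -> KannistoParams:
    """Estimate the logistic-hazard parameters from (age, q) pairs.

    The hazard u = -ln(1-q) is logit-linear in age under the model, so OLS
    of logit(u) on age over ``fit_range`` gives exact parameter recovery on
    model-generated data.  ``refine=True`` polishes the OLS solution with
    nonlinear least squares on the q scale.  NaN q values are skipped; a
    nonpositive fitted slope is flagged rather than raised.
    """
    ages = np.asarray(ages, dtype=float)
    q = np.asarray(q, dtype=float)
    if ages.shape != q.shape:
        raise KannistoError("ages and q must have matching shapes")
    lo, hi = fit_range
    keep = (ages >= lo) & (ages <= hi) & np.isfinite(q)
    if np.any(keep & ((q < 0) | (q >= 1))):
        raise KannistoError("fit q values must lie in [0, 1)")
    keep &= (q > 0)
    if keep.sum() < 3:
        raise KannistoError(
            f"need at least 3 ages with 0 < q < 1 in {fit_range}, got {int(keep.sum())}"
        )
    u = hazard_from_q(q[keep])
    if np.any(u >= 1):
        bad = ages[keep][np.asarray(u) >= 1]
        raise KannistoError(
            f"hazard >= 1 at ages {bad}: outside the logistic-hazard domain"
        )
    logit_u = np.log(u / (1.0 - u))
    slope, intercept = np.polyfit(ages[keep], logit_u, 1)
    params = KannistoParams(
        level=float(np.exp(intercept)), slope=float(slope),
        fit_ages=(int(lo), int(hi)), slope_warning=bool(slope <= 0),
    )
    if refine:
        x, y = ages[keep], q[keep]

        def resid(theta):
            p = KannistoParams(np.exp(theta[0]), theta[1], params.fit_ages)
            return q_from_hazard(kannisto_hazard(x, p)) - y

        sol = least_squares(resid, [np.log(params.level), params.slope])
        params = KannistoParams(
            level=float(np.exp(sol.x[0])), slope=float(sol.x[1]),
            fit_ages=params.fit_ages, slope_warning=bool(sol.x[1] <= 0),
        )
    return params


def extend_curve(ages, m, params: KannistoParams, max_age: int = 100,
                 start_age: int = 90, replace_all: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Extend a central-rate curve to ``max_age`` with model-based values.

    Returns (extended_ages, extended_m) covering ages[0] .. max_age.  By
    default only missing (NaN or absent) cells at ``start_age`` and above
    are filled from the model; observed old-age cells are kept.  With
    ``replace_all`` every age >= start_age takes the model value.
    """
    ages = np.asarray(ages, dtype=int)
    m = np.asarray(m, dtype=float)
    if ages.shape != m.shape:
        raise KannistoError("ages and m must have matching shapes")
    if max_age < ages.max():
        raise KannistoError("max_age must be >= the last input age")
    out_ages = np.arange(ages[0], max_age + 1)
    out = np.full(out_ages.shape, np.nan)
    idx = np.searchsorted(out_ages, ages)
    out[idx] = m
    fill = np.isnan(out) & (out_ages >= start_age)
    if replace_all:
        fill = out_ages >= start_age
    if fill.any():
        u = kannisto_hazard(out_ages[fill], params)
        q = q_from_hazard(u)
        if np.any(q >= 1):
            raise KannistoError("model q >= 1 at a target age")
        out[fill] = m_from_q(q)
    return out_ages, out
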