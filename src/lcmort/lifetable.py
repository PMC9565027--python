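"""Period life tables and life expectancy from central death rates.

A projected column of central rates m(x) for one calendar year is converted
to one-year death probabilities q(x) = m / (1 + 0.5 m) (uniform deaths
within the year), the table is closed by forcing q = 1 at the final age,
and life expectancy at the start age is the sum of the k-year survival
products plus a half year for the year of death:

    e_x = sum_k prod_{i<k} (1 - q(x+i)) + 0.5

These are period quantities: each year's table uses that single year's
mortality schedule, not the experience of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kannisto import q_from_m

__all__ = ["LifeTable", "LifeTableError", "q_schedule_from_m",
           "survival_products", "life_expectancy", "make_life_table"]


class LifeTableError(ValueError):
    pass


@dataclass
class LifeTable:
    ages: np.ndarray
    qx: np.ndarray
    survival: np.ndarray
    ex: float


def q_schedule_from_m(m) -> np.ndarray:
    """Element-wise q = m / (1 + 0.5 m); the final age's q is forced to 1
    (table closure)."""
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        raise LifeTableError("empty rate vector")
    if np.any(m < 0):
        raise LifeTableError("negative central rate")
    q = np.empty_like(m)
    q[:-1] = q_from_m(m[:-1])
    q[-1] = 1.0
    return q


def survival_products(q) -> np.ndarray:
    """k-year survival probabilities: survival[k-1] = prod_{i<k} (1 - q[i])."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise LifeTableError("q values must lie in [0, 1]")
    return np.cumprod(1.0 - q)


def life_expectancy(q, start_age: int = 0) -> float:
    """Period life expectancy e = sum of survival products + 0.5.

    ``q`` must run from ``start_age`` to the closure age (final entry 1 for
    a closed table).  The +0.5 credits the expected half year lived in the
    year of death.
    """
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise LifeTableError("empty q vector")
    return float(survival_products(q).sum() + 0.5)


def make_life_table(m, start_age: int = 0) -> LifeTable:
    """Full table from a central-rate schedule starting at ``start_age``."""
    m = np.asarray(m, dtype=float)
    q = q_schedule_from_m(m)
    surv = survival_products(q)
    return LifeTable(
        ages=np.arange(start_age, start_age + m.size),
        qx=q,
        survival=surv,
        ex=float(surv.sum() + 0.5),
    )
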