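"""Age x year mortality surfaces: ingestion, scaling, rates, and gap-filling.

The raw material of the analysis is a pair of matrices on a common grid of
single ages (rows) and calendar years (columns): death counts D[x, t] and
population exposures N[x, t] (mid-year person counts standing in for
person-years at risk).  Survey data of this kind is sparse: whole old-age
blocks are unobserved outside census years, and occasional cells are zero
or missing at young ages.  An explicit observed/missing mask travels with
the matrices so that downstream fitting can weight cells rather than guess.

Gap-filling interpolates log central rates across ages within each calendar
year with a natural cubic spline; filled cells are flagged ``imputed`` so
the model fitter can include or exclude them by policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "MortalitySurface",
    "RateSurface",
    "MortalityDataError",
    "read_mortality_csv",
    "write_surface",
    "apply_source_scaling",
    "rescale_exposure_base",
    "central_rates",
    "fill_missing_by_spline",
]


class MortalityDataError(ValueError):
    """Raised for malformed or inconsistent mortality input data."""


def _as_consecutive(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=int)
    if arr.ndim != 1 or arr.size == 0:
        raise MortalityDataError(f"{what} must be a non-empty 1-d integer vector")
    if not np.all(np.diff(arr) == 1):
        raise MortalityDataError(f"{what} must be consecutive integers, got {arr}")
    return arr


@dataclass
class MortalitySurface:
    """Death counts and exposures on an age x year grid with an observation mask.

    ``observed_mask`` is True where the cell was actually observed;
    ``imputed_mask`` marks cells later filled by interpolation or model-based
    extension (a filled cell has observed_mask False, imputed_mask True).
    Counts are real-valued: source scaling (e.g. dividing census counts by
    1000) produces non-integer "deaths".
    """

    ages: np.ndarray
    years: np.ndarray
    deaths: np.ndarray
    exposures: np.ndarray
    observed_mask: np.ndarray
    sex: str = "total"
    provenance: list = field(default_factory=list)
    imputed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.ages = _as_consecutive(self.ages, "ages")
        self.years = _as_consecutive(self.years, "years")
        shape = (self.ages.size, self.years.size)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        for name in ("deaths", "exposures", "observed_mask"):
            if getattr(self, name).shape != shape:
                raise MortalityDataError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(shape, dtype=bool)
        else:
            self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
            if self.imputed_mask.shape != shape:
                raise MortalityDataError("imputed_mask shape mismatch")
        obs = self.observed_mask
        if np.any(self.deaths[obs] < 0):
            bad = np.argwhere(obs & (self.deaths < 0))[0]
            raise MortalityDataError(
                f"negative death count at age {self.ages[bad[0]]}, year {self.years[bad[1]]}"
            )
        if np.any(~(self.exposures[obs] > 0)):
            bad = np.argwhere(obs & ~(self.exposures > 0))[0]
            raise MortalityDataError(
                f"non-positive exposure at age {self.ages[bad[0]]}, year {self.years[bad[1]]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.deaths.shape

    def copy(self) -> "MortalitySurface":
        return MortalitySurface(
            ages=self.ages.copy(),
            years=self.years.copy(),
            deaths=self.deaths.copy(),
            exposures=self.exposures.copy(),
            observed_mask=self.observed_mask.copy(),
            sex=self.sex,
            provenance=list(self.provenance),
            imputed_mask=self.imputed_mask.copy(),
        )


@dataclass
class RateSurface:
    """Central death rates m = D/N on an age x year grid.

    ``log_rates`` is finite exactly where the rate is defined and positive;
    elsewhere it is NaN and the cell is a candidate for gap-filling.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    log_rates: np.ndarray
    observed_mask: np.ndarray
    imputed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.ages = _as_consecutive(self.ages, "ages")
        self.years = _as_consecutive(self.years, "years")
        self.rates = np.asarray(self.rates, dtype=float)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.rates.shape, dtype=bool)

    def copy(self) -> "RateSurface":
        return RateSurface(
            self.ages.copy(), self.years.copy(), self.rates.copy(),
            self.log_rates.copy(), self.observed_mask.copy(),
            self.imputed_mask.copy(),
        )


# ---------------------------------------------------------------------------
# CSV ingestion / emission
# ---------------------------------------------------------------------------

def _read_wide_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, skipinitialspace=True)
    if df.columns[0].strip().lower() != "age":
        raise MortalityDataError(f"{path}: first column header must be 'age'")
    df = df.rename(columns={df.columns[0]: "age"})
    try:
        year_cols = {c: int(c) for c in df.columns[1:]}
    except ValueError as exc:
        raise MortalityDataError(f"{path}: year headers must be integers ({exc})")
    df = df.rename(columns=year_cols).set_index("age")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            age = df.index[bad.argmax()]
            raise MortalityDataError(
                f"{path}: non-numeric value at age {age}, year {col}"
            )
        df[col] = vals
        neg = vals < 0
        if neg.any():
            age = df.index[neg.argmax()]
            raise MortalityDataError(f"{path}: negative value at age {age}, year {col}")
    return df


def read_mortality_csv(deaths_path, exposures_path, sex: str = "total") -> MortalitySurface:
    """Read a deaths/exposures CSV pair (wide layout, 'age' + year columns).

    Empty cells or the token ``NA`` mark missing observations; a cell missing
    in either file is masked in the returned surface.
    """
    d = _read_wide_csv(deaths_path)
    e = _read_wide_csv(exposures_path)
    if not d.index.equals(e.index) or list(d.columns) != list(e.columns):
        raise MortalityDataError(
            "deaths and exposures files must share identical age and year grids"
        )
    observed = d.notna().to_numpy() & e.notna().to_numpy()
    deaths = d.to_numpy(dtype=float)
    exposures = e.to_numpy(dtype=float)
    deaths[~observed] = np.nan
    exposures[~observed] = np.nan
    return MortalitySurface(
        ages=d.index.to_numpy(),
        years=np.asarray(list(d.columns)),
        deaths=np.where(observed, deaths, 0.0),
        exposures=np.where(observed, exposures, 1.0),
        observed_mask=observed,
        sex=sex,
        provenance=[f"read from {deaths_path} / {exposures_path}"],
    )


def write_surface(surface: MortalitySurface, deaths_path, exposures_path,
                  mask_path=None) -> None:
    """Write a surface back to wide CSVs; masked cells become empty fields."""
    def frame(values, keep):
        arr = values.astype(float).copy()
        arr[~keep] = np.nan
        return pd.DataFrame(arr, index=pd.Index(surface.ages, name="age"),
                            columns=surface.years)

    keep = surface.observed_mask | surface.imputed_mask
    frame(surface.deaths, keep).to_csv(deaths_path)
    frame(surface.exposures, keep).to_csv(exposures_path)
    if mask_path is not None:
        pd.DataFrame(surface.observed_mask.astype(int),
                     index=pd.Index(surface.ages, name="age"),
                     columns=surface.years).to_csv(mask_path)


# ---------------------------------------------------------------------------
# Source scaling
# ---------------------------------------------------------------------------

def apply_source_scaling(surface: MortalitySurface,
                         scale_by_year: dict) -> MortalitySurface:
    """Divide deaths and exposures in listed years by per-year factors.

    Census counts and percentage-sample counts arrive on different scales
    (e.g. full census divided by 1000, a 1% sample by 10, to bring every
    year to a comparable magnitude).  Scaling both deaths and exposures by
    the same factor leaves central rates untouched.
    """
    out = surface.copy()
    for year, factor in scale_by_year.items():
        if factor <= 0:
            raise MortalityDataError(f"scale factor for year {year} must be positive")
        idx = np.flatnonzero(out.years == year)
        if idx.size == 0:
            raise MortalityDataError(f"year {year} not present in surface")
        j = idx[0]
        out.deaths[:, j] /= factor
        out.exposures[:, j] /= factor
        out.provenance.append(f"year {year}: deaths and exposures divided by {factor}")
    return out


def rescale_exposure_base(surface: MortalitySurface, base: float = 1e6) -> MortalitySurface:
    """Rescale each year so its total observed exposure equals ``base``.

    Deaths are rescaled by the same per-year factor, preserving every
    cell's death/exposure ratio (central rates are invariant).
    """
    if base <= 0:
        raise MortalityDataError("base must be positive")
    out = surface.copy()
    for j, year in enumerate(out.years):
        col_obs = out.observed_mask[:, j]
        total = out.exposures[col_obs, j].sum()
        if total <= 0:
            raise MortalityDataError(f"year {year} has no positive observed exposure")
        factor = total / base
        out.deaths[:, j] /= factor
        out.exposures[:, j] /= factor
    out.provenance.append(f"per-year exposure renormalised to base {base:g}")
    return out


# ---------------------------------------------------------------------------
# Central rates and spline gap-filling
# ---------------------------------------------------------------------------

def central_rates(surface: MortalitySurface) -> RateSurface:
    """Central death rates m[x, t] = D[x, t] / N[x, t] on observed cells.

    Zero-death cells get rate 0 with an undefined (NaN) log rate, flagging
    them for gap-filling alongside masked cells.
    """
    obs = surface.observed_mask
    if np.any(~(surface.exposures[obs] > 0)):
        raise MortalityDataError("observed cell with non-positive exposure")
    rates = np.full(surface.shape, np.nan)
    rates[obs] = surface.deaths[obs] / surface.exposures[obs]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rates = np.where(rates > 0, np.log(rates), np.nan)
    return RateSurface(
        ages=surface.ages, years=surface.years, rates=rates,
        log_rates=log_rates, observed_mask=obs.copy(),
        imputed_mask=surface.imputed_mask.copy(),
    )


def fill_missing_by_spline(rate_surface: RateSurface, min_knots: int = 4) -> RateSurface:
    """Fill undefined cells by natural cubic spline on log rate vs age, per year.

    Interpolation runs across ages within each calendar year independently,
    on the log scale, through the cells with defined (positive, observed)
    log rates.  Only interior missing ages are splined; missing ages outside
    a year's observed span are filled by nearest-knot constant extension
    (boundary cells below the old-age block) — old-age extension is the
    Kannisto model's job, not the spline's.  Filled cells are flagged in
    ``imputed_mask``; defined cells are returned bit-identical.
    """
    out = rate_surface.copy()
    A, T = out.rates.shape
    ages = out.ages.astype(float)
    for j, year in enumerate(out.years):
        defined = np.isfinite(out.log_rates[:, j])
        missing = ~defined
        if not missing.any():
            continue
        knots = np.flatnonzero(defined)
        if knots.size < min_knots:
            raise MortalityDataError(
                f"year {year}: only {knots.size} usable knots (< {min_knots})"
            )
        spline = CubicSpline(ages[knots], out.log_rates[knots, j], bc_type="natural")
        lo, hi = knots[0], knots[-1]
        interior = missing & (np.arange(A) > lo) & (np.arange(A) < hi)
        if interior.any():
            out.log_rates[interior, j] = spline(ages[interior])
        below = missing & (np.arange(A) < lo)
        if below.any():  # nearest-knot constant extension, not extrapolation
            out.log_rates[below, j] = out.log_rates[lo, j]
        # ages above the observed span are left NaN for old-age extension
        filled = missing & np.isfinite(out.log_rates[:, j])
        out.rates[filled, j] = np.exp(out.log_rates[filled, j])
        out.imputed_mask[filled, j] = True
    return out


def surface_from_rates(rate_surface: RateSurface, exposures: np.ndarray,
                       sex: str = "total") -> MortalitySurface:
    """Rebuild a count surface D = m * N from a (filled) rate surface."""
    exposures = np.asarray(exposures, dtype=float)
    defined = np.isfinite(rate_surface.rates)
    deaths = np.where(defined, rate_surface.rates * exposures, 0.0)
    return MortalitySurface(
        ages=rate_surface.ages, years=rate_surface.years,
        deaths=deaths, exposures=exposures,
        observed_mask=rate_surface.observed_mask.copy(), sex=sex,
        imputed_mask=rate_surface.imputed_mask.copy(),
    )
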