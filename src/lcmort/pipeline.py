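"""End-to-end orchestration: read -> scale -> fill -> extend -> fit ->
forecast -> project -> life tables -> evaluate.

Every stage is a thin call into the corresponding module; the pipeline's
job is sequencing, configuration defaults, and writing the output artifact
set (filled surfaces, parameter tables, the fitted-plus-forecast period
index with intervals, projected rates, life expectancies, and an
evaluation report).  Identical configuration and seed give byte-identical
numeric outputs.

Old-age completion detail: the Kannisto extension supplies central rates
for unobserved ages, but the Poisson fitter needs counts.  Exposures for
extended cells are extrapolated log-linearly in age from each year's last
ten observed cohorts, and deaths are set to m * N; both are flagged
imputed, so the fitter's ``use_imputed`` policy decides whether they carry
weight.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import log_residuals, mape
from .kannisto import fit_kannisto, extend_curve, q_from_m
from .kt_forecast import (ArimaSpec, fit_arima, forecast_kappa,
                          project_mortality_ages, select_arima, default_grid)
from .lee_carter import fit_lc_poisson, fitted_log_rates, weights_from_mask
from .lifetable import life_expectancy, q_schedule_from_m
from .surfaces import (MortalitySurface, apply_source_scaling, central_rates,
                       fill_missing_by_spline, read_mortality_csv,
                       rescale_exposure_base, write_surface)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("lcmort")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline options, each with a runnable default.

    ``inputs`` maps a sex label to {"deaths": path, "exposures": path}.
    ``arima_order`` fixes the (p, d, q) specification; set it to None to
    select over the default grid by AIC + t-screen.
    """

    inputs: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)          # sex -> {year: factor}
    exposure_base: float | None = None                   # e.g. 1e6
    fill_axis: str = "age"                               # interpolate across ages within a year
    kannisto_fit_range: tuple = (60, 89)
    kannisto_max_age: int = 100
    kannisto_placement: str = "pre_fit"                  # or "post_projection"
    lc_tol: float = 1e-6
    lc_max_iter: int = 10000
    use_imputed: bool = True
    arima_order: tuple | None = (1, 2, 1)
    arima_constant: bool | None = None                   # None -> default by d
    horizon: int = 20
    confidence_level: float = 0.95
    lifetable_start_age: int = 0
    holdout_years: int = 0
    out_dir: str = "lcmort_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown option(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.horizon < 1:
            raise PipelineError("config", "horizon must be >= 1")
        if cfg.fill_axis not in ("age", "year"):
            raise PipelineError("config", "fill_axis must be 'age' or 'year'")
        if cfg.kannisto_placement not in ("pre_fit", "post_projection"):
            raise PipelineError(
                "config", "kannisto_placement must be 'pre_fit' or 'post_projection'")
        return cfg


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON, a YAML subset) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("arima_order", "kannisto_fit_range"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _extrapolate_exposures(ages, N_col, observed_col, target_ages, n_ref=10):
    """Log-linear extrapolation of cohort sizes into unobserved old ages."""
    obs = np.flatnonzero(observed_col)
    ref = obs[-n_ref:]
    coef = np.polyfit(ages[ref].astype(float), np.log(N_col[ref]), 1)
    return np.exp(np.polyval(coef, np.asarray(target_ages, dtype=float)))


def extend_surface_kannisto(surface: MortalitySurface, filled_rates,
                            fit_range=(60, 89), max_age: int = 100,
                            replace_all: bool = False) -> MortalitySurface:
    """Complete a surface to ``max_age`` using per-year Kannisto fits.

    For every calendar year a logistic hazard is fitted to the year's death
    probabilities over ``fit_range`` and evaluated at the missing old ages.
    Observed old-age cells (census years) are kept unless ``replace_all``.
    """
    A_old = surface.ages.size
    new_ages = np.arange(surface.ages[0], max_age + 1)
    A, T = new_ages.size, surface.years.size

    deaths = np.zeros((A, T))
    exposures = np.ones((A, T))
    observed = np.zeros((A, T), dtype=bool)
    imputed = np.zeros((A, T), dtype=bool)
    deaths[:A_old] = surface.deaths
    exposures[:A_old] = surface.exposures
    observed[:A_old] = surface.observed_mask
    imputed[:A_old] = surface.imputed_mask

    start_age = max(fit_range[1] + 1, 90) if not replace_all else fit_range[1] + 1
    for j, year in enumerate(surface.years):
        m_col = np.full(A, np.nan)
        defined = np.isfinite(filled_rates.rates[:, j]) & (filled_rates.rates[:, j] > 0)
        m_col[:A_old][defined] = filled_rates.rates[defined, j]
        fit_sel = np.isfinite(m_col)
        params = fit_kannisto(new_ages[fit_sel], q_from_m(m_col[fit_sel]),
                              fit_range=fit_range)
        _, m_ext = extend_curve(new_ages, m_col, params, max_age=max_age,
                                start_age=start_age, replace_all=replace_all)
        fill = np.isfinite(m_ext) & ~np.isfinite(m_col)
        if replace_all:
            fill |= new_ages >= start_age
        if not fill.any():
            continue
        N_fill = _extrapolate_exposures(new_ages[:A_old],
                                        surface.exposures[:, j],
                                        surface.observed_mask[:, j],
                                        new_ages[fill])
        exposures[fill, j] = N_fill
        deaths[fill, j] = m_ext[fill] * N_fill
        observed[fill, j] = False
        imputed[fill, j] = True

    return MortalitySurface(
        ages=new_ages, years=surface.years, deaths=deaths,
        exposures=exposures, observed_mask=observed, sex=surface.sex,
        provenance=list(surface.provenance)
        + [f"Kannisto extension to age {max_age} (fit on {fit_range})"],
        imputed_mask=imputed,
    )


def _fill_surface(surface: MortalitySurface, cfg: PipelineConfig):
    """Central rates plus spline gap-fill along the configured axis."""
    rates = central_rates(surface)
    if cfg.fill_axis == "year":
        flipped = dataclasses.replace(
            rates, ages=np.arange(rates.years.size),
            years=np.arange(rates.ages.size) + rates.years[0],
        )
        # transpose the grid so the per-column spline runs across years
        flipped.rates = rates.rates.T.copy()
        flipped.log_rates = rates.log_rates.T.copy()
        flipped.observed_mask = rates.observed_mask.T.copy()
        flipped.imputed_mask = rates.imputed_mask.T.copy()
        filled = fill_missing_by_spline(flipped)
        rates.rates = filled.rates.T
        rates.log_rates = filled.log_rates.T
        rates.imputed_mask = filled.imputed_mask.T
        return rates
    return fill_missing_by_spline(rates)


def _apply_fill_to_surface(surface: MortalitySurface, filled) -> MortalitySurface:
    """Push gap-filled rates back into the count surface (D = m * N)."""
    out = surface.copy()
    new = filled.imputed_mask & ~surface.imputed_mask
    out.deaths[new] = filled.rates[new] * out.exposures[new]
    out.imputed_mask |= filled.imputed_mask
    return out


def _kappa_frame(years, kappa, fc) -> pd.DataFrame:
    rows = [{"year": int(y), "status": "fitted", "kappa": float(k),
             "lower": np.nan, "upper": np.nan}
            for y, k in zip(years, kappa)]
    rows += [{"year": int(y), "status": "forecast", "kappa": float(p),
              "lower": float(lo), "upper": float(hi)}
             for y, p, lo, hi in zip(fc.years, fc.point, fc.lower, fc.upper)]
    return pd.DataFrame(rows)


def _extend_projection(proj, cfg: PipelineConfig):
    """Kannisto-extend each projected year's rate column (post-projection
    placement: the model is fitted on the unextended age range)."""
    new_ages = np.arange(proj.ages[0], cfg.kannisto_max_age + 1)
    A, T = new_ages.size, proj.years.size
    rates = np.full((A, T), np.nan)
    rates[: proj.ages.size] = proj.rates
    for j in range(T):
        params = fit_kannisto(proj.ages, q_from_m(proj.rates[:, j]),
                              fit_range=cfg.kannisto_fit_range)
        _, rates[:, j] = extend_curve(new_ages, rates[:, j], params,
                                      max_age=cfg.kannisto_max_age)
    with np.errstate(divide="ignore"):
        log_rates = np.log(rates)
    return dataclasses.replace(
        proj, ages=new_ages, rates=rates, log_rates=log_rates,
        observed_mask=np.ones((A, T), dtype=bool),
        imputed_mask=np.zeros((A, T), dtype=bool))


def _holdout_mape(surface, cfg: PipelineConfig, spec: ArimaSpec) -> dict | None:
    h = cfg.holdout_years
    if h <= 0:
        return None
    T = surface.years.size
    if T - h < spec.p + spec.q + spec.d + 2:
        raise PipelineError("evaluate", f"holdout of {h} leaves too few years")
    train = MortalitySurface(
        ages=surface.ages, years=surface.years[: T - h],
        deaths=surface.deaths[:, : T - h], exposures=surface.exposures[:, : T - h],
        observed_mask=surface.observed_mask[:, : T - h], sex=surface.sex,
        imputed_mask=surface.imputed_mask[:, : T - h],
    )
    w = weights_from_mask(train, use_imputed=cfg.use_imputed)
    fit = fit_lc_poisson(train, w, tol=cfg.lc_tol, max_iter=cfg.lc_max_iter)
    afit = fit_arima(fit.params.kappa, spec)
    fc = forecast_kappa(afit, h, cfg.confidence_level,
                        last_year=int(train.years[-1]))
    proj = project_mortality_ages(fit.params, fc, surface.ages)
    actual = central_rates(surface)
    hold_mask = (surface.observed_mask[:, T - h:]
                 & np.isfinite(actual.rates[:, T - h:])
                 & (actual.rates[:, T - h:] > 0))
    value = mape(actual.rates[:, T - h:], proj.rates, hold_mask)
    return {"mape": value, "n_cells": int(hold_mask.sum()), "holdout_years": h}


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, surfaces: dict | None = None) -> dict:
    """Run the full analysis and write the artifact set to ``out_dir``.

    ``surfaces`` may supply in-memory MortalitySurface objects keyed by sex,
    bypassing the CSV-reading stage (the CLI always goes through CSVs).
    Returns a summary dict, also written as ``summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if surfaces is None:
        surfaces = {}
        for sex, paths in config.inputs.items():
            try:
                surfaces[sex] = read_mortality_csv(
                    paths["deaths"], paths["exposures"], sex=sex)
            except (KeyError, FileNotFoundError, OSError) as exc:
                raise PipelineError("read", f"{sex}: {exc}")
    if not surfaces:
        raise PipelineError("read", "no input surfaces configured")

    summary = {"version": __version__, "seed": config.seed,
               "config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in dataclasses.asdict(config).items()},
               "sexes": {}}

    for sex, surface in surfaces.items():
        log.info("processing %s", sex)
        stage = "scale"
        try:
            if config.scaling.get(sex):
                surface = apply_source_scaling(
                    surface, {int(y): f for y, f in config.scaling[sex].items()})
            if config.exposure_base:
                surface = rescale_exposure_base(surface, config.exposure_base)

            stage = "fill"
            filled = _fill_surface(surface, config)
            surface = _apply_fill_to_surface(surface, filled)

            stage = "extend"
            if config.kannisto_placement == "pre_fit":
                surface = extend_surface_kannisto(
                    surface, filled, fit_range=config.kannisto_fit_range,
                    max_age=config.kannisto_max_age)
                filled = central_rates(surface)
                filled.rates[surface.imputed_mask] = (
                    surface.deaths[surface.imputed_mask]
                    / surface.exposures[surface.imputed_mask])
                with np.errstate(divide="ignore", invalid="ignore"):
                    filled.log_rates = np.where(
                        filled.rates > 0, np.log(filled.rates), np.nan)
            write_surface(surface, out_dir / f"{sex}_deaths_filled.csv",
                          out_dir / f"{sex}_exposures_filled.csv",
                          out_dir / f"{sex}_observed_mask.csv")

            stage = "fit"
            weights = weights_from_mask(surface, use_imputed=config.use_imputed)
            fit = fit_lc_poisson(surface, weights, tol=config.lc_tol,
                                 max_iter=config.lc_max_iter)
            pd.DataFrame({"age": surface.ages, "alpha": fit.params.alpha,
                          "beta": fit.params.beta}).to_csv(
                out_dir / f"{sex}_age_params.csv", index=False)

            stage = "forecast"
            if config.arima_order is not None:
                spec = ArimaSpec(*config.arima_order,
                                 include_constant=config.arima_constant)
            else:
                spec = select_arima(fit.params.kappa, default_grid())
            afit = fit_arima(fit.params.kappa, spec)
            fc = forecast_kappa(afit, config.horizon, config.confidence_level,
                                last_year=int(surface.years[-1]))
            _kappa_frame(surface.years, fit.params.kappa, fc).to_csv(
                out_dir / f"{sex}_kappa.csv", index=False)

            stage = "project"
            proj = project_mortality_ages(fit.params, fc, surface.ages)
            if config.kannisto_placement == "post_projection":
                proj = _extend_projection(proj, config)
            pd.DataFrame(proj.rates, index=pd.Index(proj.ages, name="age"),
                         columns=proj.years).to_csv(
                out_dir / f"{sex}_projected_rates.csv")

            stage = "lifetable"
            start = config.lifetable_start_age
            sel = surface.ages >= start
            proj_sel = proj.ages >= start
            fitted_rates = np.exp(fitted_log_rates(fit.params))
            e0 = {}
            for j, year in enumerate(surface.years):
                e0[int(year)] = life_expectancy(
                    q_schedule_from_m(fitted_rates[sel, j]), start)
            for j, year in enumerate(proj.years):
                e0[int(year)] = life_expectancy(
                    q_schedule_from_m(proj.rates[proj_sel, j]), start)

            stage = "evaluate"
            actual = central_rates(surface)
            obs_pos = (weights.w > 0) & np.isfinite(actual.log_rates)
            resid = log_residuals(actual.log_rates, fitted_log_rates(fit.params),
                                  obs_pos)
            pd.DataFrame(resid, index=pd.Index(surface.ages, name="age"),
                         columns=surface.years).to_csv(
                out_dir / f"{sex}_log_residuals.csv")
            in_sample = mape(actual.rates, np.exp(fitted_log_rates(fit.params)),
                             obs_pos & (actual.rates > 0))
            holdout = _holdout_mape(surface, config, spec)
            evaluation = {"in_sample_mape": in_sample,
                          "n_cells": int(obs_pos.sum()),
                          "holdout": holdout}
            with open(out_dir / f"{sex}_evaluation.json", "w") as fh:
                json.dump(evaluation, fh, indent=2)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, f"{sex}: {exc}") from exc

        summary["sexes"][sex] = {
            "deviance": fit.deviance,
            "iterations": fit.iterations,
            "converged": fit.converged,
            "arima_order": list(spec.order),
            "arima_aic": afit.aic,
            "kappa_last_fitted": float(fit.params.kappa[-1]),
            "kappa_forecast_final": float(fc.point[-1]),
            "life_expectancy": e0,
            "evaluation": evaluation,
        }

    ex_frame = pd.DataFrame({sex: pd.Series(info["life_expectancy"])
                             for sex, info in summary["sexes"].items()})
    ex_frame.index.name = "year"
    ex_frame.to_csv(out_dir / "life_expectancy.csv")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("pipeline complete: %s", out_dir)
    return summary
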