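"""Fit and forecast quality: MAPE and log-scale residual surfaces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "EvaluationError", "mape", "log_residuals"]


class EvaluationError(ValueError):
    pass


@dataclass
class EvalReport:
    mape: float
    n_cells: int
    residual_matrix: np.ndarray | None = None


def mape(actual, predicted, mask=None) -> float:
    """Mean absolute percentage error over the masked-in cells, as a fraction.

    mean |actual - predicted| / actual; every evaluated cell must have
    actual > 0.  Scale-invariant: common rescaling of both matrices leaves
    the value unchanged.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise EvaluationError("actual and predicted shapes differ")
    mask = np.ones(actual.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if mask.shape != actual.shape:
        raise EvaluationError("mask shape differs from data")
    if not mask.any():
        raise EvaluationError("no cells selected for evaluation")
    a = actual[mask]
    if np.any(a <= 0):
        raise EvaluationError("actual must be positive on evaluated cells")
    return float(np.mean(np.abs(a - predicted[mask]) / a))


def log_residuals(observed_log_rates, fitted_log_rates, mask=None) -> np.ndarray:
    """observed - fitted log rates on masked-in cells; NaN elsewhere."""
    obs = np.asarray(observed_log_rates, dtype=float)
    fit = np.asarray(fitted_log_rates, dtype=float)
    if obs.shape != fit.shape:
        raise EvaluationError("shape mismatch between observed and fitted")
    mask = np.ones(obs.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    out = np.full(obs.shape, np.nan)
    out[mask] = obs[mask] - fit[mask]
    return out
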