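"""Allometric power-law scaling of dose-normalized exposure.

A PK parameter P is related to body weight W (kg) by P = P0·W^α.  Fitting
is ordinary least squares of ln(P) on ln(W); prediction from a single
species uses a fixed exponent:  P_target = P_source·(W_target/W_source)^α.

Prediction accuracy is expressed as fold error max(pred/obs, obs/pred),
with ≤2-fold the conventional acceptance bound.  A generalized
single-species exponent is selected by grid search: the exponent whose
geometric-mean pred/obs ratio across compounds and parameters is closest
to 1 on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "AllometricModel",
    "AllometricResults",
    "AllometricFit",
    "FoldError",
    "ExponentGridResult",
    "fit_power_law",
    "allometric_predict",
    "fold_error",
    "geometric_mean",
    "grid_search_exponent",
]


@dataclass(frozen=True)
class AllometricFit:
    """Fitted power law P = P0·W^α with regression uncertainty."""

    coefficient_p0: float
    exponent_alpha: float
    se_alpha: float
    se_log_p0: float
    r_squared: float
    n_points: int

    def predict(self, w) -> float | np.ndarray:
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("body weight must be > 0")
        out = self.coefficient_p0 * w**self.exponent_alpha
        return float(out) if out.ndim == 0 else out


class AllometricModel:
    """Power-law regression model for species-level exposure vs body weight.

    Parameters
    ----------
    weights : sequence of float
        Body weights in kg, at least two distinct values, all > 0.
    values : sequence of float
        The PK parameter (e.g. DCmax or DAUC), all > 0.
    """

    def __init__(self, weights: Sequence[float], values: Sequence[float]):
        w = np.asarray(weights, dtype=float)
        v = np.asarray(values, dtype=float)
        if w.shape != v.shape or w.ndim != 1 or len(w) < 2:
            raise ValidationError("need equal-length 1-d weights and values, n >= 2")
        if np.any(w <= 0) or np.any(v <= 0):
            raise ValidationError("weights and values must be strictly positive")
        if np.all(w == w[0]):
            raise ValidationError("singular design: all body weights are equal")
        self.weights = w
        self.values = v

    @classmethod
    def from_dataframe(cls, df, weight_col: str = "weight_kg", value_col: str = "value"):
        return cls(df[weight_col].to_numpy(), df[value_col].to_numpy())

    def fit(self) -> "AllometricResults":
        lw, lv = np.log(self.weights), np.log(self.values)
        if len(lw) == 2:
            slope = (lv[1] - lv[0]) / (lw[1] - lw[0])
            intercept, se, r2 = lv[0] - slope * lw[0], 0.0, 1.0
            se_icpt = 0.0
        else:
            res = stats.linregress(lw, lv)
            slope, intercept = res.slope, res.intercept
            se, se_icpt, r2 = res.stderr, res.intercept_stderr, res.rvalue**2
        fit = AllometricFit(
            coefficient_p0=float(math.exp(intercept)),
            exponent_alpha=float(slope),
            se_alpha=float(se),
            se_log_p0=float(se_icpt),
            r_squared=float(r2),
            n_points=len(lw),
        )
        return AllometricResults(self, fit)


class AllometricResults:
    """Results wrapper for a fitted :class:`AllometricModel`."""

    def __init__(self, model: AllometricModel, fit: AllometricFit):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> dict:
        return {"p0": self._fit.coefficient_p0, "alpha": self._fit.exponent_alpha}

    @property
    def bse(self) -> dict:
        return {"log_p0": self._fit.se_log_p0, "alpha": self._fit.se_alpha}

    @property
    def rsquared(self) -> float:
        return self._fit.r_squared

    @property
    def nobs(self) -> int:
        return self._fit.n_points

    @property
    def fit(self) -> AllometricFit:
        return self._fit

    def predict(self, w):
        return self._fit.predict(w)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Allometric power-law regression  P = P0 * W^alpha",
            f"  n points : {f.n_points}",
            f"  P0       : {f.coefficient_p0:.6g}  (SE of ln P0: {f.se_log_p0:.3g})",
            f"  alpha    : {f.exponent_alpha:.4g}  (SE: {f.se_alpha:.3g})",
            f"  R^2      : {f.r_squared:.4f}",
        ]
        return "\n".join(lines)


def fit_power_law(weights, values) -> AllometricFit:
    """OLS of ln(value) on ln(weight); returns the fitted power law."""
    return AllometricModel(weights, values).fit().fit


def allometric_predict(value_source: float, w_source: float, w_target: float,
                       alpha: float) -> float:
    """Single-species projection: value·(W_target/W_source)^α."""
    if value_source <= 0 or w_source <= 0 or w_target <= 0:
        raise ValidationError("value and weights must be > 0")
    return value_source * (w_target / w_source) ** alpha


@dataclass(frozen=True)
class FoldError:
    """Signed prediction accuracy: ratio pred/obs and its fold max(r, 1/r)."""

    ratio_pred_over_obs: float
    fold: float
    direction: str  # "over" | "under" | "exact"

    def __str__(self) -> str:
        arrow = {"over": "↑", "under": "↓", "exact": "="}[self.direction]
        return f"({arrow} {self.fold:.2f})"


def fold_error(predicted: float, observed: float) -> FoldError:
    if predicted <= 0 or observed <= 0:
        raise ValidationError("predicted and observed must be > 0")
    ratio = predicted / observed
    fold = max(ratio, 1.0 / ratio)
    direction = "over" if ratio > 1 else ("under" if ratio < 1 else "exact")
    return FoldError(ratio, fold, direction)


def geometric_mean(values: Sequence[float]) -> float:
    x = np.asarray(values, dtype=float)
    if len(x) == 0 or np.any(x <= 0):
        raise ValidationError("geometric mean requires a non-empty positive sequence")
    return float(np.exp(np.mean(np.log(x))))


@dataclass(frozen=True)
class ExponentGridResult:
    """Grid search over candidate exponents for single-species prediction."""

    grid: np.ndarray
    metric: np.ndarray  # geometric-mean pred/obs ratio (or folded) per exponent
    selected_exponent: float
    folded: bool = False

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({"exponent": self.grid, "metric": self.metric})


def grid_search_exponent(
    species_values: Mapping[str, tuple[float, float]],
    human_observed: Mapping[str, float],
    w_target: float,
    grid_min: float,
    grid_max: float,
    step: float = 0.01,
    folded: bool = False,
) -> ExponentGridResult:
    """Select a generalized single-species exponent by grid search.

    ``species_values`` maps a parameter label (e.g. ``"bnt141:dcmax"``) to
    ``(value_at_source_species, source_body_weight_kg)``; ``human_observed``
    maps the same labels to observed target-species values.  For each grid
    exponent the target value is predicted for every label and the geometric
    mean of pred/obs ratios is formed (``folded=True`` folds each ratio to
    ≥1 first); the exponent whose metric is closest to 1 in log space wins.
    Ties prefer the exponent nearer the grid midpoint, then the smaller
    magnitude.
    """
    keys = [k for k in species_values if k in human_observed]
    if not keys:
        raise ValidationError("no overlapping parameters between source and observed")
    if not (grid_min < grid_max) or step <= 0:
        raise ValidationError("need grid_min < grid_max and step > 0")
    n = int(round((grid_max - grid_min) / step))
    grid = grid_min + step * np.arange(n + 1)
    metric = np.empty_like(grid)
    for i, alpha in enumerate(grid):
        ratios = []
        for k in keys:
            value, w_source = species_values[k]
            pred = allometric_predict(value, w_source, w_target, alpha)
            r = pred / human_observed[k]
            ratios.append(max(r, 1.0 / r) if folded else r)
        metric[i] = geometric_mean(ratios)
    score = np.abs(np.log(metric))
    mid = 0.5 * (grid_min + grid_max)
    order = sorted(
        range(len(grid)),
        key=lambda i: (round(score[i], 12), round(abs(grid[i] - mid), 12), abs(grid[i])),
    )
    return ExponentGridResult(grid=grid, metric=metric,
                              selected_exponent=float(grid[order[0]]), folded=folded)
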