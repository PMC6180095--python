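"""Cross-age statistics for playground head-impact metrics.

Works on a tidy kinematics table with one row per (age, impact direction)
and columns for HIC variants, peak resultant kinematics and optional tissue
metrics.  Provides the direction-spread statistic, direction averaging with
range bars, linear and exponential age regressions, the HIC-strain linear
relation and its inversion at a strain threshold, and ratio-rule scaling of
the HIC = 1000 reference into age-dependent thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidParameterError

__all__ = [
    "DIRECTIONS",
    "METRIC_COLUMNS",
    "FitResult",
    "validate_table",
    "direction_difference_pct",
    "average_over_directions",
    "fit_vs_age",
    "hic_at_mps",
    "scale_thresholds",
]

DIRECTIONS = ("front", "back", "side")

#: Canonical metric columns of a kinematics table (tissue columns optional).
METRIC_COLUMNS = (
    "hic",
    "hic15",
    "hic36",
    "peak_lin_g",
    "peak_ang_acc_rad_s2",
    "peak_ang_vel_rad_s",
    "mps",
    "skull_stress_mpa",
)
_REQUIRED = ("age_years", "direction", "hic")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy-table contract; returns the table for chaining."""
    for col in _REQUIRED:
        if col not in table.columns:
            raise InvalidParameterError(f"kinematics table missing column {col!r}")
    if (table["age_years"] <= 0).any():
        raise InvalidParameterError("ages must be positive")
    unknown = set(table["direction"]) - set(DIRECTIONS)
    if unknown:
        raise InvalidParameterError(f"unknown impact directions {sorted(unknown)}")
    if table.duplicated(subset=["age_years", "direction"]).any():
        raise InvalidParameterError("at most one row per (age, direction)")
    metric_cols = [c for c in METRIC_COLUMNS if c in table.columns]
    if (table[metric_cols] < 0).any().any():
        raise InvalidParameterError("metric values must be >= 0")
    return table


def direction_difference_pct(values: Sequence[float]) -> float:
    """Spread between impact directions as a percent of the largest value.

    100 * (max - min) / max, e.g. 3YO HIC (877.3, 941.7, 811.5) -> 13.8.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InvalidParameterError("need at least two direction values")
    if np.any(vals <= 0):
        raise InvalidParameterError("direction values must all be positive")
    return float(100.0 * (vals.max() - vals.min()) / vals.max())


def average_over_directions(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-age mean over impact directions, with min/max for range bars.

    Returns a frame indexed by ``age_years`` with columns mean/min/max.
    """
    validate_table(table)
    if metric not in table.columns:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    sub = table.dropna(subset=[metric])
    if sub.empty:
        raise InvalidParameterError(f"metric {metric!r} has no values")
    grouped = sub.groupby("age_years")[metric].agg(["mean", "min", "max"])
    return grouped.sort_index()


@dataclass(frozen=True)
class FitResult:
    """A fitted age (or metric) trend with goodness of fit.

    ``params`` holds ``intercept``/``slope`` for the linear model
    y = intercept + slope * t, or ``a``/``b`` for the exponential model
    y = a * exp(b * t).  ``r_squared`` is 1 - SS_res/SS_tot on the original
    scale.
    """

    model: str
    params: Mapping[str, float]
    r_squared: float

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            out = self.params["intercept"] + self.params["slope"] * t
        else:
            out = self.params["a"] * np.exp(self.params["b"] * t)
        return float(out) if out.ndim == 0 else out


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_vs_age(
    ages: Iterable[float], y: Iterable[float], model: str = "linear"
) -> FitResult:
    """Least-squares trend of a metric against age.

    linear: ordinary least squares y = intercept + slope*age.
    exponential: y = a*exp(b*age), log-linear initialization refined by
    nonlinear least squares on the original scale (requires y > 0 for the
    initialization).
    """
    t = np.asarray(list(ages), dtype=float)
    v = np.asarray(list(y), dtype=float)
    if t.size != v.size or t.size < 3:
        raise InvalidParameterError("need >= 3 (age, value) pairs of equal length")
    if np.ptp(t) == 0:
        raise InvalidParameterError("singular fit: all ages identical")
    if model == "linear":
        slope, intercept = np.polyfit(t, v, 1)
        fit = FitResult("linear", {"intercept": float(intercept), "slope": float(slope)}, 0.0)
        return FitResult("linear", fit.params, _r_squared(v, np.asarray(fit.predict(t))))
    if model == "exponential":
        if np.any(v <= 0):
            raise InvalidParameterError("exponential fit requires positive values")
        b0, loga0 = np.polyfit(t, np.log(v), 1)
        popt, _ = curve_fit(
            lambda tt, a, b: a * np.exp(b * tt), t, v, p0=(np.exp(loga0), b0), maxfev=10000
        )
        fit = FitResult("exponential", {"a": float(popt[0]), "b": float(popt[1])}, 0.0)
        return FitResult("exponential", fit.params, _r_squared(v, np.asarray(fit.predict(t))))
    raise InvalidParameterError(f"unknown model {model!r}; use 'linear' or 'exponential'")


def hic_at_mps(table: pd.DataFrame, mps_value: float = 0.3) -> tuple[float, FitResult]:
    """HIC corresponding to a brain-strain level, from the HIC-MPS relation.

    Direction-averages HIC and MPS per age, fits HIC = a + b*MPS by ordinary
    least squares, and evaluates the line at ``mps_value``.  Returns the HIC
    and the fit (whose r_squared mirrors the linear-correlation quality).
    """
    validate_table(table)
    if "mps" not in table.columns:
        raise InvalidParameterError("table has no 'mps' column")
    hic_mean = average_over_directions(table, "hic")["mean"]
    mps_mean = average_over_directions(table, "mps")["mean"]
    joined = pd.concat([hic_mean, mps_mean], axis=1, keys=["hic", "mps"]).dropna()
    if len(joined) < 3:
        raise InvalidParameterError("need direction-averaged hic and mps for >= 3 ages")
    slope, intercept = np.polyfit(joined["mps"], joined["hic"], 1)
    fit = FitResult("linear", {"intercept": float(intercept), "slope": float(slope)}, 0.0)
    fit = FitResult("linear", fit.params, _r_squared(
        joined["hic"].to_numpy(), np.asarray(fit.predict(joined["mps"].to_numpy()))
    ))
    return float(intercept + slope * mps_value), fit


def scale_thresholds(
    reference_hic: float,
    tissue_by_age: Mapping[float, float],
    reference_age: float,
    rule: str = "ratio",
) -> dict[float, float]:
    """Age-dependent HIC thresholds from a tissue-response ratio rule.

    threshold(age) = reference_hic * tissue(reference_age) / tissue(age):
    ages whose tissue response at equal loading exceeds the reference age's
    get a proportionally lower HIC allowance.  The reference age maps to
    exactly ``reference_hic``.
    """
    if rule != "ratio":
        raise InvalidParameterError(f"unknown scaling rule {rule!r}")
    if reference_age not in tissue_by_age:
        raise InvalidParameterError(f"reference age {reference_age} not in tissue map")
    if any(v <= 0 for v in tissue_by_age.values()):
        raise InvalidParameterError("tissue values must be positive")
    ref = tissue_by_age[reference_age]
    return {age: reference_hic * ref / val for age, val in tissue_by_age.items()}
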