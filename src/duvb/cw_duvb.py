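"""Cumulative weighted D-UVB (CW-D-UVB): a recency-weighted exposure score.

Serum 25(OH)D integrates UVB exposure over the preceding weeks to months
(half-life one to two months), so the dose on the measurement day itself is
a poor proxy of status.  CW-D-UVB instead sums the diurnal doses of the 135
days strictly preceding the date of interest, each multiplied by a weight
that decreases with lag, so recent exposure counts more than distant
exposure.

The weighting function is configurable; two parametric schemes satisfying
the qualitative contract (w(0) = 1, positive, non-increasing, 135-day
window) ship with the package:

* ``linear_taper`` (default): w(k) = (L - k)/L over lag k = 0..L-1;
* ``exponential``: w(k) = 0.5^(k / half_life), default half-life 45 days,
  truncated at the window.

Weights are deliberately *not* normalised to sum to one, so the score keeps
kJ/m^2 units at the scale conventionally used for 25(OH)D regressions
(changes per 100 kJ/m^2).  Both forms are reconstructions consistent with
the published qualitative description, selected by configuration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .series_io import DailyDoseSeries

__all__ = ["WeightScheme", "CWSeries", "make_weights", "cw_series", "monthly_cw"]


@dataclass(frozen=True)
class WeightScheme:
    """Lag-weighting scheme for the CW-D-UVB window."""

    form: Literal["linear_taper", "exponential"] = "linear_taper"
    window_days: int = 135
    half_life_days: float = 45.0

    def __post_init__(self) -> None:
        if self.form not in ("linear_taper", "exponential"):
            raise ValueError(f"unknown weight form {self.form!r}")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.form == "exponential" and not self.half_life_days > 0:
            raise ValueError("half_life_days must be positive")


@dataclass(frozen=True)
class CWSeries:
    """Date-indexed CW-D-UVB scores; NaN where the lookback is incomplete."""

    location_name: str
    frame: pd.DataFrame  # DatetimeIndex 'date', column 'cw'

    def __post_init__(self) -> None:
        if list(self.frame.columns) != ["cw"]:
            raise ValueError("frame must have exactly the column ['cw']")
        vals = self.frame["cw"].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < -1e-12):
            raise ValueError("CW values must be non-negative where present")


def make_weights(scheme: WeightScheme) -> np.ndarray:
    """Weight vector w(k), k = 0..window-1; w(0) = 1, positive, non-increasing."""
    k = np.arange(scheme.window_days, dtype=float)
    if scheme.form == "linear_taper":
        L = float(scheme.window_days)
        return (L - k) / L
    return 0.5 ** (k / scheme.half_life_days)


def cw_series(series: DailyDoseSeries, scheme: WeightScheme | None = None) -> CWSeries:
    """CW(t) = sum over k = 1..window of w(k-1) * dose(t - k).

    The day t itself is excluded (the window is the strictly preceding 135
    days).  The input is reindexed to a gap-free daily calendar; any missing
    or absent dose inside a window makes that day's CW missing, so CW is
    defined exactly where the lookback is complete.
    """
    scheme = scheme or WeightScheme()
    w = make_weights(scheme)
    L = scheme.window_days
    full_idx = pd.date_range(series.dates[0], series.dates[-1], freq="D", name="date")
    dose = series.frame["dose"].reindex(full_idx).to_numpy(dtype=float)
    conv = np.convolve(dose, w, mode="full")  # conv[m] = sum_j dose[j] w[m-j]
    cw = np.full(len(dose), np.nan)
    if len(dose) > L:
        cw[L:] = conv[L - 1:len(dose) - 1]
    frame = pd.DataFrame({"cw": cw}, index=full_idx)
    return CWSeries(location_name=series.location.name, frame=frame)


def monthly_cw(cw: CWSeries) -> pd.Series:
    """Calendar-month means of the computable CW values over all years."""
    vals = cw.frame["cw"].dropna()
    if vals.empty:
        raise ValueError("no computable CW values (series shorter than the window?)")
    out = vals.groupby(vals.index.month).mean()
    out.index.name = "month"
    if len(out) < 12:
        raise ValueError("need at least one full year of computable CW values")
    return out
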