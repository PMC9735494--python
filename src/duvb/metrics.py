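"""Descriptive D-UVB statistics: climatology, monthly/annual summaries,
peak/trough fold ratios and the vitamin D winter.

The central object is the day-of-year *climatology*: for each of the 365
calendar days (Feb 29 omitted) the mean and SD of the diurnal dose over the
available years.  Monthly and annual summaries are computed from the 365
day entries, so the annual cumulative dose is exactly 365 times the annual
mean, and the annual mean equals the day-weighted combination of the
monthly means.

A reference table of monthly/annual mean (SD) diurnal D-UVB doses for 46
European capitals over an 18-year satellite record ships with the package
(``load_table1``) so the summary statistics can be exercised against real
published magnitudes without any download.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .series_io import DailyDoseSeries

__all__ = [
    "DAYS_IN_MONTH",
    "Climatology",
    "MonthlyStats",
    "AnnualStats",
    "VitaminDWinter",
    "build_climatology",
    "monthly_stats",
    "annual_stats",
    "annual_mean_from_monthly",
    "peak_trough_ratio",
    "vitamin_d_winter",
    "load_table1",
    "table1_monthly_stats",
    "table1_annual",
]

# non-leap calendar; the climatology drops Feb 29
DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
MONTH_NAMES = ("January", "February", "March", "April", "May", "June", "July",
               "August", "September", "October", "November", "December")


@dataclass(frozen=True)
class Climatology:
    """365 day-of-year entries of (mean_dose, sd_dose, n_years) for one site.

    ``entries`` is indexed by (month, day), Feb 29 excluded, and carries the
    columns ``mean_dose``, ``sd_dose`` and ``n_years``.
    """

    location_name: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        if len(df) != 365:
            raise ValueError(f"climatology must have exactly 365 day entries, got {len(df)}")
        if (2, 29) in df.index:
            raise ValueError("climatology must not contain Feb 29")
        if (df["mean_dose"] < 0).any():
            raise ValueError("day means must be non-negative")
        if (df["n_years"] < 1).any():
            raise ValueError("each day needs at least one observed year")

    @property
    def day_means(self) -> np.ndarray:
        return self.entries["mean_dose"].to_numpy()


@dataclass(frozen=True)
class MonthlyStats:
    """Per-month mean and SD of the climatological day entries (12 rows)."""

    location_name: str
    table: pd.DataFrame  # index month 1..12, columns mean, sd

    def __post_init__(self) -> None:
        if list(self.table.index) != list(range(1, 13)):
            raise ValueError("monthly stats must cover months 1..12")
        if (self.table["mean"] < 0).any():
            raise ValueError("monthly means must be non-negative")

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


@dataclass(frozen=True)
class AnnualStats:
    """Annual mean/SD over the 365 day entries and the cumulative annual dose."""

    mean: float
    sd: float
    cumulative: float

    def __post_init__(self) -> None:
        if not np.isclose(self.cumulative, 365.0 * self.mean, rtol=1e-09, atol=1e-06):
            raise ValueError("cumulative must equal 365 x mean")


@dataclass(frozen=True)
class VitaminDWinter:
    """Days of the climatological year whose mean dose sits below threshold."""

    duration_days: int
    threshold: float
    below_days: tuple

    def __post_init__(self) -> None:
        if self.duration_days != len(self.below_days):
            raise ValueError("duration must equal the number of below-threshold days")


def build_climatology(series: DailyDoseSeries) -> Climatology:
    """Per-(month, day) mean/SD/n over years; Feb 29 and missing days dropped.

    SD uses the n-1 denominator; a day observed in a single year gets SD = 0
    (with a warning).  Raises if any of the 365 calendar days has no
    observation at all.
    """
    df = series.frame.dropna(subset=["dose"])
    if df.empty:
        raise ValueError("cannot build a climatology from an empty series")
    keep = ~((df.index.month == 2) & (df.index.day == 29))
    df = df[keep]
    grouped = df["dose"].groupby([df.index.month, df.index.day])
    agg = grouped.agg(mean_dose="mean", sd_dose="std", n_years="count")
    agg.index.names = ["month", "day"]
    if len(agg) < 365:
        raise ValueError(f"series covers only {len(agg)} of 365 calendar days")
    singles = agg["n_years"] == 1
    if singles.any():
        warnings.warn(f"{int(singles.sum())} day(s) observed in a single year; their SD is set to 0")
    agg.loc[singles, "sd_dose"] = 0.0
    agg = agg.sort_index()
    return Climatology(location_name=series.location.name, entries=agg)


def monthly_stats(clim: Climatology) -> MonthlyStats:
    """Month mean/SD over that month's 28-31 climatological day entries."""
    months = clim.entries.index.get_level_values("month")
    g = clim.entries["mean_dose"].groupby(months)
    table = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)})
    table.index.name = "month"
    return MonthlyStats(location_name=clim.location_name, table=table)


def annual_stats(clim: Climatology) -> AnnualStats:
    """Mean/SD over the 365 day entries; cumulative = sum of the day means."""
    means = clim.day_means
    return AnnualStats(mean=float(means.mean()), sd=float(means.std(ddof=1)),
                       cumulative=float(means.sum()))


def _monthly_means(monthly) -> np.ndarray:
    if isinstance(monthly, MonthlyStats):
        return monthly.means
    arr = np.asarray(monthly, dtype=float)
    if arr.shape != (12,):
        raise ValueError("expected 12 monthly means")
    return arr


def annual_mean_from_monthly(monthly) -> float:
    """Day-weighted annual mean from 12 monthly means (non-leap day counts)."""
    means = _monthly_means(monthly)
    days = np.asarray(DAYS_IN_MONTH, dtype=float)
    return float((means * days).sum() / 365.0)


def peak_trough_ratio(monthly) -> float:
    """Fold difference between the highest and lowest monthly mean dose."""
    means = _monthly_means(monthly)
    trough = means.min()
    if trough == 0.0:
        warnings.warn("trough month mean is zero; fold ratio is infinite")
        return float("inf")
    return float(means.max() / trough)


def vitamin_d_winter(clim: Climatology, threshold: float = 1.0) -> VitaminDWinter:
    """Count climatological days with mean dose strictly below ``threshold``.

    1 kJ/m^2 is the conventional limit below which cutaneous vitamin D
    synthesis is negligible; boundary days equal to the threshold count as
    synthesis days.
    """
    below = clim.entries["mean_dose"] < threshold
    days = tuple(clim.entries.index[below])
    return VitaminDWinter(duration_days=int(below.sum()), threshold=threshold,
                          below_days=days)


def load_table1() -> pd.DataFrame:
    """The packaged 46-capital reference table, indexed by city.

    Columns: ``annual_mean``, ``annual_sd`` and ``m{1..12}_mean``/``_sd``
    monthly pairs, all in kJ/m^2.
    """
    with resources.files("duvb.data").joinpath("table1_duvb.csv").open() as fh:
        return pd.read_csv(fh, index_col="city")


def table1_monthly_stats(city: str, table: pd.DataFrame | None = None) -> MonthlyStats:
    """MonthlyStats for one capital from the packaged reference table."""
    table = load_table1() if table is None else table
    row = table.loc[city]
    data = pd.DataFrame(
        {"mean": [row[f"m{m}_mean"] for m in range(1, 13)],
         "sd": [row[f"m{m}_sd"] for m in range(1, 13)]},
        index=pd.Index(range(1, 13), name="month"),
    )
    return MonthlyStats(location_name=city, table=data)


def table1_annual(city: str, table: pd.DataFrame | None = None) -> tuple[float, float]:
    """(annual mean, annual SD) for one capital from the reference table."""
    table = load_table1() if table is None else table
    row = table.loc[city]
    return float(row["annual_mean"]), float(row["annual_sd"])
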