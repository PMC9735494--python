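"""Daily D-UVB dose series: file I/O and the two missing-data rules.

A series is a strictly date-ordered table of diurnal doses with a per-day
provenance flag.  Two rules mirror how satellite dose products patch gaps:

* *blackout imputation* — a day with no retrieval is substituted with the
  mean dose for that calendar day at that location over the other years;
* *winter cloud factor* — days on which the cloud retrieval is geometrically
  impossible (noon SZA above 78 degrees) carry a clear-sky dose scaled by a
  fixed mean-attenuation factor of 0.7.

Canonical file dialect: headered CSV ``date,dose_kjm2,flag`` with ISO dates;
an empty dose field means missing.
"""
from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .solar_geometry import GeoLocation, noon_zenith_angle

__all__ = [
    "FLAGS",
    "FLAG_MEASURED",
    "FLAG_BLACKOUT_IMPUTED",
    "FLAG_WINTER_FACTOR",
    "FLAG_MISSING",
    "DailyDoseSeries",
    "SeriesFormatError",
    "read_daily_series",
    "write_daily_series",
    "impute_blackouts",
    "winter_gap_days",
    "apply_winter_cloud_factor",
]

FLAG_MEASURED = "measured"
FLAG_BLACKOUT_IMPUTED = "blackout_imputed"
FLAG_WINTER_FACTOR = "winter_factor"
FLAG_MISSING = "missing"
FLAGS = (FLAG_MEASURED, FLAG_BLACKOUT_IMPUTED, FLAG_WINTER_FACTOR, FLAG_MISSING)

# gap rule: the geostationary cloud retrieval fails above this noon SZA
WINTER_GAP_NOON_SZA = 78.0


class SeriesFormatError(ValueError):
    """Raised when a daily-series file violates the format contract."""


@dataclass(frozen=True)
class DailyDoseSeries:
    """Date-indexed diurnal D-UVB doses (kJ/m^2) with provenance flags.

    ``frame`` has a DatetimeIndex named ``date`` (strictly increasing,
    unique), a float ``dose`` column (NaN iff the day is missing) and a
    ``flag`` column drawn from :data:`FLAGS`.
    """

    location: GeoLocation
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if list(df.columns) != ["dose", "flag"]:
            raise ValueError("frame must have exactly the columns ['dose', 'flag']")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("frame index must be a DatetimeIndex of dates")
        if not df.index.is_monotonic_increasing or not df.index.is_unique:
            raise ValueError("dates must be strictly increasing (no duplicates)")
        bad_flags = set(df["flag"]) - set(FLAGS)
        if bad_flags:
            raise ValueError(f"unknown flags: {sorted(bad_flags)}")
        dose = df["dose"].to_numpy(dtype=float)
        missing = df["flag"].to_numpy() == FLAG_MISSING
        if np.any(np.isnan(dose) != missing):
            raise ValueError("dose must be NaN exactly on days flagged 'missing'")
        if np.any(dose[~missing] < 0):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def with_frame(self, frame: pd.DataFrame) -> "DailyDoseSeries":
        return DailyDoseSeries(location=self.location, frame=frame)


def series_from_records(location: GeoLocation, dates, doses, flags=None) -> DailyDoseSeries:
    """Build a series from parallel arrays; flags default to measured/missing."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)), name="date")
    dose = np.asarray(doses, dtype=float)
    if flags is None:
        flags = np.where(np.isnan(dose), FLAG_MISSING, FLAG_MEASURED)
    frame = pd.DataFrame({"dose": dose, "flag": list(flags)}, index=idx)
    return DailyDoseSeries(location=location, frame=frame)


def read_daily_series(path, location: GeoLocation) -> DailyDoseSeries:
    """Read a ``date,dose_kjm2,flag`` CSV into a validated series.

    Unparseable rows are reported with their 1-based line numbers; the flag
    column is optional and defaults to ``measured`` (``missing`` for empty
    dose fields).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SeriesFormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header[:2] != ["date", "dose_kjm2"]:
        raise SeriesFormatError(f"{path}: header must start with 'date,dose_kjm2'")
    dates, doses, flags, errors = [], [], [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = [p.strip() for p in raw.split(",")]
        try:
            date = _dt.date.fromisoformat(parts[0])
            dose_field = parts[1] if len(parts) > 1 else ""
            dose = float(dose_field) if dose_field else float("nan")
            flag = parts[2] if len(parts) > 2 and parts[2] else None
            if flag is None:
                flag = FLAG_MISSING if np.isnan(dose) else FLAG_MEASURED
            if flag not in FLAGS:
                raise ValueError(f"unknown flag {flag!r}")
            if not np.isnan(dose) and dose < 0:
                raise ValueError(f"negative dose {dose}")
            if flag == FLAG_MISSING and not np.isnan(dose):
                raise ValueError("flag 'missing' with a dose value")
        except (ValueError, IndexError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        dates.append(date)
        doses.append(dose)
        flags.append(flag)
    if errors:
        raise SeriesFormatError(f"{path}: " + "; ".join(errors))
    try:
        return series_from_records(location, dates, doses, flags)
    except ValueError as exc:
        raise SeriesFormatError(f"{path}: {exc}") from exc


def write_daily_series(series: DailyDoseSeries, path) -> None:
    """Write the canonical CSV dialect (read/write round-trip is the identity)."""
    with open(path, "w") as fh:
        fh.write("date,dose_kjm2,flag\n")
        for date, row in series.frame.iterrows():
            dose = "" if np.isnan(row["dose"]) else format(row["dose"], ".10g")
            fh.write(f"{date.date().isoformat()},{dose},{row['flag']}\n")


def impute_blackouts(series: DailyDoseSeries, return_report: bool = False):
    """Substitute missing days with the same-calendar-day multi-year mean.

    Every ``missing`` day with at least one observation on the same (month,
    day) in another year receives the mean of those observations and the
    flag ``blackout_imputed``; Feb 29 draws only on other leap years.  Days
    with an empty imputation base stay missing (summarised in the report).
    Measured values are never altered; the operation is idempotent.
    """
    df = series.frame.copy()
    missing_mask = df["flag"] == FLAG_MISSING
    if not missing_mask.any():
        return (series, {"imputed": 0, "unimputable": []}) if return_report else series
    key = list(zip(df.index.month, df.index.day))
    base = df.loc[~missing_mask, "dose"].groupby(
        [df.index[~missing_mask].month, df.index[~missing_mask].day]).mean()
    unimputable = []
    doses = df["dose"].to_numpy(dtype=float).copy()
    flags = df["flag"].to_numpy(dtype=object).copy()
    for pos in np.flatnonzero(missing_mask.to_numpy()):
        k = key[pos]
        if k in base.index:
            doses[pos] = base.loc[k]
            flags[pos] = FLAG_BLACKOUT_IMPUTED
        else:
            unimputable.append(df.index[pos].date())
    out = series.with_frame(pd.DataFrame({"dose": doses, "flag": flags}, index=df.index))
    report = {"imputed": int(missing_mask.sum()) - len(unimputable), "unimputable": unimputable}
    return (out, report) if return_report else out


def winter_gap_days(location: GeoLocation, year: int) -> list[_dt.date]:
    """Calendar days of ``year`` on which noon SZA exceeds 78 degrees."""
    out = []
    day = _dt.date(year, 1, 1)
    while day.year == year:
        if noon_zenith_angle(location, day) > WINTER_GAP_NOON_SZA:
            out.append(day)
        day += _dt.timedelta(days=1)
    return out


def apply_winter_cloud_factor(series: DailyDoseSeries, factor: float = 0.7,
                              gap_predicate=None) -> DailyDoseSeries:
    """Scale doses by ``factor`` on days without cloud retrieval.

    ``gap_predicate(date) -> bool`` marks the affected days; by default a
    day qualifies when noon SZA at the series location exceeds 78 degrees
    (the geostationary-retrieval limit).  Affected non-missing days are
    multiplied by ``factor`` and flagged ``winter_factor``; everything else
    is untouched.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("winter cloud factor must be in (0, 1]")
    if gap_predicate is None:
        loc = series.location
        gap_predicate = lambda d: noon_zenith_angle(loc, d) > WINTER_GAP_NOON_SZA
    df = series.frame.copy()
    flagged = np.array([gap_predicate(ts.date()) for ts in df.index])
    apply_mask = flagged & (df["flag"].to_numpy() != FLAG_MISSING)
    df.loc[apply_mask, "dose"] = df.loc[apply_mask, "dose"] * factor
    df.loc[apply_mask, "flag"] = FLAG_WINTER_FACTOR
    return series.with_frame(df)
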