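"""Solar position and daylight geometry.

A deliberately low-precision solar ephemeris: Spencer's Fourier expansions
for declination and the equation of time (accurate to roughly 0.3 degrees
and one minute respectively), the standard spherical-triangle zenith-angle
formula, and bisection for sunrise/sunset.  This is plenty for dose
climatology, where the solar zenith angle (SZA) enters only through the
airmass and the daylight window; full ephemeris precision buys nothing.

All instants are UTC.  A day's dose is attributed to the UTC calendar date
of its local solar noon.
"""
from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AXIAL_TILT_DEG",
    "GeoLocation",
    "SolarPosition",
    "DaylightWindow",
    "solar_declination",
    "equation_of_time",
    "solar_position",
    "solar_zenith_angle",
    "cos_zenith",
    "solar_noon_utc",
    "noon_zenith_angle",
    "daylight_window",
]

AXIAL_TILT_DEG = 23.45


@dataclass(frozen=True)
class GeoLocation:
    """A named site; the spatial key of every dose series.

    latitude in degrees north, longitude in degrees east, elevation in
    meters above sea level (the Dead Sea shore, -430 m, is the floor).
    """

    name: str
    latitude: float
    longitude: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude!r} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude!r} outside [-180, 180]")
        if not (math.isfinite(self.elevation) and self.elevation >= -430.0):
            raise ValueError(f"elevation {self.elevation!r} must be finite and >= -430 m")


@dataclass(frozen=True)
class SolarPosition:
    """Sun geometry at one instant: zenith angle, declination, hour angle (degrees)."""

    zenith_angle: float
    declination: float
    hour_angle: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zenith_angle <= 180.0:
            raise ValueError("zenith_angle outside [0, 180]")
        if abs(self.declination) > AXIAL_TILT_DEG + 1e-9:
            raise ValueError("declination exceeds Earth's axial tilt")


@dataclass(frozen=True)
class DaylightWindow:
    """Sunrise/sunset (UTC) for one date, or a polar-day/-night sentinel."""

    kind: str  # "normal" | "polar_night" | "polar_day"
    sunrise: _dt.datetime | None = None
    sunset: _dt.datetime | None = None

    @property
    def duration_hours(self) -> float:
        if self.kind == "polar_night":
            return 0.0
        if self.kind == "polar_day":
            return 24.0
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _check_doy(day_of_year) -> None:
    doy = np.asarray(day_of_year)
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year must be in 1..366")


def _gamma(day_of_year, hour_utc=12.0):
    """Fractional year in radians (Spencer's argument)."""
    return 2.0 * math.pi / 365.0 * (np.asarray(day_of_year, dtype=float) - 1.0 + (np.asarray(hour_utc, dtype=float) - 12.0) / 24.0)


def solar_declination(day_of_year, hour_utc=12.0):
    """Solar declination in degrees for a (1-based) day of year.

    Spencer's Fourier series, clipped to the axial-tilt bound; antisymmetric
    about the solstices to within the series' ~0.3 degree accuracy.
    Accepts scalars or arrays.
    """
    _check_doy(day_of_year)
    g = _gamma(day_of_year, hour_utc)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    decl_deg = np.clip(np.degrees(decl), -AXIAL_TILT_DEG, AXIAL_TILT_DEG)
    return float(decl_deg) if np.isscalar(day_of_year) else decl_deg


def equation_of_time(day_of_year, hour_utc=12.0):
    """Equation of time in minutes (true solar time minus mean solar time)."""
    _check_doy(day_of_year)
    g = _gamma(day_of_year, hour_utc)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    return float(eot) if np.isscalar(day_of_year) else eot


def cos_zenith(latitude_deg, declination_deg, hour_angle_deg):
    """cos(SZA) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(H); vectorised."""
    phi = np.radians(latitude_deg)
    dec = np.radians(declination_deg)
    ha = np.radians(hour_angle_deg)
    return np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(ha)


def _hour_angle_deg(longitude_deg, day_of_year, hours_utc):
    """Hour angle from longitude-corrected true solar time, degrees."""
    tst_hours = np.asarray(hours_utc, dtype=float) + longitude_deg / 15.0 + equation_of_time(day_of_year, hours_utc) / 60.0
    return 15.0 * (tst_hours - 12.0)


def _as_utc(instant: _dt.datetime) -> _dt.datetime:
    if instant.tzinfo is None:
        return instant.replace(tzinfo=_dt.timezone.utc)
    return instant.astimezone(_dt.timezone.utc)


def solar_position(loc: GeoLocation, instant: _dt.datetime) -> SolarPosition:
    """Solar position at a UTC instant (naive datetimes are taken as UTC)."""
    instant = _as_utc(instant)
    doy = instant.timetuple().tm_yday
    hours = instant.hour + instant.minute / 60.0 + instant.second / 3600.0
    decl = solar_declination(doy, hours)
    ha = float(_hour_angle_deg(loc.longitude, doy, hours))
    # wrap the hour angle to (-180, 180] so it reads as a local angle
    ha = (ha + 180.0) % 360.0 - 180.0
    mu = float(np.clip(cos_zenith(loc.latitude, decl, ha), -1.0, 1.0))
    return SolarPosition(zenith_angle=math.degrees(math.acos(mu)), declination=decl, hour_angle=ha)


def solar_zenith_angle(loc: GeoLocation, instant: _dt.datetime) -> float:
    """Solar zenith angle in degrees at a UTC instant."""
    return solar_position(loc, instant).zenith_angle


def zenith_angles(loc: GeoLocation, date: _dt.date, hours_utc) -> np.ndarray:
    """Vectorised SZA (degrees) over an array of UTC hours on one date."""
    doy = date.timetuple().tm_yday
    hours_utc = np.asarray(hours_utc, dtype=float)
    decl = solar_declination(np.full_like(hours_utc, doy), hours_utc)
    ha = _hour_angle_deg(loc.longitude, np.full_like(hours_utc, doy), hours_utc)
    mu = np.clip(cos_zenith(loc.latitude, decl, ha), -1.0, 1.0)
    return np.degrees(np.arccos(mu))


def solar_noon_utc(loc: GeoLocation, date: _dt.date) -> _dt.datetime:
    """UTC instant of local solar noon on a calendar date."""
    doy = date.timetuple().tm_yday
    noon_hours = 12.0 - loc.longitude / 15.0 - equation_of_time(doy) / 60.0
    base = _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc)
    return base + _dt.timedelta(hours=float(noon_hours))


def noon_zenith_angle(loc: GeoLocation, date: _dt.date) -> float:
    """SZA at local solar noon; equals |latitude - declination| up to ephemeris error."""
    return solar_zenith_angle(loc, solar_noon_utc(loc, date))


def _bisect_horizon(loc: GeoLocation, lo: _dt.datetime, hi: _dt.datetime) -> _dt.datetime:
    """Find the SZA = 90 crossing between lo and hi to 1-minute resolution."""
    f_lo = solar_zenith_angle(loc, lo) - 90.0
    while (hi - lo) > _dt.timedelta(minutes=1):
        mid = lo + (hi - lo) / 2
        f_mid = solar_zenith_angle(loc, mid) - 90.0
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return lo + (hi - lo) / 2


def daylight_window(loc: GeoLocation, date: _dt.date) -> DaylightWindow:
    """Sunrise and sunset (UTC, 1-minute resolution) bracketing local solar noon.

    Returns the ``polar_night`` sentinel when the sun never rises and
    ``polar_day`` when it never sets on that date.
    """
    noon = solar_noon_utc(loc, date)
    half = _dt.timedelta(hours=12)
    if solar_zenith_angle(loc, noon) >= 90.0:
        return DaylightWindow(kind="polar_night")
    if solar_zenith_angle(loc, noon - half) < 90.0 and solar_zenith_angle(loc, noon + half) < 90.0:
        return DaylightWindow(kind="polar_day")
    sunrise = _bisect_horizon(loc, noon - half, noon)
    sunset = _bisect_horizon(loc, noon, noon + half)
    return DaylightWindow(kind="normal", sunrise=sunrise, sunset=sunset)
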