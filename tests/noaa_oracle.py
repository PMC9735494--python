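"""Independent solar-position oracle for cross-checking tests.

A from-scratch implementation of NOAA's "General Solar Position
Calculations" (Julian-century mean longitude / mean anomaly / equation of
center / apparent longitude / true obliquity), an entirely different route
to declination, the equation of time and the zenith angle than the
package's Spencer-series ephemeris.  Used only as a test oracle.
"""
from __future__ import annotations

import datetime as dt
import math


def _julian_day(instant: dt.datetime) -> float:
    frac = (instant.hour + instant.minute / 60.0 + instant.second / 3600.0) / 24.0
    return instant.toordinal() + 1721424.5 + frac


def noaa_solar_angles(instant: dt.datetime, latitude: float, longitude: float):
    """(zenith_angle_deg, declination_deg, eqtime_minutes) at a UTC instant."""
    jd = _julian_day(instant)
    jc = (jd - 2451545.0) / 36525.0

    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
         + math.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    eps_r = math.radians(eps)

    decl = math.degrees(math.asin(math.sin(eps_r) * math.sin(math.radians(app_long))))

    y = math.tan(eps_r / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * e * math.sin(mr)
        + 4.0 * e * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr))

    minutes = instant.hour * 60.0 + instant.minute + instant.second / 60.0
    tst = minutes + eqtime + 4.0 * longitude
    ha = tst / 4.0 - 180.0

    phi = math.radians(latitude)
    dr = math.radians(decl)
    mu = (math.sin(phi) * math.sin(dr)
          + math.cos(phi) * math.cos(dr) * math.cos(math.radians(ha)))
    zen = math.degrees(math.acos(max(-1.0, min(1.0, mu))))
    return zen, decl, eqtime
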