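"""A small registry of European capital coordinates used throughout the
package as simulation sites (latitude deg N, longitude deg E, elevation m)."""
from __future__ import annotations

from .solar_geometry import GeoLocation

__all__ = ["CAPITALS", "capital"]

_RAW = {
    # name: (lat, lon, elev_m)
    "Nicosia": (35.19, 33.38, 150.0),
    "Valletta": (35.90, 14.51, 20.0),
    "Athens": (37.98, 23.73, 70.0),
    "Lisbon": (38.72, -9.14, 45.0),
    "Madrid": (40.42, -3.70, 657.0),
    "Rome": (41.90, 12.50, 21.0),
    "Sofia": (42.70, 23.32, 550.0),
    "Belgrade": (44.82, 20.46, 117.0),
    "Bern": (46.95, 7.45, 542.0),
    "Vienna": (48.21, 16.37, 171.0),
    "Paris": (48.86, 2.35, 35.0),
    "Prague": (50.08, 14.44, 200.0),
    "Kiev": (50.45, 30.52, 179.0),
    "Brussels": (50.80, 4.36, 56.0),
    "London": (51.51, -0.13, 11.0),
    "Berlin": (52.52, 13.41, 34.0),
    "Dublin": (53.35, -6.26, 20.0),
    "Vilnius": (54.69, 25.28, 112.0),
    "Copenhagen": (55.68, 12.57, 14.0),
    "Moscow": (55.76, 37.62, 156.0),
    "Riga": (56.95, 24.11, 6.0),
    "Stockholm": (59.33, 18.07, 28.0),
    "Tallinn": (59.44, 24.75, 9.0),
    "Oslo": (59.91, 10.75, 23.0),
    "Helsinki": (60.17, 24.94, 16.0),
    "Reykjavik": (64.15, -21.94, 15.0),
}

CAPITALS: dict[str, GeoLocation] = {
    name: GeoLocation(name=name, latitude=lat, longitude=lon, elevation=elev)
    for name, (lat, lon, elev) in _RAW.items()
}


def capital(name: str) -> GeoLocation:
    """Look up a capital by name (KeyError with the known names otherwise)."""
    try:
        return CAPITALS[name]
    except KeyError:
        raise KeyError(f"unknown capital {name!r}; known: {sorted(CAPITALS)}") from None
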