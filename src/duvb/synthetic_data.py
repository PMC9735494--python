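"""Synthetic TEMIS-like daily D-UVB series and matched 25(OH)D study tables.

The generator is the package's stand-in for the satellite dose record: for
each site it computes the clear-sky diurnal D-UVB dose per day of year
(cached - the clear sky depends on the calendar day only), then produces a
multi-year daily series by

* multiplying each day's clear-sky dose by a random cloud modification
  factor drawn from a Beta distribution rescaled to (0.2, 1.0] whose
  variance grows with the clear-sky dose (cloud losses matter most, and
  day-to-day dose varies most, in summer);
* marking a Bernoulli fraction of days as blackout days (missing);
* on days whose noon SZA exceeds 78 degrees (no cloud retrieval possible),
  publishing the clear-sky dose scaled by the fixed 0.7 mean attenuation.

Seasonal total-column ozone follows a cosine with a springtime maximum.
Each location draws from its own random stream split off the master seed,
so adding a location never perturbs the others, and a fixed seed makes the
whole pipeline reproducible bit-for-bit.

``generate_study_tables`` builds the generative twin of the 25(OH)D
linkage: study-level monthly means constructed as
``baseline + true_slope * (CW[m] - CW[March]) + noise`` around known ground
truth, which the regression stage should recover.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locations import CAPITALS
from .series_io import (FLAG_MEASURED, FLAG_MISSING, FLAG_WINTER_FACTOR,
                        WINTER_GAP_NOON_SZA, DailyDoseSeries)
from .solar_geometry import GeoLocation, noon_zenith_angle
from .spectral_model import (ActionSpectrum, AtmosphereParams,
                             default_atmosphere, diurnal_duvb_dose,
                             load_action_spectrum)

__all__ = ["StudySpec", "ScenarioConfig", "clearsky_doy_doses",
           "generate_series", "generate_study_tables"]

_CLOUD_FLOOR = 0.2  # rescale Beta draws into (0.2, 1.0]


@dataclass(frozen=True)
class StudySpec:
    """Generative design of the synthetic 25(OH)D study tables.

    ``true_slope`` is in nmol/L per kJ/m^2 of CW-D-UVB (0.126 by default,
    i.e. 12.6 nmol/L per 100 kJ/m^2, the population-based regime);
    ``noise_sd`` is the scatter of a study's reported monthly mean in
    nmol/L (2.5 by default, the order of the standard error of a monthly
    cohort mean in population-based studies).
    """

    n_studies: int = 9
    months: tuple = tuple(range(1, 13))
    true_slope: float = 0.126
    noise_sd: float = 2.5
    baseline_mean: float = 50.0
    baseline_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if 3 not in self.months:
            raise ValueError("March must be observed (it is the reference month)")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise/baseline SDs must be non-negative")


def _default_locations() -> tuple:
    return (CAPITALS["Athens"], CAPITALS["Dublin"], CAPITALS["Reykjavik"])


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic record.

    Defaults mirror the emulated satellite record: an 18-year span
    (2004-2021), springtime-peaking ozone around 330 DU, mean cloud
    transmission ~0.7, and a few percent blackout days.
    """

    locations: tuple = field(default_factory=_default_locations)
    years: tuple = (2004, 2021)
    ozone_mean_du: float = 330.0
    ozone_amplitude_du: float = 30.0
    cloud_mean: float = 0.7
    cloud_concentration: float = 8.0
    blackout_rate: float = 0.05
    seed: int = 0
    study_spec: StudySpec = field(default_factory=StudySpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.blackout_rate < 1.0:
            raise ValueError("blackout_rate must be in [0, 1)")
        if not _CLOUD_FLOOR < self.cloud_mean <= 1.0:
            raise ValueError(f"cloud_mean must be in ({_CLOUD_FLOOR}, 1]")
        if self.cloud_concentration <= 0:
            raise ValueError("cloud_concentration must be positive")
        if self.years[0] > self.years[1]:
            raise ValueError("years must be (first, last) with first <= last")
        if self.ozone_mean_du - self.ozone_amplitude_du <= 0:
            raise ValueError("seasonal ozone must stay positive")


def _seasonal_ozone(doy: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """Total column ozone per day of year, DU; maximum in early spring (~doy 90)."""
    return cfg.ozone_mean_du + cfg.ozone_amplitude_du * np.cos(2 * np.pi * (doy - 90.0) / 365.25)


def clearsky_doy_doses(loc: GeoLocation, cfg: ScenarioConfig,
                       spectrum: ActionSpectrum | None = None) -> np.ndarray:
    """Clear-sky diurnal dose (kJ/m^2) for day-of-year 1..366 at one site.

    Computed once per site on a leap reference year and reused across the
    simulated years (the clear sky depends only on the calendar day).
    """
    spectrum = spectrum or load_action_spectrum()
    doys = np.arange(1, 367)
    ozone = _seasonal_ozone(doys.astype(float), cfg)
    ref_year = 2004  # leap year -> all 366 calendar days exist
    out = np.empty(366)
    for i, doy in enumerate(doys):
        date = _dt.date(ref_year, 1, 1) + _dt.timedelta(days=int(doy) - 1)
        params = default_atmosphere(total_column_ozone=float(ozone[i]))
        out[i] = diurnal_duvb_dose(loc, date, params, spectrum).dose
    return out


def _gap_doys(loc: GeoLocation) -> np.ndarray:
    """Day-of-year mask (366,) of noon-SZA > 78 deg retrieval-gap days."""
    ref_year = 2004
    mask = np.zeros(366, dtype=bool)
    for doy in range(1, 367):
        date = _dt.date(ref_year, 1, 1) + _dt.timedelta(days=doy - 1)
        mask[doy - 1] = noon_zenith_angle(loc, date) > WINTER_GAP_NOON_SZA
    return mask


def generate_series(cfg: ScenarioConfig) -> dict[str, DailyDoseSeries]:
    """Generate one multi-year daily D-UVB series per configured location."""
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.locations))
    out = {}
    for loc, ss in zip(cfg.locations, streams):
        rng = np.random.default_rng(ss)
        clearsky = clearsky_doy_doses(loc, cfg)
        gap = _gap_doys(loc)
        rel = clearsky / clearsky.max() if clearsky.max() > 0 else np.zeros_like(clearsky)

        dates = pd.date_range(_dt.date(cfg.years[0], 1, 1),
                              _dt.date(cfg.years[1], 12, 31), freq="D")
        doy_idx = np.array([d.timetuple().tm_yday - 1 for d in dates])
        # map non-leap years onto the leap-year table: after Feb 28 shift by one
        nonleap = ~np.array([d.is_leap_year for d in dates])
        after_feb = np.array([(d.month, d.day) > (2, 28) for d in dates])
        doy_idx = doy_idx + (nonleap & after_feb)

        cs = clearsky[doy_idx]
        # cloud factor: Beta on (0, 1), rescaled to (0.2, 1.0]; concentration
        # drops (variance grows) as the clear-sky dose rises
        mu_unit = (cfg.cloud_mean - _CLOUD_FLOOR) / (1.0 - _CLOUD_FLOOR)
        kappa = cfg.cloud_concentration * (1.5 - rel[doy_idx])
        cloud = _CLOUD_FLOOR + (1.0 - _CLOUD_FLOOR) * rng.beta(mu_unit * kappa,
                                                               (1.0 - mu_unit) * kappa)
        blackout = rng.random(len(dates)) < cfg.blackout_rate

        dose = cs * cloud
        flags = np.full(len(dates), FLAG_MEASURED, dtype=object)
        gap_mask = gap[doy_idx] & ~blackout
        dose[gap_mask] = cs[gap_mask] * 0.7
        flags[gap_mask] = FLAG_WINTER_FACTOR
        dose[blackout] = np.nan
        flags[blackout] = FLAG_MISSING

        frame = pd.DataFrame({"dose": dose, "flag": flags},
                             index=pd.DatetimeIndex(dates, name="date"))
        out[loc.name] = DailyDoseSeries(location=loc, frame=frame)
    return out


def generate_study_tables(cfg: ScenarioConfig, cw_monthly_by_city: dict):
    """Synthetic study-level monthly 25(OH)D tables with known ground truth.

    Each study draws a baseline March 25(OH)D level, is assigned a capital
    (cycling through ``cw_monthly_by_city``), and reports
    ``baseline + true_slope * (CW[m] - CW[3]) + eps`` for each observed
    month, ``eps ~ N(0, noise_sd)``.  Returns ``(studies, ground_truth)``
    where ``studies`` matches the study-table CSV schema and
    ``ground_truth`` records the generative parameters.
    """
    spec = cfg.study_spec
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(
        len(cfg.locations) + 1)[-1])
    cities = list(cw_monthly_by_city)
    if not cities:
        raise ValueError("need at least one city CW profile")
    rows = []
    for s in range(spec.n_studies):
        city = cities[s % len(cities)]
        cw = pd.Series(cw_monthly_by_city[city]).astype(float)
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
        for m in spec.months:
            eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            val = baseline + spec.true_slope * (cw.loc[m] - cw.loc[3]) + eps
            rows.append({
                "study_id": f"synth{s + 1:02d}",
                "cohort_class": "A",
                "city_rule": city,
                "month": m,
                "mean_25ohd_nmol_l": max(val, 1.0),
            })
    studies = pd.DataFrame(rows)
    truth = {"true_slope": spec.true_slope, "noise_sd": spec.noise_sd,
             "n_studies": spec.n_studies,
             "n_pairs": spec.n_studies * (len(spec.months) - 1)}
    return studies, truth
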