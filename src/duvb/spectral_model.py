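"""Clear-sky vitamin-D-weighted irradiance and diurnal D-UVB dose.

The model is a deliberately simplified plane-parallel, two-extinction
(ozone absorption + effective Rayleigh depth) Beer-Lambert transfer with the
Kasten-Young airmass, applied to an extraterrestrial solar spectrum on a
1-nm grid over 290-315 nm and weighted by the vitamin-D synthesis action
spectrum.  It emulates the *structure* of a satellite-derived D-UVB product
(seasonality, latitude dependence, ozone sensitivity); it is not a
radiative-transfer code and is never compared against satellite values.

Unit conventions: irradiance in W/m^2 (action-spectrum weighted), diurnal
dose in kJ/m^2, ozone in Dobson units (DU).
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .solar_geometry import GeoLocation, daylight_window, zenith_angles

__all__ = [
    "ActionSpectrum",
    "AtmosphereParams",
    "DiurnalDose",
    "load_action_spectrum",
    "export_action_spectrum",
    "default_atmosphere",
    "atmosphere_from_config",
    "airmass",
    "clearsky_weighted_irradiance",
    "diurnal_duvb_dose",
]

# 1-nm grid spanning the vitamin-D-active band.
WAVELENGTHS_NM = np.arange(290, 316, dtype=float)

# Relative previtamin-D3 synthesis efficiency per wavelength (reconstruction
# of the CIE action spectrum shape: unit peak at 297 nm, steep long-wave
# tail that is <1% by 315 nm).
_ACTION_WEIGHTS = np.array([
    0.713, 0.767, 0.806, 0.841, 0.887, 0.959, 0.993, 1.000, 0.986, 0.926,
    0.824, 0.696, 0.563, 0.441, 0.334, 0.248, 0.180, 0.129, 0.0914, 0.0637,
    0.0440, 0.0300, 0.0204, 0.0137, 0.00919, 0.00613,
])

# Extraterrestrial spectral irradiance anchors, W m^-2 nm^-1 (smoothed solar
# spectrum; linearly interpolated to the 1-nm grid).
_E0_ANCHORS_NM = np.array([290.0, 295.0, 300.0, 305.0, 310.0, 315.0])
_E0_ANCHORS = np.array([0.482, 0.584, 0.514, 0.603, 0.686, 0.767])

# Ozone absorption cross sections, 1e-19 cm^2 molecule^-1 (Hartley-Huggins
# band anchors; log-linearly interpolated — the band decays near-exponentially).
_O3_XS_ANCHORS = np.array([14.7, 7.55, 3.91, 1.91, 0.92, 0.45])
_MOLEC_PER_DU = 2.6868e16  # molecules cm^-2 per Dobson unit


@dataclass(frozen=True)
class ActionSpectrum:
    """Vitamin-D synthesis action spectrum on a 1-nm grid over 290-315 nm."""

    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())
    weights: np.ndarray = field(default_factory=lambda: _ACTION_WEIGHTS.copy())

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if wl.shape != w.shape:
            raise ValueError("wavelengths and weights must have the same shape")
        if not np.array_equal(wl, WAVELENGTHS_NM):
            raise ValueError("action spectrum must live on the 1-nm 290-315 nm grid")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.isclose(w.max(), 1.0):
            raise ValueError("maximum weight must be 1 (normalisation convention)")
        peak = wl[int(np.argmax(w))]
        if not 295.0 <= peak <= 298.0:
            raise ValueError(f"peak wavelength {peak} nm outside the 295-298 nm synthesis peak")
        if w[wl == 315.0] >= 0.01:
            raise ValueError("weight at 315 nm must be < 0.01")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "weights", w)

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.weights))])


def load_action_spectrum() -> ActionSpectrum:
    """The packaged vitamin-D action spectrum (unit peak at 297 nm)."""
    return ActionSpectrum()


def export_action_spectrum(path, spectrum: ActionSpectrum | None = None) -> None:
    """Write the action spectrum as two-column CSV (wavelength_nm, weight)."""
    spectrum = spectrum or load_action_spectrum()
    arr = np.column_stack([spectrum.wavelengths, spectrum.weights])
    np.savetxt(path, arr, fmt=("%.0f", "%.6g"), delimiter=",",
               header="wavelength_nm,weight", comments="")


def _default_o3_coeff() -> np.ndarray:
    """Per-DU ozone optical depth per wavelength (dimensionless / DU)."""
    log_xs = np.interp(WAVELENGTHS_NM, _E0_ANCHORS_NM, np.log(_O3_XS_ANCHORS))
    return np.exp(log_xs) * 1e-19 * _MOLEC_PER_DU


def _default_rayleigh() -> np.ndarray:
    """Effective Rayleigh optical depth per wavelength.

    Half the nadir molecular-scattering depth 0.00877 * lambda_um^-4.05:
    in the UV roughly half of the Rayleigh-scattered light still reaches the
    surface as diffuse irradiance, so only the other half acts as loss in a
    direct-beam Beer-Lambert model.
    """
    lam_um = WAVELENGTHS_NM / 1000.0
    return 0.5 * 0.00877 * lam_um ** -4.05


@dataclass(frozen=True)
class AtmosphereParams:
    """Atmospheric state and adjustment factors for the clear-sky model.

    Per-wavelength tables share the action-spectrum grid.  The cloud
    modification factor multiplies the diurnal dose (1.0 = clear sky);
    elevation_scaling is the fractional dose gain per km of surface
    elevation and surface_albedo feeds a (1 + 0.25 * albedo) enhancement.
    """

    total_column_ozone: float = 330.0  # DU
    ozone_cross_section: np.ndarray = field(default_factory=_default_o3_coeff)  # per DU
    rayleigh_optical_depth: np.ndarray = field(default_factory=_default_rayleigh)
    extraterrestrial_spectrum: np.ndarray = field(
        default_factory=lambda: np.interp(WAVELENGTHS_NM, _E0_ANCHORS_NM, _E0_ANCHORS)
    )  # W m^-2 nm^-1
    cloud_modification_factor: float = 1.0
    surface_albedo: float = 0.05
    elevation_scaling: float = 0.08  # fraction per km

    def __post_init__(self) -> None:
        if not self.total_column_ozone > 0:
            raise ValueError("total column ozone must be positive (DU)")
        if not 0.0 < self.cloud_modification_factor <= 1.2:
            raise ValueError("cloud modification factor must be in (0, 1.2]")
        if not 0.0 <= self.surface_albedo <= 1.0:
            raise ValueError("surface albedo must be in [0, 1]")
        if self.elevation_scaling < 0:
            raise ValueError("elevation scaling must be >= 0")
        for name in ("ozone_cross_section", "rayleigh_optical_depth", "extraterrestrial_spectrum"):
            tab = np.asarray(getattr(self, name), dtype=float)
            if tab.shape != WAVELENGTHS_NM.shape:
                raise ValueError(f"{name} must be tabulated on the 290-315 nm 1-nm grid")
            object.__setattr__(self, name, tab)


@dataclass(frozen=True)
class DiurnalDose:
    """One day's vitamin-D-weighted dose in kJ/m^2 (zero on polar night)."""

    date: _dt.date
    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


def default_atmosphere(**overrides) -> AtmosphereParams:
    """AtmosphereParams with packaged reference tables; scalars overridable."""
    return AtmosphereParams(**overrides)


def atmosphere_from_config(path) -> AtmosphereParams:
    """Load scalar AtmosphereParams overrides from a YAML key-value file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"total_column_ozone", "cloud_modification_factor",
               "surface_albedo", "elevation_scaling"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown atmosphere config keys: {sorted(unknown)}")
    return AtmosphereParams(**cfg)


def airmass(sza_deg):
    """Kasten-Young relative airmass, bounded as SZA -> 90 deg; vectorised."""
    z = np.minimum(np.asarray(sza_deg, dtype=float), 90.0)
    return 1.0 / (np.cos(np.radians(z)) + 0.50572 * (96.07995 - z) ** -1.6364)


def clearsky_weighted_irradiance(sza_deg, params: AtmosphereParams,
                                 spectrum: ActionSpectrum | None = None,
                                 elevation_m: float = 0.0):
    """Vitamin-D weighted clear-sky surface irradiance, W/m^2.

    Trapezoid integral over the 1-nm grid of
    ``E0(lam) * cos(SZA) * exp(-(sigma_O3 * ozone + tau_R) * m(SZA)) * w(lam)``,
    scaled by the elevation and albedo enhancements.  Zero for SZA >= 90.
    Accepts scalar or array SZA.
    """
    spectrum = spectrum or load_action_spectrum()
    if params.total_column_ozone <= 0:
        raise ValueError("total column ozone must be positive")
    sza = np.asarray(sza_deg, dtype=float)
    scalar = sza.ndim == 0
    sza = np.atleast_1d(sza)
    if np.any(sza < 0) or np.any(sza > 180):
        raise ValueError("SZA must be in [0, 180] degrees")

    mu = np.cos(np.radians(sza))
    up = sza < 90.0
    tau = (params.ozone_cross_section * params.total_column_ozone
           + params.rayleigh_optical_depth)  # (n_lambda,)
    m = airmass(sza)[:, None]
    trans = np.exp(-tau[None, :] * m)
    integrand = params.extraterrestrial_spectrum * trans * spectrum.weights
    band = np.trapezoid(integrand, spectrum.wavelengths, axis=1)
    out = np.where(up, band * np.maximum(mu, 0.0), 0.0)
    out *= (1.0 + params.elevation_scaling * elevation_m / 1000.0)
    out *= (1.0 + 0.25 * params.surface_albedo)
    return float(out[0]) if scalar else out


def diurnal_duvb_dose(loc: GeoLocation, date: _dt.date,
                      params: AtmosphereParams | None = None,
                      spectrum: ActionSpectrum | None = None,
                      step_minutes: float = 5.0) -> DiurnalDose:
    """Integrate weighted irradiance from sunrise to sunset into a diurnal dose.

    Midpoint rule on a ``step_minutes`` grid (5 min by default, must be
    <= 30); the result is multiplied by the cloud modification factor and
    returned in kJ/m^2.  Zero on polar night; polar day integrates the full
    24 h.
    """
    params = params or default_atmosphere()
    spectrum = spectrum or load_action_spectrum()
    if not 0 < step_minutes <= 30:
        raise ValueError("step_minutes must be in (0, 30]")
    window = daylight_window(loc, date)
    if window.kind == "polar_night":
        return DiurnalDose(date=date, dose=0.0)
    if window.kind == "polar_day":
        start_h, end_h = 0.0, 24.0
    else:
        day0 = _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc)
        start_h = (window.sunrise - day0).total_seconds() / 3600.0
        end_h = (window.sunset - day0).total_seconds() / 3600.0
    step_h = step_minutes / 60.0
    n = max(int(np.ceil((end_h - start_h) / step_h)), 1)
    mid = start_h + (np.arange(n) + 0.5) * (end_h - start_h) / n
    sza = zenith_angles(loc, date, mid)
    irr = clearsky_weighted_irradiance(sza, params, spectrum, elevation_m=loc.elevation)
    dt_seconds = (end_h - start_h) / n * 3600.0
    dose_kj = float(irr.sum() * dt_seconds / 1000.0) * params.cloud_modification_factor
    return DiurnalDose(date=date, dose=dose_kj)
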