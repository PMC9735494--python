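# Methods

This note documents the models behind `duvb`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Solar geometry

Declination and the equation of time use Spencer's Fourier expansions
(about 0.3° and 1 minute of accuracy), the zenith angle the standard
spherical-triangle formula `cos z = sin φ sin δ + cos φ cos δ cos H`, with
the hour angle from longitude-corrected true solar time. Full ephemeris
precision is pointless for dose climatology, where the solar zenith angle
(SZA) only drives the airmass and the daylight window. Declination is
clipped to ±23.45° to keep the axial-tilt invariant under the series'
small overshoot. All instants are UTC; a day's dose belongs to the UTC
date of its local solar noon. Sunrise/sunset are found by bisection on
SZA − 90° to 1-minute resolution, with explicit polar-day/-night
sentinels. Atmospheric refraction and topographic horizons are ignored.

Two consequences of Earth's orbital eccentricity are worth knowing when
testing: the declination track is mirror-symmetric about a solstice only
within ~±1 month (the asymmetry reaches ~0.8° at ±60 days), and on the
June solstice the diurnal dose *peaks near the subsolar latitude* (~23° N)
rather than at the equator — monotone decrease with latitude holds poleward
of the subsolar point, and everywhere on the equinox. The test suite
asserts the properties in that physically correct form. An independently
implemented NOAA-style solar-position algorithm serves as the test oracle
(agreement within 0.5° on a random grid).

## Clear-sky spectral model

The weighted surface irradiance is

    I(z) = ∫ E₀(λ) · cos z · exp(−[σ_O₃(λ)·Ω + τ_R(λ)]·m(z)) · w(λ) dλ

on a 1-nm grid over 290–315 nm (trapezoid rule), with `m(z)` the
Kasten–Young airmass (finite as z → 90°), `Ω` the total column ozone in
Dobson units, and `w(λ)` the vitamin-D action spectrum (unit peak at
297 nm, < 1% by 315 nm; the packaged table is a reconstruction of the CIE
previtamin-D3 spectrum shape). The result is scaled by `(1 + 0.08/km)` for
surface elevation and `(1 + 0.25·albedo)` — simple monotone placeholders
for adjustments that real products derive from retrievals. The diurnal
dose integrates `I` at 5-minute midpoints from sunrise to sunset
(refinement to 1 minute changes the dose by < 0.5%) and multiplies by a
cloud modification factor.

Parameter tables: the extraterrestrial spectrum is a smoothed solar
spectrum (0.48–0.77 W m⁻² nm⁻¹ across the band); ozone cross sections are
Hartley–Huggins band anchors log-interpolated per nm. The default
`rayleigh_optical_depth` is *half* the nadir molecular depth
`0.00877·λ_μm⁻⁴·⁰⁵`: in a direct-beam-only model, fully counting Rayleigh
extinction discards the roughly half of scattered photons that still reach
the ground; halving the scattering depth is the standard one-parameter
correction.

**Known limitation — absolute scale.** Without multiple scattering the
model underestimates absolute doses by roughly a factor of 3–4 relative to
satellite products (a simulated Athens clear-sky June day is ~3 kJ/m²),
and the deficit grows at high SZA, so simulated winters are deeper and
vitamin-D-winter durations longer than observed. The simulator is therefore
used *structurally only* — seasonality, latitude and ozone monotonicity,
fold ratios, lags — and is never compared against satellite values; all
absolute-magnitude statistics come from the packaged 46-capital reference
table. The irradiance formula was kept in the simple two-extinction form
deliberately; adding diffuse terms would buy realism the package's claims
do not depend on.

## Series rules

The canonical file dialect is headered CSV `date,dose_kjm2,flag` with flags
from {measured, blackout_imputed, winter_factor, missing}. Blackout
imputation replaces a missing day with the mean of the same (month, day)
over the other years (Feb 29 only from leap years); it never touches
measured values, is idempotent, and leaves every day-of-year mean exactly
unchanged relative to dropping the missing days (algebraically exact;
numerically to round-off, ~1e-16 relative — tests assert rtol 1e-12). Day
SDs shrink by construction, which is the price of mean-imputation. The
winter cloud factor (0.7) applies per-day by the noon-SZA > 78° criterion
rather than by a country list — the list is a consequence of the geometry:
the rule yields ~105 affected days/year at 64° N and ~11 at 54.7° N. In
the simulator the factor applies to clear-sky doses on gap days.

## Climatology and summaries

Climatologies have exactly 365 day entries (Feb 29 omitted); day SD uses
the n−1 denominator, defined as 0 with a warning when a day is observed in
a single year. Monthly statistics are the mean/SD over that month's 28–31
day entries; annual statistics over all 365, so `cumulative = 365 × mean`
exactly and the day-weighted recombination of monthly means
`Σ mᵢ·daysᵢ / 365` reproduces the annual mean exactly. The vitamin D
winter counts day entries with mean strictly below the threshold
(default 1 kJ/m²); boundary days count as synthesis days. Fold ratios are
max/min monthly mean; comparisons against published integer folds use
nearest-integer rounding. The packaged reference table is transcribed
verbatim (two obvious typography artifacts normalised: one "(0.1)0" → 0.10
and annual SDs printed with one decimal).

## CW-D-UVB

`CW(t) = Σₖ₌₁…L w(k−1)·dose(t−k)` with `L = 135` days and day `t` itself
excluded ("the 135 days preceding"). The published description defers the
weight function to earlier work without a formula, so two parametric
reconstructions ship, selected by configuration: a linear taper
`w(k) = (L−k)/L` (default; weight sum exactly 68) and a truncated
exponential `w(k) = 0.5^(k/45)` keyed to the 1–2-month half-life of
25(OH)D. Both satisfy the qualitative contract: `w(0)=1`, positive,
non-increasing, and an annual-cycle phase lag of 30–60 days (measured: 51
days on a seasonal sinusoid for both). Weights are deliberately not
normalised to sum 1, keeping kJ/m² units at the per-100-kJ/m² scale used
in the 25(OH)D regressions. CW is missing exactly where the 135-day
lookback is incomplete; any interior missing day invalidates exactly the
135 windows that contain it. "Day-to-day variance" in the smoothing claims
is made precise as `var(first differences)/mean²` — scale-free, so the
raw series and the ~68×-larger CW series are comparable; a noise-free
sinusoid has no meaningful day-to-day noise, so the ≥20-fold reduction is
asserted on a multiplicatively noisy input (measured: ~2500-fold).

## Delta-vs-March linkage

Studies report monthly mean 25(OH)D in nmol/L (no unit conversion is
attempted); each study must include March, the typical seasonal trough,
and contributes the pairs `(CW[m]−CW[3], 25OHD[m]−25OHD[3])` for its other
observed months, using its capital's monthly CW profile (or the elementwise
mean of two capitals via the `average(a, b)` city rule, for cohorts between
capitals). One OLS line is fitted per cohort class, pooling studies
without random effects — mirroring a single published slope/r²/p per
class — and without weighting by study size (a `weights` option provides
WLS for sensitivity analyses). The fit is closed-form (normal equations;
two-sided t-test on the slope with n−2 df, undefined for a saturated
two-point fit); statsmodels OLS is the independent oracle in tests
(agreement to 1e-10 relative). The slope is invariant to adding constants
to either axis — the delta construction makes baseline differences between
cohorts drop out exactly. No multiple-testing adjustment across the three
pre-specified classes.

## Synthetic generator

Defaults mirror the emulated record: 18 years (2004–2021), total ozone
`330 + 30·cos(2π(doy−90)/365.25)` DU (springtime maximum), blackout
probability 5%/day, cloud modification factors drawn per day from a Beta
distribution rescaled to (0.2, 1.0] with mean 0.7 and concentration
falling (variance rising) with the clear-sky dose — day-to-day dose varies
most in summer, when there is most to lose. Clear-sky doses are computed
once per day-of-year and site and reused across years. Each site draws
from its own stream split off the master seed (adding a site never
perturbs the others); a fixed seed makes series, climatology, CW and
regression byte-identical end to end.

The study-table generator produces
`25OHD[m] = baseline + 0.126·(CW[m]−CW[3]) + ε` per study with
`ε ~ N(0, 2.5)` nmol/L and baselines `N(50, 10)`; nine 12-month studies
give n ≈ 100 delta pairs. The true slope 0.126 nmol/L per kJ/m² matches
the strength of the UVB–25(OH)D relationship in population-based cohorts;
2.5 nmol/L is the order of the standard error of a monthly cohort mean,
which at the simulator's CW scale yields the strong-correlation regime
(r² ≈ 0.6–0.8) characteristic of such cohorts. Note the March noise draw
enters every delta of its study, so pairs are weakly correlated within
study; the pooled-OLS 95% CI still covers the true slope at ≈ 0.93–0.94
over 200 replicates.

What passing tests show — and don't: the generator reproduces seasonal
structure, gap mechanics and the generative linkage, so green tests
demonstrate the *pipeline's* correctness (imputation invariance, exact CW
algebra, OLS equivalence, parameter recovery). They do not validate the
spectral model against real radiative transfer, real cloud climatology
(no autocorrelation, no spatial correlation between sites), air-pollution
effects, or the behaviour of real heterogeneous cohorts.

## Problem sizes

Default test/acceptance runs use deliberately small simulations — 3–6
years per site, a 7-site latitude transect (35–64° N) for the
vitamin-D-winter gradient, 200 replicates for CI coverage — sizes at which
every asserted property is stable and the whole suite runs in well under a
minute of simulation time.
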