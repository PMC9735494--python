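"""Linking monthly CW-D-UVB to published monthly 25(OH)D means.

Published studies report mean serum 25(OH)D by calendar month for cohorts
that differ in baseline status, assay and population, so absolute levels
are not comparable across studies.  The linkage therefore works on
*differences relative to March* (the typical seasonal trough of 25(OH)D):
for each study and month m, the pair

    (CW[m] - CW[March],  25OHD[m] - 25OHD[March])

is formed using the monthly CW-D-UVB profile of the study country's capital
city, and one ordinary least squares line is fitted per cohort class
(A: healthy/population-based, B: disease cohorts, C: laboratory/database
samples), pooling all studies of the class.  March itself is excluded from
the fit (its pair is identically (0, 0) by construction).

Input format: headered CSV ``study_id,cohort_class,city_rule,month,
mean_25ohd_nmol_l`` with 25(OH)D strictly in nmol/L.  ``city_rule`` is
either a capital name or ``average(city1, city2)`` for cohorts between two
capitals.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COHORT_CLASSES",
    "RegressionResult",
    "StudyLinkError",
    "load_studies",
    "resolve_city_cw",
    "deltas_vs_march",
    "build_delta_pairs",
    "fit_class_regression",
]

COHORT_CLASSES = ("A", "B", "C")
REFERENCE_MONTH = 3  # March
STUDY_COLUMNS = ["study_id", "cohort_class", "city_rule", "month", "mean_25ohd_nmol_l"]


class StudyLinkError(ValueError):
    """Raised for malformed study tables or degenerate fits."""


@dataclass(frozen=True)
class RegressionResult:
    """Pooled OLS fit of delta-25(OH)D on delta-CW-D-UVB.

    ``slope`` is in nmol/L per kJ/m^2 (multiply by 100 for the per-100-kJ/m^2
    convention); ``p_value`` is the two-sided t-test on the slope with n-2
    degrees of freedom, NaN for a saturated two-point fit.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    slope_se: float = float("nan")

    @property
    def slope_per_100(self) -> float:
        return 100.0 * self.slope

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a fit needs at least 2 points")
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def load_studies(path) -> pd.DataFrame:
    """Read and validate a study-level monthly 25(OH)D table."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise StudyLinkError(f"missing columns: {sorted(missing)}")
    df = df[STUDY_COLUMNS].copy()
    bad_class = set(df["cohort_class"]) - set(COHORT_CLASSES)
    if bad_class:
        raise StudyLinkError(f"unknown cohort classes: {sorted(bad_class)}")
    if not df["month"].between(1, 12).all():
        raise StudyLinkError("months must be in 1..12")
    if (df["mean_25ohd_nmol_l"] <= 0).any():
        raise StudyLinkError("25(OH)D means must be positive (nmol/L)")
    dup = df.duplicated(subset=["study_id", "month"])
    if dup.any():
        raise StudyLinkError("months must be unique within a study")
    return df


def resolve_city_cw(city_rule: str, cw_library) -> pd.Series:
    """Monthly CW profile for a city rule.

    A plain city name returns that city's 12 monthly means from
    ``cw_library`` (a mapping city -> Series indexed by month 1..12);
    ``average(city1, city2)`` returns the elementwise mean of the two.
    """
    rule = city_rule.strip()
    m = re.fullmatch(r"average\(\s*([^,)]+?)\s*,\s*([^,)]+?)\s*\)", rule, flags=re.IGNORECASE)
    names = [m.group(1), m.group(2)] if m else [rule]
    profiles = []
    for name in names:
        if name not in cw_library:
            raise StudyLinkError(f"unknown city {name!r} in rule {city_rule!r}")
        prof = pd.Series(cw_library[name])
        if list(prof.index) != list(range(1, 13)):
            raise StudyLinkError(f"CW profile for {name!r} must cover months 1..12")
        profiles.append(prof.astype(float))
    out = profiles[0] if len(profiles) == 1 else (profiles[0] + profiles[1]) / 2.0
    out.index.name = "month"
    return out


def deltas_vs_march(study: pd.DataFrame, cw_monthly: pd.Series) -> pd.DataFrame:
    """Per-month (delta_cw, delta_25ohd) pairs relative to March for one study.

    The study must report March (otherwise it is rejected with an explicit
    reason); March itself is excluded from the output since its pair is
    (0, 0) by construction.
    """
    months = study["month"].to_numpy()
    if REFERENCE_MONTH not in months:
        sid = study["study_id"].iat[0] if len(study) else "<empty>"
        raise StudyLinkError(f"study {sid!r} rejected: no March (reference month) record")
    x25 = study.set_index("month")["mean_25ohd_nmol_l"].astype(float)
    ref_cw = float(cw_monthly.loc[REFERENCE_MONTH])
    ref_25 = float(x25.loc[REFERENCE_MONTH])
    keep = x25.index[x25.index != REFERENCE_MONTH]
    out = pd.DataFrame({
        "study_id": study["study_id"].iat[0],
        "month": keep,
        "delta_cw": [float(cw_monthly.loc[m]) - ref_cw for m in keep],
        "delta_25ohd": [float(x25.loc[m]) - ref_25 for m in keep],
    })
    return out.reset_index(drop=True)


def build_delta_pairs(studies: pd.DataFrame, cw_library,
                      cohort_class: str | None = None) -> pd.DataFrame:
    """Pool delta pairs over all studies (optionally of one cohort class)."""
    df = studies
    if cohort_class is not None:
        if cohort_class not in COHORT_CLASSES:
            raise StudyLinkError(f"unknown cohort class {cohort_class!r}")
        df = df[df["cohort_class"] == cohort_class]
    frames = []
    for sid, group in df.groupby("study_id", sort=False):
        cw = resolve_city_cw(group["city_rule"].iat[0], cw_library)
        pairs = deltas_vs_march(group, cw)
        pairs.insert(1, "cohort_class", group["cohort_class"].iat[0])
        frames.append(pairs)
    if not frames:
        return pd.DataFrame(columns=["study_id", "cohort_class", "month", "delta_cw", "delta_25ohd"])
    return pd.concat(frames, ignore_index=True)


def fit_class_regression(pairs: pd.DataFrame, weights=None) -> RegressionResult:
    """Pooled OLS of delta_25ohd on delta_cw, in closed form.

    Normal-equation slope/intercept, centred r-squared, and a two-sided
    t-test p-value on the slope (n-2 df).  ``weights`` (e.g. study sample
    sizes) switches to weighted least squares; pooling is unweighted by
    default.  A constant predictor is a degenerate design and raises.
    """
    x = pairs["delta_cw"].to_numpy(dtype=float)
    y = pairs["delta_25ohd"].to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise StudyLinkError("need at least 2 delta pairs to fit")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w <= 0):
        raise StudyLinkError("weights must be positive and match the pairs")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    syy = (w * (y - ybar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    if sxx <= 0:
        raise StudyLinkError("degenerate fit: delta_cw is constant")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sse = (w * resid ** 2).sum()
    r_squared = 1.0 - sse / syy if syy > 0 else float("nan")
    if n > 2:
        sigma2 = sse / (n - 2)
        slope_se = float(np.sqrt(sigma2 / sxx))
        if slope_se > 0:
            t = slope / slope_se
            p_value = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        else:
            p_value = 0.0
    else:
        slope_se, p_value = float("nan"), float("nan")
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r_squared=float(np.clip(r_squared, 0.0, 1.0)) if np.isfinite(r_squared) else r_squared,
                            p_value=p_value, n_points=n, slope_se=slope_se)
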