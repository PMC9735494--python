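import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import duvb
from duvb import GeoLocation, metrics, series_io as sio


def constant_climatology(value: float, name: str = "const") -> metrics.Climatology:
    idx = pd.MultiIndex.from_tuples(
        [(m, d) for m, days in enumerate(metrics.DAYS_IN_MONTH, start=1)
         for d in range(1, days + 1)], names=["month", "day"])
    entries = pd.DataFrame({"mean_dose": value, "sd_dose": 0.0, "n_years": 3}, index=idx)
    return metrics.Climatology(location_name=name, entries=entries)


def sinusoid_climatology(seed: int = 0) -> metrics.Climatology:
    idx = pd.MultiIndex.from_tuples(
        [(m, d) for m, days in enumerate(metrics.DAYS_IN_MONTH, start=1)
         for d in range(1, days + 1)], names=["month", "day"])
    doy = np.arange(365, dtype=float)
    rng = np.random.default_rng(seed)
    means = 2.0 + 1.8 * np.sin(2 * np.pi * (doy - 80) / 365.0) + rng.normal(0, 0.05, 365)
    means = np.clip(means, 0.0, None)
    entries = pd.DataFrame({"mean_dose": means, "sd_dose": 0.1, "n_years": 5}, index=idx)
    return metrics.Climatology(location_name="sin", entries=entries)


class TestBuildClimatology:
    def test_single_year_reproduces_values_with_zero_sd(self):
        dates = pd.date_range("2019-01-01", "2019-12-31", freq="D")
        doses = np.linspace(0.5, 4.0, len(dates))
        series = sio.series_from_records(GeoLocation("x", 50, 0), dates, doses)
        with pytest.warns(UserWarning, match="single year"):
            clim = metrics.build_climatology(series)
        assert np.array_equal(clim.day_means, doses)
        assert np.all(clim.entries["sd_dose"] == 0.0)
        assert np.all(clim.entries["n_years"] == 1)

    def test_two_year_day_mean_is_midpoint(self):
        dates = list(pd.date_range("2019-01-01", "2019-12-31", freq="D"))
        dates += list(pd.date_range("2020-01-01", "2020-12-31", freq="D"))
        doses = np.concatenate([np.full(365, 2.0), np.full(366, 4.0)])
        series = sio.series_from_records(GeoLocation("x", 50, 0), dates, doses)
        clim = metrics.build_climatology(series)
        assert np.allclose(clim.day_means, 3.0)

    def test_matches_brute_force_groupby(self, dublin_sim):
        clim = metrics.build_climatology(dublin_sim)
        df = dublin_sim.frame.dropna(subset=["dose"])
        df = df[~((df.index.month == 2) & (df.index.day == 29))]
        for month, day in [(1, 15), (4, 1), (7, 31), (12, 25)]:
            sel = df[(df.index.month == month) & (df.index.day == day)]["dose"]
            row = clim.entries.loc[(month, day)]
            assert row["mean_dose"] == pytest.approx(sel.mean(), rel=1e-12)
            assert row["sd_dose"] == pytest.approx(sel.std(ddof=1), rel=1e-12)
            assert row["n_years"] == len(sel)

    def test_leap_day_omitted(self, dublin_sim):
        clim = metrics.build_climatology(dublin_sim)
        assert len(clim.entries) == 365
        assert (2, 29) not in clim.entries.index

    def test_empty_series_rejected(self):
        dates = pd.date_range("2019-01-01", periods=3)
        series = sio.series_from_records(GeoLocation("x", 50, 0), dates,
                                         [np.nan] * 3, ["missing"] * 3)
        with pytest.raises(ValueError):
            metrics.build_climatology(series)


class TestSummaries:
    def test_constant_climatology_constant_months(self):
        clim = constant_climatology(2.5)
        mon = metrics.monthly_stats(clim)
        assert np.allclose(mon.means, 2.5)
        assert np.allclose(mon.table["sd"], 0.0)
        ann = metrics.annual_stats(clim)
        assert ann.mean == pytest.approx(2.5)
        assert ann.cumulative == pytest.approx(365 * 2.5)

    def test_monthly_stats_match_brute_force(self):
        clim = sinusoid_climatology()
        mon = metrics.monthly_stats(clim)
        months = clim.entries.index.get_level_values("month")
        for m in range(1, 13):
            vals = clim.entries.loc[months == m, "mean_dose"]
            assert mon.table.loc[m, "mean"] == pytest.approx(vals.mean(), rel=1e-12)
            assert mon.table.loc[m, "sd"] == pytest.approx(vals.std(ddof=1), rel=1e-12)

    def test_annual_consistency_identities(self):
        clim = sinusoid_climatology()
        ann = metrics.annual_stats(clim)
        mon = metrics.monthly_stats(clim)
        # conservation and day-weighted decomposition, both exact
        assert ann.cumulative == pytest.approx(365.0 * ann.mean, rel=1e-12)
        assert metrics.annual_mean_from_monthly(mon) == pytest.approx(ann.mean, rel=1e-12)

    def test_annual_mean_from_equal_months_is_that_value(self):
        assert metrics.annual_mean_from_monthly([3.3] * 12) == pytest.approx(3.3)

    def test_fold_ratio_constant_series_is_one(self):
        assert metrics.peak_trough_ratio([2.0] * 12) == pytest.approx(1.0)

    def test_fold_ratio_zero_trough_is_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert metrics.peak_trough_ratio([0.0] + [1.0] * 11) == float("inf")


class TestVitaminDWinter:
    def test_all_above_threshold_no_winter(self):
        assert metrics.vitamin_d_winter(constant_climatology(2.0)).duration_days == 0

    def test_all_below_threshold_year_round_winter(self):
        winter = metrics.vitamin_d_winter(constant_climatology(0.5))
        assert winter.duration_days == 365
        assert len(winter.below_days) == 365

    def test_matches_brute_force_threshold_scan(self):
        clim = sinusoid_climatology()
        winter = metrics.vitamin_d_winter(clim, threshold=1.0)
        assert winter.duration_days == int((clim.day_means < 1.0).sum())

    def test_boundary_day_counts_as_synthesis_day(self):
        clim = constant_climatology(1.0)
        assert metrics.vitamin_d_winter(clim, threshold=1.0).duration_days == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 5.0), min_size=2, max_size=6).map(sorted))
    def test_duration_monotone_non_increasing_in_threshold(self, thresholds):
        clim = sinusoid_climatology(seed=1)
        durations = [metrics.vitamin_d_winter(clim, threshold=t).duration_days
                     for t in thresholds]
        assert all(a <= b for a, b in zip(durations, durations[1:]))


class TestReferenceTable:
    def test_table_has_46_capitals(self):
        table = metrics.load_table1()
        assert len(table) == 46
        assert "Nicosia" in table.index and "Reykjavik" in table.index

    def test_athens_monthly_extremes(self):
        mon = metrics.table1_monthly_stats("Athens")
        assert mon.table.loc[7, "mean"] == pytest.approx(10.02)
        assert mon.table.loc[12, "mean"] == pytest.approx(0.77)

    @pytest.mark.parametrize("city,annual", [
        ("Reykjavik", 1.16), ("Kiev", 2.72), ("Nicosia", 5.57),
    ])
    def test_day_weighted_annual_matches_printed_value(self, city, annual):
        mon = metrics.table1_monthly_stats(city)
        assert metrics.annual_mean_from_monthly(mon) == pytest.approx(annual, abs=0.01)

    def test_east_west_gradient_at_50N(self):
        # same latitude band: Kiev > Prague > Brussels in annual dose
        annuals = {c: metrics.table1_annual(c)[0] for c in ("Kiev", "Prague", "Brussels")}
        assert annuals["Kiev"] > annuals["Prague"] > annuals["Brussels"]
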