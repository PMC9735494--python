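import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api
from scipy import stats

from duvb import study_link as sl
from duvb import synthetic_data as syn


def study_frame(study_id, months, values, cohort_class="A", city="Athens"):
    return pd.DataFrame({
        "study_id": study_id, "cohort_class": cohort_class, "city_rule": city,
        "month": months, "mean_25ohd_nmol_l": values,
    })


def cw_profile(values):
    return pd.Series(values, index=pd.Index(range(1, 13), name="month"), dtype=float)


LINEAR_CW = cw_profile(np.arange(10.0, 130.0, 10.0))  # month m -> 10 m


class TestDeltas:
    def test_march_only_study_yields_empty_set(self):
        study = study_frame("s1", [3], [50.0])
        pairs = sl.deltas_vs_march(study, LINEAR_CW)
        assert len(pairs) == 0

    def test_constant_25ohd_gives_zero_deltas(self):
        study = study_frame("s1", [1, 3, 6, 9], [55.0] * 4)
        pairs = sl.deltas_vs_march(study, LINEAR_CW)
        assert np.allclose(pairs["delta_25ohd"], 0.0)
        assert 3 not in set(pairs["month"])

    def test_hand_built_four_month_table(self):
        # by hand: cw deltas vs March are -20, +30, +50; 25OHD deltas -5, +8, +12
        study = study_frame("s1", [1, 3, 6, 8], [45.0, 50.0, 58.0, 62.0])
        pairs = sl.deltas_vs_march(study, LINEAR_CW).set_index("month")
        assert pairs.loc[1, "delta_cw"] == pytest.approx(-20.0)
        assert pairs.loc[6, "delta_cw"] == pytest.approx(30.0)
        assert pairs.loc[8, "delta_cw"] == pytest.approx(50.0)
        assert pairs.loc[1, "delta_25ohd"] == pytest.approx(-5.0)
        assert pairs.loc[6, "delta_25ohd"] == pytest.approx(8.0)
        assert pairs.loc[8, "delta_25ohd"] == pytest.approx(12.0)

    def test_missing_march_rejected_with_reason(self):
        study = study_frame("s1", [1, 2, 6], [45.0, 47.0, 58.0])
        with pytest.raises(sl.StudyLinkError, match="March"):
            sl.deltas_vs_march(study, LINEAR_CW)


class TestCityRule:
    def test_single_city_is_identity(self):
        lib = {"Dublin": LINEAR_CW}
        assert sl.resolve_city_cw("Dublin", lib).equals(LINEAR_CW)

    def test_average_of_identical_profiles_is_unchanged(self):
        lib = {"Oslo": LINEAR_CW, "Reykjavik": LINEAR_CW}
        out = sl.resolve_city_cw("average(Oslo, Reykjavik)", lib)
        assert np.allclose(out, LINEAR_CW)

    def test_average_is_elementwise_mean(self):
        lib = {"a": cw_profile([2.0] * 12), "b": cw_profile([4.0] * 12)}
        assert np.allclose(sl.resolve_city_cw("average(a, b)", lib), 3.0)

    def test_unknown_city_rejected(self):
        with pytest.raises(sl.StudyLinkError, match="unknown city"):
            sl.resolve_city_cw("Atlantis", {"Dublin": LINEAR_CW})


class TestRegression:
    def test_exact_line_recovered_perfectly(self):
        x = np.array([-30.0, -10.0, 5.0, 20.0, 60.0])
        pairs = pd.DataFrame({"delta_cw": x, "delta_25ohd": 0.1 * x})
        fit = sl.fit_class_regression(pairs)
        assert fit.slope == pytest.approx(0.1, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_saturated_fit(self):
        pairs = pd.DataFrame({"delta_cw": [0.0, 10.0], "delta_25ohd": [1.0, 3.0]})
        fit = sl.fit_class_regression(pairs)
        assert fit.slope == pytest.approx(0.2)
        assert fit.r_squared == pytest.approx(1.0)
        assert np.isnan(fit.p_value)

    def test_constant_predictor_degenerate(self):
        pairs = pd.DataFrame({"delta_cw": [5.0, 5.0, 5.0], "delta_25ohd": [1.0, 2.0, 3.0]})
        with pytest.raises(sl.StudyLinkError, match="degenerate"):
            sl.fit_class_regression(pairs)

    def test_agrees_with_statsmodels_on_random_datasets(self):
        # independent oracle: statsmodels OLS, 100 random small datasets
        rng = np.random.default_rng(101)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            x = rng.normal(0, rng.uniform(0.5, 50), n)
            y = rng.uniform(-0.5, 0.5) * x + rng.normal(0, rng.uniform(0.1, 20), n)
            pairs = pd.DataFrame({"delta_cw": x, "delta_25ohd": y})
            fit = sl.fit_class_regression(pairs)
            oracle = sm_api.OLS(y, sm_api.add_constant(x)).fit()
            assert fit.slope == pytest.approx(oracle.params[1], rel=1e-10)
            assert fit.intercept == pytest.approx(oracle.params[0], rel=1e-10, abs=1e-10)
            assert fit.r_squared == pytest.approx(oracle.rsquared, rel=1e-10)
            assert fit.p_value == pytest.approx(oracle.pvalues[1], rel=1e-10, abs=1e-300)

    def test_slope_invariant_to_axis_shifts(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 20, 30)
        y = 0.126 * x + rng.normal(0, 2, 30)
        base = sl.fit_class_regression(pd.DataFrame({"delta_cw": x, "delta_25ohd": y}))
        shifted = sl.fit_class_regression(pd.DataFrame({"delta_cw": x + 500.0,
                                                        "delta_25ohd": y - 30.0}))
        assert shifted.slope == pytest.approx(base.slope, rel=1e-09)

    def test_parameter_recovery_within_two_se(self):
        # generative model y = 0.126 x + N(0, sigma) at n = 96
        rng = np.random.default_rng(17)
        n, sigma, true_slope = 96, 3.0, 0.126
        x = rng.normal(0, 30, n)
        design_r2 = (true_slope ** 2 * x.var()) / (true_slope ** 2 * x.var() + sigma ** 2)
        y = true_slope * x + rng.normal(0, sigma, n)
        fit = sl.fit_class_regression(pd.DataFrame({"delta_cw": x, "delta_25ohd": y}))
        assert abs(fit.slope - true_slope) <= 2.0 * fit.slope_se
        assert fit.r_squared == pytest.approx(design_r2, abs=0.1)

    def test_sample_size_weighting_reweights_the_fit(self):
        x = np.array([-10.0, 0.0, 10.0, 20.0])
        y = np.array([-1.0, 0.0, 1.0, 10.0])
        pairs = pd.DataFrame({"delta_cw": x, "delta_25ohd": y})
        unweighted = sl.fit_class_regression(pairs)
        downweight_outlier = sl.fit_class_regression(pairs, weights=[1, 1, 1, 1e-09])
        assert downweight_outlier.slope == pytest.approx(0.1, rel=1e-05)
        assert unweighted.slope > downweight_outlier.slope


class TestPooling:
    def test_pool_filters_by_class_and_pools_across_studies(self, trio_cw_library):
        cities = list(trio_cw_library)
        studies = pd.concat([
            study_frame("s1", [3, 6, 9], [50.0, 60.0, 55.0], cohort_class="A", city=cities[0]),
            study_frame("s2", [3, 7], [40.0, 52.0], cohort_class="A", city=cities[1]),
            study_frame("s3", [3, 6], [45.0, 50.0], cohort_class="B", city=cities[0]),
        ])
        pairs_a = sl.build_delta_pairs(studies, trio_cw_library, cohort_class="A")
        assert len(pairs_a) == 3  # (6, 9) from s1 and (7,) from s2; March excluded
        assert set(pairs_a["study_id"]) == {"s1", "s2"}
        pairs_all = sl.build_delta_pairs(studies, trio_cw_library)
        assert len(pairs_all) == 4

    def test_load_studies_validates_schema(self, tmp_path):
        path = tmp_path / "studies.csv"
        study_frame("s1", [3, 6], [50.0, 60.0]).to_csv(path, index=False)
        loaded = sl.load_studies(path)
        assert list(loaded.columns) == sl.STUDY_COLUMNS
        bad = study_frame("s1", [3, 6], [50.0, 60.0], cohort_class="Z")
        bad.to_csv(path, index=False)
        with pytest.raises(sl.StudyLinkError, match="cohort class"):
            sl.load_studies(path)

    def test_synthetic_pipeline_ci_coverage(self, trio_cw_library):
        # 95% CI for the slope covers the generative truth at ~nominal rate
        hits, reps = 0, 200
        for s in range(reps):
            cfg = syn.ScenarioConfig(seed=5000 + s)
            studies, truth = syn.generate_study_tables(cfg, trio_cw_library)
            fit = sl.fit_class_regression(
                sl.build_delta_pairs(studies, trio_cw_library, cohort_class="A"))
            tcrit = stats.t.ppf(0.975, fit.n_points - 2)
            if abs(fit.slope - truth["true_slope"]) <= tcrit * fit.slope_se:
                hits += 1
        assert 0.90 <= hits / reps <= 0.99
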