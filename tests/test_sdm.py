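import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lagoshift.env_stack import EnvStack, GridSpec
from lagoshift.sdm import (
    TooFewRecordsError,
    choose_replication,
    expand_features,
    fit_pb_model,
    fit_replicates,
    pb_objective,
    predict_map,
    predict_suitability,
)


def sample_rows(rng, n, signal=0.0):
    """Rows with two variables; presences shifted along x when signal > 0."""
    return pd.DataFrame({
        "x": rng.normal(signal, 1.0, n),
        "y": rng.normal(0.0, 1.0, n),
        "period": "post1950",
    })


class TestFeatureExpansion:
    def test_counts_p3_and_p1(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        exp, X = expand_features(t, ["a", "b", "c"])
        assert X.shape[1] == 9  # 3 linear + 3 quadratic + C(3,2) products
        exp1, X1 = expand_features(t, ["a"])
        assert X1.shape[1] == 2

    def test_ordering_linear_quadratic_products(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        exp, _ = expand_features(t, ["a", "b", "c"])
        assert exp.names == ["a", "b", "c", "a^2", "b^2", "c^2", "a*b", "a*c", "b*c"]

    def test_training_features_scaled_to_unit_interval(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        _, X = expand_features(t, ["a", "b"])
        assert X.min() == pytest.approx(0.0) and X.max() == pytest.approx(1.0)

    def test_constant_variable_excluded_with_warning(self):
        t = pd.DataFrame({"a": np.arange(10.0), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            exp, X = expand_features(t, ["a", "c"])
        assert exp.base_variables == ["a"] and X.shape[1] == 2


class TestChooseReplication:
    @pytest.mark.parametrize("n,scheme", [(29, "bootstrap10"), (30, "cv4fold"), (8, "bootstrap10")])
    def test_record_count_rule(self, n, scheme):
        assert choose_replication(n) == scheme

    def test_below_minimum_flags_unmodellable_by_data(self):
        with pytest.raises(TooFewRecordsError):
            choose_replication(5, minimum_records=8)


class TestFitPBModel:
    def test_no_signal_prediction_near_uniform(self):
        rng = np.random.default_rng(0)
        pres, bg = sample_rows(rng, 100), sample_rows(rng, 400)
        m = fit_pb_model(pres, bg, ["x", "y"])
        raw = predict_suitability(fit_pb_model(pres, bg, ["x", "y"], output_transform="raw"), bg, clamp=False)
        # raw density within a factor ~2 of uniform everywhere (pure noise fit)
        assert raw.max() / raw.min() < 4.0
        # and discrimination is absent
        from lagoshift.evaluation import rank_auc
        sp = predict_suitability(m, pres)
        sb = predict_suitability(m, bg)
        assert abs(rank_auc(sp, sb) - 0.5) < 0.1

    def test_signal_gives_positive_linear_coefficient(self):
        rng = np.random.default_rng(1)
        pres, bg = sample_rows(rng, 150, signal=1.5), sample_rows(rng, 600)
        m = fit_pb_model(pres, bg, ["x", "y"])
        assert m.coefficients[m.expansion.names.index("x")] > 0

    def test_huge_regularization_zeroes_everything(self):
        rng = np.random.default_rng(2)
        pres, bg = sample_rows(rng, 50, signal=1.0), sample_rows(rng, 200)
        m = fit_pb_model(pres, bg, ["x", "y"], reg_multiplier=1e6)
        np.testing.assert_allclose(m.coefficients, 0.0)

    def test_raw_output_sums_to_one_over_training_background(self):
        rng = np.random.default_rng(3)
        pres, bg = sample_rows(rng, 80, signal=1.0), sample_rows(rng, 300)
        m = fit_pb_model(pres, bg, ["x", "y"], output_transform="raw")
        raw = predict_suitability(m, bg, clamp=False)
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_generic_optimizer_on_small_instance(self):
        """Penalised fit vs direct Powell minimisation of the same objective."""
        rng = np.random.default_rng(4)
        pres, bg = sample_rows(rng, 40, signal=1.0), sample_rows(rng, 120)
        m = fit_pb_model(pres, bg, ["x"])  # 2 features: linear + quadratic
        Xp = m.expansion.design_matrix(pres)
        Xb = m.expansion.design_matrix(bg)
        lam = m.regularization
        res = minimize(pb_objective, np.zeros(2), args=(Xp, Xb, lam),
                       method="Powell", options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10000})
        assert np.abs(m.coefficients - res.x).max() < 1e-3


class TestReplicates:
    def test_cv4fold_disjoint_covering_folds(self):
        rng = np.random.default_rng(5)
        pres, bg = sample_rows(rng, 40, signal=1.0), sample_rows(rng, 150)
        reps = fit_replicates("cv4fold", pres, bg, ["x", "y"], seed=0)
        all_test = np.concatenate(reps.test_indices)
        assert len(reps.models) == 4
        assert sorted(all_test) == list(range(40))
        assert all(len(t) == 10 for t in reps.test_indices)

    def test_same_seed_same_folds(self):
        rng = np.random.default_rng(6)
        pres, bg = sample_rows(rng, 32, signal=1.0), sample_rows(rng, 100)
        r1 = fit_replicates("cv4fold", pres, bg, ["x", "y"], seed=7)
        r2 = fit_replicates("cv4fold", pres, bg, ["x", "y"], seed=7)
        for a, b in zip(r1.test_indices, r2.test_indices):
            np.testing.assert_array_equal(a, b)

    def test_bootstrap10_has_ten_models_with_oob_tests(self):
        rng = np.random.default_rng(7)
        pres, bg = sample_rows(rng, 20, signal=1.0), sample_rows(rng, 80)
        reps = fit_replicates("bootstrap10", pres, bg, ["x", "y"], seed=1)
        assert len(reps.models) == 10
        for t in reps.test_indices:  # OOB sets are strict subsets
            assert 0 < len(t) < 20


class TestPredictMap:
    def make_stack(self):
        grid = GridSpec(n_rows=8, n_cols=8, cell_size=0.5, x_origin=0.0, y_origin=55.0)
        rng = np.random.default_rng(8)
        return EnvStack("p", grid, {
            "x": rng.normal(size=(8, 8)),
            "y": rng.normal(size=(8, 8)),
        })

    def test_training_cells_reproduce_row_predictions(self):
        stack = self.make_stack()
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 8, 60)
        cols = rng.integers(0, 8, 60)
        lon, lat = stack.grid.cell_center(rows, cols)
        pres = pd.DataFrame({"x": stack.layers["x"][rows[:20], cols[:20]],
                             "y": stack.layers["y"][rows[:20], cols[:20]]})
        bg = pd.DataFrame({"x": stack.layers["x"][rows, cols],
                           "y": stack.layers["y"][rows, cols]})
        m = fit_pb_model(pres, bg, ["x", "y"])
        mp = predict_map(m, stack)
        got = mp[rows[:20], cols[:20]]
        np.testing.assert_allclose(got, predict_suitability(m, pres), atol=1e-12)

    def test_nodata_propagates_and_missing_variable_errors(self):
        stack = self.make_stack()
        stack.layers["x"][0, 0] = np.nan
        rng = np.random.default_rng(10)
        pres, bg = sample_rows(rng, 30, 1.0), sample_rows(rng, 100)
        m = fit_pb_model(pres, bg, ["x", "y"])
        mp = predict_map(m, stack)
        assert np.isnan(mp[0, 0])
        del stack.layers["y"]
        with pytest.raises(KeyError):
            predict_map(m, stack)
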