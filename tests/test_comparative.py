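import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from lagoshift.comparative import (
    aicc,
    akaike_weights,
    bm_covariance,
    dredge,
    fit_gls_ar1,
    gls_trend,
    graft_tips,
    lambda_transform,
    model_average,
    pgls_fit,
    rank_correlation,
    refit_without_outliers,
    residual_normality,
    studentized_outliers,
    vif_screen,
)
from lagoshift.synth import gen_comparative


def read_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestVIF:
    def test_orthogonal_traits_all_retained_unit_vif(self):
        rng = np.random.default_rng(0)
        # orthogonalise against the intercept too (columns mean-centred)
        q, _ = np.linalg.qr(np.column_stack([np.ones(40), rng.normal(size=(40, 3))]))
        traits = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        kept, vifs = vif_screen(traits)
        assert kept == ["a", "b", "c"]
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)

    def test_duplicated_column_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        traits = pd.DataFrame({"a": a, "a2": a, "b": rng.normal(size=30)})
        kept, _ = vif_screen(traits)
        assert len(kept) == 2 and "b" in kept

    def test_vif_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        traits = pd.DataFrame({
            "a": x,
            "b": 0.8 * x + 0.6 * rng.normal(size=50),
            "c": rng.normal(size=50),
        })
        _, vifs = vif_screen(traits, vif_cut=1e9)  # no removal, just values
        for j, col in enumerate(traits.columns):
            others = traits.drop(columns=col)
            X = np.column_stack([np.ones(50), others.to_numpy()])
            beta, *_ = np.linalg.lstsq(X, traits[col], rcond=None)
            resid = traits[col] - X @ beta
            r2 = 1 - (resid @ resid) / ((traits[col] - traits[col].mean()) ** 2).sum()
            assert vifs[col] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestGraft:
    # ((A:6,B:6):4,(C:9,D:9):1):0 — depth 10, clade (A,B) stem length 4
    nwk = "((A:6,B:6):4,(C:9,D:9):1);"

    def test_pendant_length_restores_ultrametricity(self):
        tree = graft_tips(read_tree(self.nwk), {"X": ["A", "B"]})
        tree.calc_node_root_distances()
        depths = {lf.taxon.label: lf.root_distance for lf in tree.leaf_node_iter()}
        x_leaf = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == "X")
        assert x_leaf.edge.length == pytest.approx(8.0)  # attach at stem midpoint depth 2
        assert all(d == pytest.approx(10.0) for d in depths.values())

    def test_existing_pairwise_distances_unchanged(self):
        before = read_tree(self.nwk)
        V0, labels = bm_covariance(before)
        after = graft_tips(before, {"X": ["C", "D"]})
        V1, labels1 = bm_covariance(after, tip_order=labels)
        np.testing.assert_allclose(V1, V0, atol=1e-12)

    def test_non_monophyletic_placement_rejected(self):
        with pytest.raises(ValueError, match="monophyletic"):
            graft_tips(read_tree(self.nwk), {"X": ["A", "C"]})

    def test_tip_labels_unique(self):
        tree = graft_tips(read_tree(self.nwk), {"X": ["A", "B"]})
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert len(labels) == len(set(labels)) == 5


class TestBMCovariance:
    def test_three_taxon_path_enumeration(self):
        V, labels = bm_covariance(read_tree("((A:1,B:1):1,C:2);"),
                                  tip_order=["A", "B", "C"])
        np.testing.assert_allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_diagonal(self):
        V, _ = bm_covariance(read_tree("(A:3,B:3,C:3,D:3);"))
        np.testing.assert_allclose(V, 3 * np.eye(4))

    def test_lambda_transform_scales_off_diagonal_only(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(lambda_transform(V, 0.0), 2 * np.eye(2))
        np.testing.assert_allclose(lambda_transform(V, 0.5), [[2, 0.5], [0.5, 2]])


class TestPGLS:
    def test_star_tree_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(3)
        n = 40
        V = np.eye(n) * 2.5
        x = rng.normal(size=n)
        y = 1.0 + 0.7 * x + rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        fit = pgls_fit(y, X, V)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_lambda_zero_equals_diagonal_weighted_regression(self):
        sim = gen_comparative(n_tips=40, lambda_true=1.0, seed=4)
        y = sim["response"].to_numpy()
        X = pd.DataFrame({"intercept": 1.0, "trait1": sim["traits"]["trait1"]})
        fit0 = pgls_fit(y, X, sim["V"], fixed_lambda=0.0)
        W = np.diag(1 / np.diag(sim["V"]))
        Xn = X.to_numpy()
        beta_w = np.linalg.solve(Xn.T @ W @ Xn, Xn.T @ W @ y)
        np.testing.assert_allclose(fit0.beta, beta_w, atol=1e-8)

    def test_singular_design_names_terms(self):
        sim = gen_comparative(n_tips=30, seed=5)
        t = sim["traits"]["trait1"]
        X = pd.DataFrame({"intercept": 1.0, "a": t, "b": 2 * t})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            pgls_fit(sim["response"].to_numpy(), X, sim["V"])

    def test_noiseless_brownian_recovers_beta_exactly(self):
        sim = gen_comparative(n_tips=60, lambda_true=1.0,
                              beta_true=(1.0, 0.5), noise_sd=1e-6, seed=6)
        X = pd.DataFrame({"intercept": 1.0, "trait1": sim["traits"]["trait1"]})
        fit = pgls_fit(sim["response"].to_numpy(), X, sim["V"])
        np.testing.assert_allclose(fit.beta, [1.0, 0.5], atol=1e-4)


class TestOutliersAndNormality:
    def make_fit(self, inject=None, seed=7):
        sim = gen_comparative(n_tips=50, lambda_true=0.5, noise_sd=1.0, seed=seed)
        y = sim["response"].to_numpy().copy()
        if inject is not None:
            y[inject] += 10.0
        X = pd.DataFrame({"intercept": 1.0, "trait1": sim["traits"]["trait1"]})
        return pgls_fit(y, X, sim["V"])

    def test_gross_outlier_flagged_and_refit_removes_it(self):
        fit = self.make_fit(inject=13)
        flagged = studentized_outliers(fit)
        assert 13 in flagged
        refit, removed = refit_without_outliers(fit)
        assert refit.n < fit.n and 13 in removed

    def test_clean_data_rarely_flags(self):
        n_flagged = sum(len(studentized_outliers(self.make_fit(seed=s))) > 0
                        for s in range(20))
        assert n_flagged <= 3

    def test_flagging_invariant_to_row_order(self):
        sim = gen_comparative(n_tips=40, seed=8)
        y = sim["response"].to_numpy().copy()
        y[5] += 10
        X = np.column_stack([np.ones(40), sim["traits"]["trait1"]])
        perm = np.random.default_rng(0).permutation(40)
        f1 = pgls_fit(y, X, sim["V"])
        f2 = pgls_fit(y[perm], X[perm], sim["V"][np.ix_(perm, perm)])
        s1 = set(studentized_outliers(f1))
        s2 = {int(perm[i]) for i in studentized_outliers(f2)}
        assert s1 == s2 == {5}

    def test_normality_pvalue_and_degenerate_error(self):
        fit = self.make_fit(seed=9)
        p = residual_normality(fit)
        assert 0 <= p <= 1
        flat = self.make_fit(seed=9)
        flat.y = flat.X @ np.array([1.0, 2.0])  # residuals exactly zero
        with pytest.raises(ValueError):
            residual_normality(flat)


class TestAICcDredge:
    def test_aicc_minus_aic_identity(self):
        # k=2, n=10: 2k(k+1)/(n-k-1) = 12/7
        assert aicc(0.0, 2, 10) - (2 * 2) == pytest.approx(12 / 7)

    def test_akaike_weights_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-9)
        assert w.sum() == pytest.approx(1.0)

    def test_dredge_enumerates_all_subsets_and_matches_brute_force(self):
        sim = gen_comparative(n_tips=40, beta_true=(0.0, 0.8, 0.0, 0.3),
                              n_traits=3, seed=10)
        y = sim["response"].to_numpy()
        X = pd.DataFrame({"intercept": 1.0, **{c: sim["traits"][c] for c in sim["traits"]}})
        table = dredge(y, X, sim["V"])
        assert len(table) == 8
        # exhaustive oracle: refit every subset independently and compare AICc
        oracle = {}
        for r in range(4):
            for subset in itertools.combinations(["trait1", "trait2", "trait3"], r):
                cols = ["intercept", *subset]
                oracle["+".join(subset) if subset else "(intercept)"] = \
                    pgls_fit(y, X[cols], sim["V"]).aicc
        for _, row in table.iterrows():
            assert row["aicc"] == pytest.approx(oracle[row["model"]], abs=1e-8)
        assert table["aicc"].is_monotonic_increasing

    def test_weights_invariant_to_loglik_shift(self):
        a = np.array([10.0, 12.0, 15.0])
        np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 100), atol=1e-12)

    def test_model_average_zero_substitution(self):
        table = pd.DataFrame({
            "model": ["x", "(intercept)"],
            "has_x": [True, False],
            "beta_intercept": [1.0, 2.0],
            "beta_x": [3.0, np.nan],
            "aicc": [0.0, 0.0],
        })
        table["weight"] = akaike_weights(table["aicc"])
        avg = model_average(table)
        assert avg.loc["x", "estimate"] == pytest.approx(1.5)   # (3 + 0)/2
        assert avg.loc["x", "importance"] == pytest.approx(0.5)
        cond = model_average(table, conditional=True)
        assert cond.loc["x", "estimate"] == pytest.approx(3.0)

    def test_too_many_terms_refused(self):
        X = pd.DataFrame(np.ones((30, 22)), columns=["intercept"] + [f"t{i}" for i in range(21)])
        with pytest.raises(ValueError, match="refus"):
            dredge(np.ones(30), X, np.eye(30))


class TestGLSTrend:
    def make_panel(self, phi=0.0, trend_by_group=(0.5, 0.5, 0.5), seed=0, n_per_group=8, n_periods=4):
        rng = np.random.default_rng(seed)
        rows = []
        for g, slope in zip(["pikas", "rabbits", "hares"], trend_by_group):
            for s in range(n_per_group):
                e = rng.normal(size=n_periods)
                for t in range(1, n_periods):
                    e[t] = phi * e[t - 1] + np.sqrt(1 - phi**2) * e[t]
                for t in range(n_periods):
                    rows.append({"species": f"{g}{s}", "group": g,
                                 "period_index": t, "y": slope * t + e[t]})
        return pd.DataFrame(rows)

    def test_phi_zero_matches_ordinary_least_squares(self):
        df = self.make_panel(phi=0.0, seed=1)
        fit = gls_trend(df, "y")
        groups = sorted(df["group"].unique())
        t = df.sort_values(["species", "period_index"])["period_index"].to_numpy(float)
        dfs = df.sort_values(["species", "period_index"])
        cols = [np.ones(len(dfs)), t]
        for g in groups[1:]:
            ind = (dfs["group"] == g).to_numpy(float)
            cols += [ind, ind * t]
        X = np.column_stack(cols)
        beta_ols, *_ = np.linalg.lstsq(X, dfs["y"].to_numpy(), rcond=None)
        assert abs(fit.phi) < 0.25
        np.testing.assert_allclose(fit.beta, beta_ols, atol=0.15)

    def test_group_with_larger_trend_detected(self):
        df = self.make_panel(phi=0.3, trend_by_group=(0.0, 0.0, 2.0), seed=2)
        fit = gls_trend(df, "y")
        assert fit.f_tests.loc["group:period", "p"] < 0.01

    def test_single_period_refused(self):
        df = self.make_panel(n_periods=1)
        with pytest.raises(ValueError, match="2 periods"):
            gls_trend(df, "y")

    def test_ar1_phi_recovered_on_long_series(self):
        rng = np.random.default_rng(3)
        n = 300
        e = np.empty(n)
        e[0] = rng.normal()
        for t in range(1, n):
            e[t] = 0.6 * e[t - 1] + np.sqrt(1 - 0.36) * rng.normal()
        X = np.ones((n, 1))
        fit = fit_gls_ar1(e, X, np.zeros(n), ["intercept"])
        assert fit.phi == pytest.approx(0.6, abs=0.12)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert rank_correlation(x, x)[0] == pytest.approx(1.0)
        assert rank_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = rank_correlation(x, y)
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation(np.ones(10), np.arange(10.0))
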