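import numpy as np
import pandas as pd
import pytest

from netplast import prediction as pr
from netplast.topology import FEATURE_NAMES


def toy_matrix(n=20, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 14)), columns=FEATURE_NAMES)
    df["size"] = np.abs(df["size"]) + 2
    df["D_ER"] = rng.normal(size=n)
    df["D_BA"] = rng.normal(size=n)
    df[pr.RESPONSE] = rng.normal(size=n)
    return df


class TestBuildFeatureMatrix:
    def test_assembles_sixteen_predictors_plus_response(self):
        feats = pd.DataFrame(np.ones((3, 14)), columns=FEATURE_NAMES,
                             index=["a", "b", "c"])
        fm = pr.build_feature_matrix(feats, {"a": 1, "b": 2, "c": 3},
                                     {"a": 4, "b": 5, "c": 6},
                                     {"a": 0.1, "b": 0.2, "c": 0.3})
        assert list(fm.columns) == list(pr.PREDICTOR_NAMES) + [pr.RESPONSE]

    def test_missing_values_rejected(self):
        feats = pd.DataFrame(np.ones((2, 14)), columns=FEATURE_NAMES,
                             index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            pr.build_feature_matrix(feats, {"a": 1}, {"a": 2, "b": 3},
                                    {"a": 0.1, "b": 0.2})


class TestPca:
    def test_perfectly_correlated_columns_share_pc1(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        df = pd.DataFrame({"u": x, "v": 2 * x + 5, "w": rng.normal(size=50)})
        scores, loadings, var = pr.pca_features(df, columns=["u", "v", "w"])
        l1 = loadings.loc["PC1"]
        assert abs(l1["u"]) == pytest.approx(abs(l1["v"]), abs=1e-6)
        assert var[0] > 0.6

    def test_planted_two_factor_structure_recovered(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.normal(size=(2, 60))
        cols = {}
        for i in range(5):
            cols[f"a{i}"] = f1 + 0.05 * rng.normal(size=60)
            cols[f"b{i}"] = f2 + 0.05 * rng.normal(size=60)
        df = pd.DataFrame(cols)
        _, _, var = pr.pca_features(df, columns=list(cols))
        assert var[:2].sum() >= 0.90

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0],
                           "c": [3.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings, var = pr.pca_features(df, columns=["a", "b", "c"])
        assert "a" not in loadings.columns

    def test_variance_fractions_sum_to_one(self):
        df = toy_matrix(15, seed=3)
        _, _, var = pr.pca_features(df)
        assert var.sum() == pytest.approx(1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pr.pca_features(toy_matrix(2))

    def test_sign_convention_deterministic(self):
        df = toy_matrix(12, seed=4)
        l1 = pr.pca_features(df)[1]
        l2 = pr.pca_features(df)[1]
        pd.testing.assert_frame_equal(l1, l2)
        for _, row in l1.iterrows():
            assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_real_er_ba_panels_separate_along_pc1(self):
        """Joint PCA of real + ER + BA replicate features puts the three
        groups in order along the first component."""
        from netplast import null_models, synthetic, topology

        real = [synthetic.mixture_network(80, 1200, 0.6, seed=s,
                                          name=f"real{s}") for s in range(5)]
        er = [null_models.generate_er(80, 1200, seed=20 + s) for s in range(5)]
        ba = [null_models.generate_ba(real[0], seed=40 + s) for s in range(5)]
        rows, labels = [], []
        for grp, nets in (("real", real), ("ER", er), ("BA", ba)):
            for g in nets:
                rows.append(topology.compute_features(g, modularity_seed=1))
                labels.append(grp)
        df = pd.DataFrame(rows)
        keep = [c for c in df.columns if df[c].std() > 0]
        scores, _, _ = pr.pca_features(df, columns=keep)
        pc1 = scores["PC1"].groupby(pd.Series(labels, index=scores.index)).mean()
        # real networks sit between the two model clusters
        assert (pc1["ER"] < pc1["real"] < pc1["BA"]) or \
               (pc1["BA"] < pc1["real"] < pc1["ER"])


class TestUnivariate:
    def test_exact_linear_response_gives_zero_cv_mse(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x": x, pr.RESPONSE: 2 * x})
        fit = pr.fit_univariate(df, "x", k_folds=5, seed=0)
        assert fit["cv_mse"] == pytest.approx(0.0, abs=1e-20)
        assert fit["slope"] == pytest.approx(2.0)

    def test_independent_predictor_cv_mse_near_response_variance(self):
        rng = np.random.default_rng(5)
        mses, var_y = [], []
        for _ in range(100):
            y = rng.normal(size=40)
            df = pd.DataFrame({"x": rng.normal(size=40), pr.RESPONSE: y})
            mses.append(pr.fit_univariate(df, "x", seed=0)["cv_mse"])
            var_y.append(y.var())
        assert np.mean(mses) == pytest.approx(np.mean(var_y), rel=0.15)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), pr.RESPONSE: np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            pr.fit_univariate(df, "x")

    def test_scan_sorted_and_skips_constants(self):
        df = toy_matrix(18, seed=6)
        df["size"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            scan = pr.univariate_scan(df, k_folds=3, seed=0)
        assert "size" not in set(scan["predictor"])
        assert scan["cv_mse"].is_monotonic_increasing


class TestRandomForest:
    def test_deterministic_given_seed(self):
        df = toy_matrix(25, seed=7)
        a = pr.fit_random_forest(df, n_trees=60, seed=3)
        b = pr.fit_random_forest(df, n_trees=60, seed=3)
        assert a["cv_mse"] == b["cv_mse"]
        pd.testing.assert_series_equal(a["importances"], b["importances"])

    def test_planted_signal_ranks_first_in_importance(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(80, 14)), columns=FEATURE_NAMES)
        df[pr.RESPONSE] = np.tanh(df["degree_entropy"]) \
            + 0.05 * rng.normal(size=80)
        rf = pr.fit_random_forest(df, n_trees=200, seed=0)
        assert rf["importances"].index[0] == "degree_entropy"

    def test_noise_response_spreads_importance(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(60, 14)), columns=FEATURE_NAMES)
        df[pr.RESPONSE] = rng.normal(size=60)
        rf = pr.fit_random_forest(df, n_trees=200, seed=0)
        imp = rf["importances"]
        assert imp.max() < 4 * (1 / 14)
        assert imp.sum() == pytest.approx(1.0)

    def test_cv_mse_non_negative(self):
        df = toy_matrix(20, seed=10)
        assert pr.fit_random_forest(df, n_trees=40, seed=1)["cv_mse"] >= 0
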