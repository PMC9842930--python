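import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nspnet import (
    best_k_search,
    common_score_pca,
    cross_predict,
    graph_baselines,
    loo_cv_predict,
    permutation_pvalue,
    rank_features,
    system_weights,
)
from nspnet.prediction import _loo_hat_predict, normalize_features


def _noise_features(rng, n, k):
    return rng.standard_normal((n, k))


class TestRankFeatures:
    def test_signal_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 50)
        x = np.column_stack([rng.normal(0, 1, (50, 3)), y])
        assert rank_features(x, y)[0] == 3

    def test_f_equals_squared_t_of_univariate_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (40, 1))
        y = 0.5 * x[:, 0] + rng.normal(0, 1, 40)
        from sklearn.feature_selection import f_regression

        f_val = f_regression(x, y)[0][0]
        slope, _, _, p, se = sps.linregress(x[:, 0], y)
        assert f_val == pytest.approx((slope / se) ** 2, rel=1e-8)

    def test_ranking_tracks_population_correlations(self):
        good = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            z = rng.normal(0, 1, 500)
            x = np.column_stack(
                [
                    0.9 * z + np.sqrt(1 - 0.81) * rng.normal(0, 1, 500),
                    0.5 * z + np.sqrt(1 - 0.25) * rng.normal(0, 1, 500),
                    rng.normal(0, 1, 500),
                ]
            )
            good += list(rank_features(x, z)) == [0, 1, 2]
        assert good >= 38

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            rank_features(np.random.default_rng(0).normal(0, 1, (10, 2)),
                          np.ones(10))


class TestLooCV:
    def test_noiseless_linear_signal_predicted_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (20, 1))
        y = 2.0 + 3.0 * x[:, 0]
        assert np.allclose(loo_cv_predict(x, y), y, atol=1e-8)

    def test_hat_matrix_fast_path_matches_explicit_folds(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (25, 4))
        y = rng.normal(0, 1, 25)
        assert np.allclose(
            loo_cv_predict(x, y), _loo_hat_predict(x, y), atol=1e-9
        )

    def test_null_predictions_anticorrelate_on_average(self):
        # LOO-CV on pure noise is pessimistic: r(y, y_pred) centers below 0
        rs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, (30, 3))
            y = rng.normal(0, 1, 30)
            pred = _loo_hat_predict(x, y)
            rs.append(np.corrcoef(y, pred)[0, 1])
        assert np.mean(rs) < 0.0

    def test_subject_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (15, 2))
        y = rng.normal(0, 1, 15)
        perm = rng.permutation(15)
        assert np.allclose(
            loo_cv_predict(x, y)[perm], loo_cv_predict(x[perm], y[perm])
        )

    def test_rank_deficient_fold_names_fold(self):
        x = np.zeros((8, 2))
        x[:, 0] = np.arange(8.0)
        x[:, 1] = 2 * x[:, 0]  # collinear
        with pytest.raises(ValueError, match="fold"):
            loo_cv_predict(x, np.arange(8.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n >= k"):
            loo_cv_predict(np.eye(3), np.arange(3.0))


class TestBestKSearch:
    def test_duplicated_score_feature_wins_at_k1(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 40)
        x = np.column_stack([_noise_features(rng, 40, 5), y])
        res = best_k_search(x, y)
        assert res.best_k == 1
        assert res.selected == ["5"]
        assert res.r_obs > 0.999

    def test_max_over_k_at_least_k1(self):
        rng = np.random.default_rng(1)
        x = _noise_features(rng, 30, 6)
        y = x[:, 0] + rng.normal(0, 1, 30)
        res = best_k_search(x, y)
        r_k1 = res.per_k.query("k == 1")["r"].iloc[0]
        assert res.r_obs >= r_k1

    def test_unselected_weights_are_zero(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(
            _noise_features(rng, 30, 6), columns=[f"f{j}" for j in range(6)]
        )
        y = x["f2"].to_numpy() + rng.normal(0, 0.1, 30)
        res = best_k_search(x, y)
        unselected = res.weights.index.difference(res.selected)
        assert (res.weights.loc[unselected] == 0).all()
        assert (res.weights.loc[res.selected] != 0).all()

    def test_selection_leakage_biases_r_upward_on_noise(self):
        # selection on all subjects peeks at y: null r_obs is optimistic
        rs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            x = _noise_features(rng, 40, 60)
            y = rng.normal(0, 1, 40)
            rs.append(best_k_search(x, y).r_obs)
        assert np.mean(rs) > 0.2

    def test_nested_mode_runs_and_reduces_null_optimism(self):
        rs_fixed, rs_nested = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = _noise_features(rng, 30, 20)
            y = rng.normal(0, 1, 30)
            rs_fixed.append(best_k_search(x, y, max_k=5).r_obs)
            rs_nested.append(best_k_search(x, y, max_k=5, nested=True).r_obs)
        assert np.mean(rs_nested) <= np.mean(rs_fixed)

    def test_weight_invariance_to_feature_rescaling(self):
        rng = np.random.default_rng(3)
        x = _noise_features(rng, 40, 5)
        y = x[:, 1] + rng.normal(0, 0.2, 40)
        res_a = best_k_search(x, y)
        x_scaled = x * np.array([1.0, 100.0, 0.01, 5.0, 2.0])
        res_b = best_k_search(x_scaled + 7.0, y)
        assert np.allclose(
            res_a.weights.to_numpy(), res_b.weights.to_numpy(), atol=1e-8
        )


class TestPermutation:
    def test_perfect_prediction_attains_minimum_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 1))
        y = 2 * x[:, 0]
        p = permutation_pvalue(x, y, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_doubling_permutations_is_stable(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (40, 2))
        y = 0.6 * x[:, 0] + rng.normal(0, 1.2, 40)
        p1 = permutation_pvalue(x, y, n_perm=1000, seed=5)
        p2 = permutation_pvalue(x, y, n_perm=2000, seed=5)
        assert abs(p1 - p2) < 0.02

    def test_minimum_permutation_count_enforced(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.ones((10, 1)), np.arange(10.0), n_perm=10)


class TestSystemWeights:
    @pytest.fixture
    def atlas(self):
        return pd.Series(
            ["limbic", "limbic", "visual", "visual", "motor", "motor"],
            index=[f"r{j}" for j in range(6)],
        )

    def test_single_selected_region(self, atlas):
        w = pd.Series([0.7, 0, 0, 0, 0, 0], index=atlas.index)
        out = system_weights(w, ["r0"], atlas)
        assert out.loc["limbic", "mean_weight"] == pytest.approx(0.7)
        assert out.loc["visual", "mean_weight"] == 0.0
        assert out.loc["visual", "empty"]
        assert not out.loc["limbic", "empty"]

    def test_cancelling_weights_average_to_zero(self, atlas):
        w = pd.Series([0.2, -0.2, 0, 0, 0, 0], index=atlas.index)
        out = system_weights(w, ["r0", "r1"], atlas)
        assert out.loc["limbic", "mean_weight"] == pytest.approx(0.0)
        assert out.loc["limbic", "n_selected"] == 2

    def test_signal_system_dominates_over_seeds(self, atlas):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(
                rng.standard_normal((60, 6)), columns=atlas.index
            )
            y = (x["r0"] + x["r1"]).to_numpy() + rng.normal(0, 0.5, 60)
            res = best_k_search(x, y)
            out = system_weights(res.weights, res.selected, atlas)
            hits += out["mean_weight"].abs().idxmax() == "limbic"
        assert hits >= 40

    def test_unknown_selected_region_rejected(self, atlas):
        w = pd.Series(0.0, index=atlas.index)
        with pytest.raises(ValueError):
            system_weights(w, ["nope"], atlas)


class TestGraphBaselines:
    def test_all_ones_degree(self):
        atlas = pd.Series(["a", "a", "b", "b"],
                          index=[str(j) for j in range(4)])
        out = graph_baselines(np.ones((4, 4)), atlas)
        assert np.allclose(out["degree"], 3.0)

    def test_within_system_only_region_has_zero_pc(self):
        atlas = pd.Series(["a", "a", "b"], index=["0", "1", "2"])
        fc = np.array([[1, 0.8, 0], [0.8, 1, 0], [0, 0, 1.0]])
        out = graph_baselines(fc, atlas)
        assert out.loc["0", "pc"] == pytest.approx(0.0)

    def test_even_spread_over_seven_systems(self):
        # one hub with equal weight into each of 7 systems: PC = 6/7
        n = 8
        fc = np.zeros((n, n))
        fc[0, 1:] = fc[1:, 0] = 0.5
        np.fill_diagonal(fc, 1.0)
        atlas = pd.Series(
            ["hub"] + [f"s{j}" for j in range(7)],
            index=[str(j) for j in range(n)],
        )
        out = graph_baselines(fc, atlas)
        assert out.loc["0", "pc"] == pytest.approx(6 / 7)

    def test_isolated_region_pc_zero(self):
        atlas = pd.Series(["a", "a", "b"], index=["0", "1", "2"])
        fc = np.eye(3)
        out = graph_baselines(fc, atlas)
        assert np.allclose(out["pc"], 0.0)
        assert np.allclose(out["degree"], 0.0)


class TestCommonScorePCA:
    def test_identical_scores_explain_everything(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 50)
        _, var = common_score_pca(s, s)
        assert var == pytest.approx(1.0)

    def test_closed_form_variance_for_known_correlation(self):
        # construct vectors with exact sample correlation rho
        rng = np.random.default_rng(1)
        n, rho = 200, 0.6
        u = rng.normal(0, 1, n)
        v = rng.normal(0, 1, n)
        u = (u - u.mean()) / u.std()
        v = v - v.mean()
        v -= (v @ u) / (u @ u) * u
        v /= v.std()
        y = rho * u + np.sqrt(1 - rho**2) * v
        _, var = common_score_pca(u, y)
        assert var == pytest.approx((1 + rho) / 2, abs=1e-8)

    def test_sign_fixed_to_first_score(self):
        rng = np.random.default_rng(2)
        bd = rng.normal(0, 1, 100)
        adhd = 0.5 * bd + rng.normal(0, 1, 100)
        pc1, _ = common_score_pca(bd, adhd)
        assert np.corrcoef(pc1, bd)[0, 1] > 0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            common_score_pca(np.ones(10), np.arange(10.0))


class TestCrossPredict:
    def test_same_scores_reproduce_source_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 2))
        y = x[:, 0] + rng.normal(0, 0.5, 30)
        r_self = np.corrcoef(y, loo_cv_predict(x, y))[0, 1]
        r_cross, _ = cross_predict(x, y, n_perm=200, seed=0)
        assert r_cross == pytest.approx(r_self, rel=1e-10)

    def test_affine_transformed_scores_keep_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (30, 2))
        y = x[:, 0] + rng.normal(0, 0.5, 30)
        r_a, _ = cross_predict(x, y, n_perm=200, seed=0)
        r_b, _ = cross_predict(x, 3.0 * y + 10.0, n_perm=200, seed=0)
        assert r_b == pytest.approx(r_a, rel=1e-10)

    def test_unrelated_scores_rarely_significant(self):
        sig = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, (30, 3))
            y_b = rng.normal(0, 1, 30)
            _, p = cross_predict(x, y_b, n_perm=200, seed=seed)
            sig += p < 0.05
        assert sig <= 6


def test_normalize_features_rejects_constant_column():
    x = np.ones((10, 2))
    with pytest.raises(ValueError):
        normalize_features(x)
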