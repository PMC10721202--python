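"""Cross-validation engine, ridge path, permutation test and battery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

import actsparse as asp
from actsparse.errors import ConfigurationError, DegenerateInputError, DomainError
from actsparse.regression import _adjusted_r2, _ridge_path


def _synth(n, beta, target_r2, seed, n_layers=None, layer_size=64):
    n_layers = n_layers if n_layers is not None else len(beta)
    cfg = asp.SyntheticConfig(
        n_images=n, n_layers=n_layers, layer_sizes=[layer_size] * n_layers,
        beta=np.asarray(beta, dtype=float), target_r2=target_r2, seed=seed)
    S = asp.zscore_columns(
        asp.sparsity_profile(asp.generate_activations(cfg)).to_numpy())
    y, info = asp.simulate_scores(S, cfg)
    return S, y, cfg, info


class TestFolds:
    def test_partition_properties(self):
        cfg = asp.CVConfig(folds=10, repeats=1, seed=5)
        fold_id = asp.make_folds(100, cfg, 0)
        counts = np.bincount(fold_id, minlength=10)
        assert np.all(counts == 10)  # ten test sets of size 10

    def test_deterministic_per_repeat(self):
        cfg = asp.CVConfig(folds=7, repeats=1, seed=5)
        assert np.array_equal(asp.make_folds(53, cfg, 3),
                              asp.make_folds(53, cfg, 3))
        assert not np.array_equal(asp.make_folds(53, cfg, 3),
                                  asp.make_folds(53, cfg, 4))

    def test_too_few_samples_raises(self):
        with pytest.raises(DomainError):
            asp.make_folds(5, asp.CVConfig(folds=10, repeats=1, seed=0), 0)


class TestConfigValidation:
    def test_bad_folds(self):
        with pytest.raises(ConfigurationError):
            asp.CVConfig(folds=1)

    def test_empty_lambda_grid(self):
        with pytest.raises(ConfigurationError):
            asp.CVConfig(lambda_grid=np.array([]))

    def test_negative_lambda(self):
        with pytest.raises(ConfigurationError):
            asp.CVConfig(lambda_grid=np.array([-1.0, 1.0]))


class TestUnivariate:
    def test_noiseless_signal_near_perfect(self):
        rng = np.random.default_rng(0)
        x = asp.zscore_columns(rng.normal(size=200))
        y = 2.0 * x
        cfg = asp.CVConfig(folds=10, repeats=2, seed=1)
        res = asp.fit_univariate(x, y, cfg)
        assert res.r2 >= 0.999
        assert res.coefficients[0] == pytest.approx(2.0, abs=1e-10)

    def test_null_predictor_r2_near_zero(self):
        rng = np.random.default_rng(1)
        x = asp.zscore_columns(rng.normal(size=1000))
        y = rng.normal(size=1000)
        cfg = asp.CVConfig(folds=10, repeats=20, seed=2)
        res = asp.fit_univariate(x, y, cfg)
        assert -0.02 <= res.r2 <= 0.01

    def test_population_r2_half_recovered(self):
        rng = np.random.default_rng(3)
        x = asp.zscore_columns(rng.normal(size=2000))
        beta = 1.0
        noise = rng.normal(0, 1.0, size=2000)  # Var(bx)/Var(y) = 0.5
        y = beta * x + noise
        cfg = asp.CVConfig(folds=10, repeats=2, seed=4)
        res = asp.fit_univariate(x, y, cfg)
        assert 0.45 <= res.r2 <= 0.55

    def test_r2_invariant_to_affine_rescaling_of_y(self):
        rng = np.random.default_rng(5)
        x = asp.zscore_columns(rng.normal(size=300))
        y = x + rng.normal(0, 1, 300)
        cfg = asp.CVConfig(folds=10, repeats=2, seed=6)
        r1 = asp.fit_univariate(x, y, cfg).r2
        r2 = asp.fit_univariate(x, 3.7 * y - 11.0, cfg).r2
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(DegenerateInputError):
            asp.fit_univariate(np.ones(50), np.arange(50.0),
                               asp.CVConfig(folds=5, repeats=1, seed=0))


class TestRidge:
    def test_vanishing_penalty_matches_ols(self):
        rng = np.random.default_rng(7)
        X = asp.zscore_columns(rng.normal(size=(300, 5)))
        y = X @ np.array([1, -2, 0.5, 0, 3.0]) + rng.normal(0, 0.5, 300)
        cfg = asp.CVConfig(folds=5, repeats=1, seed=8,
                           lambda_grid=np.array([1e-8]))
        res = asp.fit_ridge(X, y, cfg)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(300), X]), y, rcond=None)[0]
        np.testing.assert_allclose(res.coefficients, ols[1:], atol=1e-4)

    def test_infinite_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(9)
        X = asp.zscore_columns(rng.normal(size=(200, 4)))
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        cfg = asp.CVConfig(folds=5, repeats=1, seed=10,
                           lambda_grid=np.array([1e8]))
        res = asp.fit_ridge(X, y, cfg)
        assert np.abs(res.coefficients).max() < 1e-4
        assert res.r2 <= 0.0

    def test_path_solver_matches_sklearn_ridge(self):
        """The SVD regularization path must agree with an independent
        penalized solver across the grid."""
        rng = np.random.default_rng(11)
        X = asp.zscore_columns(rng.normal(size=(80, 6)))
        y = rng.normal(size=80)
        lambdas = np.array([1e-3, 1.0, 50.0, 1e3])
        coefs, intercepts = _ridge_path(X, y, lambdas)
        for lam, c, b in zip(lambdas, coefs, intercepts):
            sk = Ridge(alpha=lam, fit_intercept=True).fit(X, y)
            np.testing.assert_allclose(c, sk.coef_, atol=1e-8)
            assert b == pytest.approx(sk.intercept_, abs=1e-8)

    def test_recovery_at_population_r2_quarter(self):
        beta = np.array([1, -1, 0.5, -0.5, 1, 0.3, -0.3, 0.8, -0.8, 0.2,
                         1, -1, 0.5, 0.4, -0.6])
        S, y, cfg, _ = _synth(2000, beta, 0.25, seed=12)
        cv = asp.CVConfig(folds=10, repeats=2, seed=13)
        res = asp.fit_ridge(S, y, cv)
        assert 0.20 <= res.r2 <= 0.30
        signs = np.sign(res.coefficients) == np.sign(beta)
        assert signs.sum() >= 14

    def test_coefficient_correlation_at_r2_half(self):
        beta = np.array([1, -1, 0.5, -0.5, 1, 0.3, -0.3, 0.8, -0.8, 0.2,
                         1, -1, 0.5, 0.4, -0.6])
        S, y, cfg, _ = _synth(2000, beta, 0.5, seed=14)
        cv = asp.CVConfig(folds=10, repeats=2, seed=15)
        res = asp.fit_ridge(S, y, cv)
        assert np.corrcoef(res.coefficients, beta)[0, 1] >= 0.9

    def test_adjusted_r2_formula(self):
        assert _adjusted_r2(0.5, 101, 10) == pytest.approx(
            1 - 0.5 * 100 / 90)
        assert np.isnan(_adjusted_r2(0.5, 10, 10))


class TestPermutation:
    def test_perfect_signal_minimal_p(self):
        rng = np.random.default_rng(16)
        x = asp.zscore_columns(rng.normal(size=100))
        cfg = asp.CVConfig(folds=10, repeats=1, seed=17, permutations=999)
        p = asp.permutation_pvalue(x, 2 * x, cfg, "univariate")
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(18)
        x = asp.zscore_columns(rng.normal(size=60))
        y = x + rng.normal(0, 2, 60)
        cfg = asp.CVConfig(folds=5, repeats=1, seed=19, permutations=199)
        assert (asp.permutation_pvalue(x, y, cfg)
                == asp.permutation_pvalue(x, y, cfg))

    def test_too_few_permutations_rejected(self):
        cfg = asp.CVConfig(folds=5, repeats=1, seed=0, permutations=10)
        with pytest.raises(ConfigurationError):
            asp.permutation_pvalue(np.arange(50.0), np.arange(50.0), cfg)


@pytest.fixture(scope="module")
def battery(class_image_run):
    run = class_image_run
    profile = asp.sparsity_profile(run["acts"])
    mats = asp.activation_matrices(run["acts"])
    features = asp.reduce_layers(mats)
    cfg = asp.CVConfig(folds=10, repeats=2, seed=21, permutations=99)
    return asp.run_model_battery(profile, features, run["scores"], cfg)


class TestBattery:
    def test_family_predictor_counts_fixture_rule(self, battery):
        """4-layer backend: counts 1 / 4 / k_l / 12 / 16."""
        tab = battery.battery_table.set_index("model_family")
        assert tab.loc["sparsity_per_layer", "n_predictors"] == 1
        assert tab.loc["sparsity_all", "n_predictors"] == 4
        assert tab.loc["pc_all3", "n_predictors"] == 12
        assert tab.loc["combined", "n_predictors"] == 16

    def test_five_families_reported(self, battery):
        assert list(battery.battery_table["model_family"]) == [
            "sparsity_per_layer", "sparsity_all", "pc_per_layer",
            "pc_all3", "combined"]

    def test_per_layer_table_contract(self, battery):
        t = battery.per_layer_table
        assert list(t["layer_id"]) == ["conv1_1", "conv2_1", "conv3_1", "fc1"]
        assert t["p_sparsity"].between(0, 1).all()
        assert np.isfinite(t["r2_sparsity"]).all()
        assert np.isfinite(t["coef_sparsity"]).all()

    def test_combined_not_much_worse_than_components(self, battery):
        tab = battery.battery_table.set_index("model_family")["r2"]
        assert tab["combined"] >= tab["sparsity_all"] - 0.05
        assert tab["combined"] >= tab["pc_all3"] - 0.05

    def test_sparsity_driven_signal_favors_sparsity_model(self):
        """When scores depend only on sparsity, the all-layer sparsity
        family beats the global 3-PC feature family clearly."""
        beta = np.array([1.5, -1.0, 0.8, -0.5])
        cfgs = asp.SyntheticConfig(
            n_images=300, n_layers=4, layer_sizes=[128, 96, 64, 32],
            beta=beta, target_r2=0.8, seed=22)
        acts = asp.generate_activations(cfgs)
        profile = asp.sparsity_profile(acts)
        S = asp.zscore_columns(profile.to_numpy())
        y, _ = asp.simulate_scores(S, cfgs)
        mats = asp.activation_matrices(acts)
        features = asp.reduce_layers(mats)
        cfg = asp.CVConfig(folds=10, repeats=1, seed=23, permutations=10_000)
        bat = asp.run_model_battery(profile, features, y, cfg,
                                    permute_univariate=False)
        tab = bat.battery_table.set_index("model_family")["r2"]
        assert tab["sparsity_all"] >= tab["pc_all3"] + 0.1

    def test_layer_mismatch_raises(self, class_image_run):
        run = class_image_run
        profile = asp.sparsity_profile(run["acts"])
        mats = asp.activation_matrices(run["acts"])
        features = asp.reduce_layers(mats)
        features.pop("fc1")
        cfg = asp.CVConfig(folds=5, repeats=1, seed=0)
        with pytest.raises(ConfigurationError):
            asp.run_model_battery(profile, features, run["scores"], cfg)

    def test_full_determinism_of_result_tables(self, class_image_run):
        run = class_image_run
        profile = asp.sparsity_profile(run["acts"])
        mats = asp.activation_matrices(run["acts"])
        features = asp.reduce_layers(mats)
        cfg = asp.CVConfig(folds=5, repeats=2, seed=31, permutations=99)
        b1 = asp.run_model_battery(profile, features, run["scores"], cfg)
        b2 = asp.run_model_battery(profile, features, run["scores"], cfg)
        pd.testing.assert_frame_equal(b1.battery_table, b2.battery_table)
        pd.testing.assert_frame_equal(b1.per_layer_table, b2.per_layer_table)

    def test_fold_mode_close_to_full_mode_at_moderate_n(self, class_image_run):
        """Leak-free preprocessing should not change conclusions at this
        signal strength, only shave a little optimism."""
        run = class_image_run
        profile = asp.sparsity_profile(run["acts"])
        mats = asp.activation_matrices(run["acts"])
        features = asp.reduce_layers(mats)
        cfg_full = asp.CVConfig(folds=5, repeats=1, seed=32)
        cfg_fold = asp.CVConfig(folds=5, repeats=1, seed=32,
                                preprocess="fold")
        r_full = asp.run_model_battery(profile, features, run["scores"],
                                       cfg_full, permute_univariate=False)
        r_fold = asp.run_model_battery(profile, None, run["scores"], cfg_fold,
                                       activations=mats,
                                       permute_univariate=False)
        full = r_full.battery_table.set_index("model_family")["r2"]
        fold = r_fold.battery_table.set_index("model_family")["r2"]
        assert abs(full["sparsity_all"] - fold["sparsity_all"]) < 0.05
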