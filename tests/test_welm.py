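import numpy as np
import pytest

from sipwelm.welm import (
    GOLDEN_RATIO,
    KernelSpec,
    TrainingConfig,
    activation_apply,
    compute_class_weights,
    grid_search,
    hidden_output,
    init_hidden_layer,
    kernel_welm_predict,
    kernel_welm_score,
    kernel_welm_train,
    welm_predict,
    welm_score,
    welm_train,
    _solve_beta,
)


def gaussian_blobs(seed, n_pos=20, n_neg=20, d=4, sep=4.0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(sep, 1.0, (n_pos, d)), rng.normal(0.0, 1.0, (n_neg, d))]
    )
    y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
    return X, y


class TestActivations:
    @pytest.mark.parametrize(
        "z,expected", [(0.0, 1.0), (1.0, 0.0), (-1.0, 0.0), (2.0, 0.0), (-0.5, 0.5)]
    )
    def test_tribas_hat_shape(self, z, expected):
        assert activation_apply("tribas", z) == pytest.approx(expected)

    def test_sigmoid_midpoint(self):
        assert activation_apply("sigmoid", 0.0) == pytest.approx(0.5)

    def test_hardlim_threshold_and_radbas_peak(self):
        assert activation_apply("hardlim", 0.0) == 1.0
        assert activation_apply("hardlim", -1e-9) == 0.0
        assert activation_apply("radbas", 0.0) == 1.0

    def test_unknown_activation_lists_supported(self):
        with pytest.raises(ValueError, match="tribas"):
            activation_apply("relu", 0.0)


class TestHiddenLayer:
    def test_same_seed_reproduces_identical_layer(self):
        a = init_hidden_layer(5, 10, "tribas", seed=42)
        b = init_hidden_layer(5, 10, "tribas", seed=42)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.biases, b.biases)

    def test_different_seeds_differ(self):
        a = init_hidden_layer(5, 10, "tribas", seed=1)
        b = init_hidden_layer(5, 10, "tribas", seed=2)
        assert not np.array_equal(a.input_weights, b.input_weights)

    def test_draw_ranges(self):
        layer = init_hidden_layer(3, 10_000, "tribas", seed=0)
        assert layer.input_weights.min() >= -1 and layer.input_weights.max() <= 1
        assert layer.biases.min() >= 0 and layer.biases.max() <= 1

    def test_zero_weights_give_unit_tribas_output(self):
        layer = init_hidden_layer(3, 4, "tribas", seed=0)
        layer.input_weights[:] = 0.0
        layer.biases[:] = 0.0
        np.testing.assert_array_equal(
            hidden_output(layer, np.ones((5, 3))), np.ones((5, 4))
        )

    def test_output_matches_elementwise_loop(self):
        layer = init_hidden_layer(4, 6, "sigmoid", seed=3)
        X = np.random.default_rng(5).normal(size=(7, 4))
        F = hidden_output(layer, X)
        for i in range(7):
            for l in range(6):
                z = layer.input_weights[l] @ X[i] + layer.biases[l]
                assert F[i, l] == pytest.approx(1 / (1 + np.exp(-z)))

    def test_dimension_mismatch(self):
        layer = init_hidden_layer(4, 6, "tribas", seed=0)
        with pytest.raises(ValueError, match="expects 4"):
            hidden_output(layer, np.ones((2, 5)))


class TestClassWeights:
    def test_balanced_w1_gives_uniform_weights(self):
        y = np.r_[np.ones(10), -np.ones(10)]
        ws = compute_class_weights(y, "W1")
        np.testing.assert_allclose(ws.per_sample_weights, 0.1)

    def test_w1_ratio_equals_imbalance(self):
        y = np.r_[np.ones(1), -np.ones(9)]
        w = compute_class_weights(y, "W1").per_sample_weights
        assert w[0] / w[1] == pytest.approx(9.0)

    def test_w2_scales_majority_by_golden_ratio(self):
        y = np.r_[np.ones(2), -np.ones(8)]
        w = compute_class_weights(y, "W2").per_sample_weights
        assert w[0] == pytest.approx(1 / 2)
        assert w[-1] == pytest.approx(GOLDEN_RATIO / 8)

    def test_none_ignores_imbalance(self):
        y = np.r_[np.ones(1), -np.ones(99)]
        np.testing.assert_array_equal(
            compute_class_weights(y, "none").per_sample_weights, 1.0
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_class_weights(np.ones(5), "W1")


class TestWelmTrain:
    def test_left_and_right_forms_agree(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(8, 6))
        y = np.where(rng.normal(size=8) > 0, 1.0, -1.0)
        w = rng.uniform(0.5, 2.0, size=8)
        np.testing.assert_allclose(
            _solve_beta(F, y, w, 10.0, "right"),
            _solve_beta(F, y, w, 10.0, "left"),
            atol=1e-8,
        )

    def test_left_right_agree_over_shape_sweep(self):
        rng = np.random.default_rng(1)
        for n, L in [(5, 60), (60, 5), (30, 30), (60, 60)]:
            F = rng.normal(size=(n, L))
            y = np.where(rng.normal(size=n) > 0, 1.0, -1.0)
            w = rng.uniform(0.1, 3.0, size=n)
            np.testing.assert_allclose(
                _solve_beta(F, y, w, 100.0, "right"),
                _solve_beta(F, y, w, 100.0, "left"),
                atol=1e-8,
            )

    def test_identity_weights_reduce_to_unweighted_elm(self):
        X, y = gaussian_blobs(2, n_pos=12, n_neg=8)
        cfg = TrainingConfig(n_hidden=10, C=50.0, scheme="none", seed=4)
        model = welm_train(X, y, cfg)
        # unweighted ELM closed form: beta = F^T (I/C + F F^T)^{-1} y
        F = hidden_output(model.hidden, X)
        beta_u = F.T @ np.linalg.solve(np.eye(len(y)) / 50.0 + F @ F.T, y)
        np.testing.assert_allclose(model.beta, beta_u, atol=1e-8)

    def test_separable_data_large_c_fits_training_labels(self):
        X, y = gaussian_blobs(3)
        cfg = TrainingConfig(n_hidden=60, C=1e6, scheme="none", seed=1)
        model = welm_train(X, y, cfg)
        np.testing.assert_array_equal(welm_predict(model, X), y)

    def test_small_c_shrinks_beta_to_zero(self):
        X, y = gaussian_blobs(4)
        norms = []
        for C in (1e-2, 1e-5, 1e-8):
            cfg = TrainingConfig(n_hidden=20, C=C, scheme="none", seed=0)
            norms.append(np.linalg.norm(welm_train(X, y, cfg).beta))
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-6

    def test_nonpositive_c_rejected(self):
        X, y = gaussian_blobs(5)
        with pytest.raises(ValueError, match="C must be positive"):
            welm_train(X, y, TrainingConfig(C=0.0))

    def test_auto_solver_picks_by_shape(self):
        X, y = gaussian_blobs(6, n_pos=5, n_neg=5, d=3)
        assert welm_train(X, y, TrainingConfig(n_hidden=20)).solver_form == "right"
        assert welm_train(X, y, TrainingConfig(n_hidden=4)).solver_form == "left"

    def test_default_profile(self):
        cfg = TrainingConfig()
        assert (cfg.activation, cfg.n_hidden, cfg.C, cfg.scheme) == (
            "tribas", 5000, 100.0, "W1",
        )


class TestScoresAndPredictions:
    def test_zero_beta_gives_zero_scores(self):
        X, y = gaussian_blobs(7)
        model = welm_train(X, y, TrainingConfig(n_hidden=8, seed=0))
        model.beta[:] = 0.0
        np.testing.assert_array_equal(welm_score(model, X), 0.0)
        np.testing.assert_array_equal(welm_predict(model, X), 1)  # tie -> +1

    def test_single_sample_matches_manual_dot_product(self):
        X, y = gaussian_blobs(8)
        model = welm_train(X, y, TrainingConfig(n_hidden=8, seed=0))
        x = X[:1]
        expected = hidden_output(model.hidden, x)[0] @ model.beta
        assert welm_score(model, x)[0] == pytest.approx(expected)

    def test_predictions_are_sign_of_scores(self):
        X, y = gaussian_blobs(9)
        model = welm_train(X, y, TrainingConfig(n_hidden=25, seed=2))
        scores = welm_score(model, X)
        np.testing.assert_array_equal(
            welm_predict(model, X), np.where(scores >= 0, 1, -1)
        )


class TestKernelWelm:
    def test_linear_kernel_on_feature_map_equals_explicit(self):
        X, y = gaussian_blobs(10, n_pos=15, n_neg=10)
        cfg = TrainingConfig(n_hidden=12, C=20.0, scheme="W1", seed=6)
        explicit = welm_train(X, y, cfg)
        F = hidden_output(explicit.hidden, X)
        kernel = kernel_welm_train(F, y, KernelSpec("linear"), C=20.0, scheme="W1")
        np.testing.assert_allclose(
            kernel_welm_score(kernel, F), welm_score(explicit, X), atol=1e-6
        )

    def test_tribas_map_kernel_equals_explicit_welm(self):
        X, y = gaussian_blobs(11, n_pos=10, n_neg=14)
        cfg = TrainingConfig(n_hidden=15, C=5.0, scheme="W1", seed=9)
        explicit = welm_train(X, y, cfg)
        kernel = kernel_welm_train(
            X, y, KernelSpec("tribas_map", n_hidden=15, seed=9), C=5.0, scheme="W1"
        )
        np.testing.assert_allclose(
            kernel_welm_score(kernel, X), welm_score(explicit, X), atol=1e-6
        )

    def test_single_point_scalar_closed_form(self):
        X = np.array([[2.0, 1.0]])
        y = np.array([1.0])
        omega = (X @ X.T).item()
        for C in (1.0, 1e6):
            model = kernel_welm_train(X, y, KernelSpec("linear"), C=C, scheme="none")
            expected = omega / (1.0 / C + omega)
            assert kernel_welm_score(model, X)[0] == pytest.approx(expected)
        assert kernel_welm_score(model, X)[0] == pytest.approx(1.0, abs=1e-5)

    def test_rbf_interpolates_distinct_points_at_large_c(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 3))
        y = np.where(rng.normal(size=20) > 0, 1.0, -1.0)
        model = kernel_welm_train(
            X, y, KernelSpec("rbf", gamma=0.5), C=1e6, scheme="none"
        )
        np.testing.assert_array_equal(kernel_welm_predict(model, X), y)

    def test_invalid_kernel_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            KernelSpec("poly")
        with pytest.raises(ValueError, match="gamma"):
            KernelSpec("rbf")


class TestGridSearch:
    def test_single_point_grid_returns_that_config(self):
        X, y = gaussian_blobs(13)
        cfg, table = grid_search(
            X, y, {"C": [7.0], "n_hidden": [10]}, folds=2, seed=0
        )
        assert cfg.C == 7.0 and cfg.n_hidden == 10
        assert len(table) == 1

    def test_dominant_config_selected_over_degenerate(self):
        X, y = gaussian_blobs(14, n_pos=20, n_neg=20)
        cfg, table = grid_search(
            X, y, {"C": [100.0, 1e-9], "n_hidden": [30]}, folds=2, seed=1
        )
        assert cfg.C == 100.0
        assert len(table) == 2

    def test_same_seed_gives_identical_selection_and_table(self):
        X, y = gaussian_blobs(15)
        out1 = grid_search(X, y, {"C": [1.0, 10.0]}, folds=2, seed=5)
        out2 = grid_search(X, y, {"C": [1.0, 10.0]}, folds=2, seed=5)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_unknown_metric_rejected(self):
        X, y = gaussian_blobs(16)
        with pytest.raises(ValueError, match="unknown metric"):
            grid_search(X, y, {"C": [1.0]}, folds=2, metric="F1")

    def test_excessive_folds_rejected(self):
        X, y = gaussian_blobs(17, n_pos=3, n_neg=20)
        with pytest.raises(ValueError, match="exceeds"):
            grid_search(X, y, {"C": [1.0]}, folds=4)


class TestImbalanceProperty:
    def test_weighting_raises_minority_sensitivity(self):
        """On 10:1 imbalanced Gaussian data the W1 scheme recovers more of
        the minority class than unweighted ELM, and its Sn*Sp geometric mean
        is higher for most seeds (sign test at alpha=0.05 over 20 seeds)."""
        from scipy.stats import binomtest

        from sipwelm.evaluation import compute_metrics, confusion_counts

        sn_w, sn_u, wins, ties = [], [], 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [rng.normal(0.6, 1.0, (20, 10)), rng.normal(0.0, 1.0, (200, 10))]
            )
            y = np.r_[np.ones(20), -np.ones(200)]
            Xt = np.vstack(
                [rng.normal(0.6, 1.0, (150, 10)), rng.normal(0.0, 1.0, (150, 10))]
            )
            yt = np.r_[np.ones(150), -np.ones(150)]
            gm = {}
            for scheme in ("W1", "none"):
                cfg = TrainingConfig(n_hidden=80, C=100.0, scheme=scheme, seed=seed)
                rep = compute_metrics(
                    confusion_counts(yt, welm_predict(welm_train(X, y, cfg), Xt))
                )
                gm[scheme] = np.sqrt(rep.Sn * rep.Sp)
                (sn_w if scheme == "W1" else sn_u).append(rep.Sn)
            if gm["W1"] > gm["none"]:
                wins += 1
            elif gm["W1"] == gm["none"]:
                ties += 1
        assert np.mean(sn_w) >= np.mean(sn_u)
        p = binomtest(wins, 20 - ties, alternative="greater").pvalue
        assert p < 0.05
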