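"""FCM initialisation, gradients, the training loop and cross-validation."""

import numpy as np
import pytest

import fuzzybci as fb
from fuzzybci import _kernels
from fuzzybci import training as tr
from fuzzybci.errors import (
    ClusterCountError,
    ConfigError,
    SmallClassWarning,
)
from .conftest import make_model


def numerical_gradients(x, u_d, model, eps=1e-6):
    """Central-difference oracle over every parameter of the model."""
    groups = {
        "mixing": model.mixing.weights,
        "coefficients": model.consequents.coefficients,
        "intercepts": model.consequents.intercepts,
        "centers": model.antecedents.centers,
        "widths": model.antecedents.widths,
    }
    out = {}
    for name, arr in groups.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            ep = tr.sample_error(fb.forward(x, model), u_d)
            arr[i] = orig - eps
            em = tr.sample_error(fb.forward(x, model), u_d)
            arr[i] = orig
            g[i] = (ep - em) / (2 * eps)
        out[name] = g
    return out


class TestFCM:
    def test_identical_points_single_cluster(self):
        X = np.full((6, 3), 2.5)
        res = tr.fcm_cluster(X, 1, seed=0)
        np.testing.assert_allclose(res.centers, 2.5)

    def test_two_blob_center_recovery(self, rng):
        a = rng.normal(0.0, 0.1, (60, 2))
        b = rng.normal(10.0, 0.1, (60, 2))
        X = np.vstack([a, b])
        res = tr.fcm_cluster(X, 2, seed=1)
        means = np.sort(res.centers[:, 0])
        targets = np.sort([a.mean(axis=0)[0], b.mean(axis=0)[0]])
        np.testing.assert_allclose(means, targets, atol=0.2)

    def test_membership_rows_sum_to_one(self, rng):
        X = rng.random((40, 5))
        res = tr.fcm_cluster(X, 4, seed=2)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert ((res.memberships >= 0) & (res.memberships <= 1)).all()

    def test_objective_non_increasing(self, rng):
        X = rng.random((80, 3))
        res = tr.fcm_cluster(X, 3, seed=3)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-9).all()

    def test_more_clusters_than_samples_raises(self):
        with pytest.raises(ClusterCountError):
            tr.fcm_cluster(np.zeros((2, 2)), 3)

    def test_deterministic_given_seed(self, rng):
        X = rng.random((30, 4))
        r1 = tr.fcm_cluster(X, 3, seed=9)
        r2 = tr.fcm_cluster(X, 3, seed=9)
        np.testing.assert_array_equal(r1.centers, r2.centers)


class TestAntecedentInit:
    def test_width_is_half_the_center_distance(self):
        fcm = tr.FCMResult(np.array([[0.0, 0.0], [3.0, 4.0]]),
                           np.ones((2, 2)) / 2, 1, 0.0)
        ants = tr.init_antecedents(fcm, alpha=0.5, floor=1e-3)
        np.testing.assert_allclose(ants.widths, 2.5)  # alpha * 5
        np.testing.assert_allclose(ants.centers, fcm.centers.T)

    def test_coincident_centers_fall_back_to_data_std(self):
        X = np.random.default_rng(0).normal(0, 0.3, (50, 2))
        fcm = tr.FCMResult(np.zeros((3, 2)), np.ones((50, 3)) / 3, 1, 0.0)
        ants = tr.init_antecedents(fcm, floor=1e-3, X=X)
        np.testing.assert_allclose(
            ants.widths, np.repeat(X.std(axis=0)[:, None], 3, axis=1),
            atol=1e-12,
        )

    def test_duplicate_centers_ignore_each_other(self):
        # two merged centres plus one distinct: widths from the 0-3 distance
        centers = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        fcm = tr.FCMResult(centers, np.ones((3, 3)) / 3, 1, 0.0)
        ants = tr.init_antecedents(fcm, alpha=0.5, floor=1e-3)
        np.testing.assert_allclose(ants.widths, 1.5)

    def test_single_rule_uses_data_std(self):
        X = np.random.default_rng(1).normal(0, 0.3, (200, 3))
        fcm = tr.FCMResult(X.mean(axis=0, keepdims=True),
                           np.ones((200, 1)), 1, 0.0)
        ants = tr.init_antecedents(fcm, X=X)
        np.testing.assert_allclose(ants.widths[:, 0], X.std(axis=0))


class TestConsequentInit:
    def test_reproducible_and_in_range(self):
        c1, m1 = tr.init_consequents(4, 3, 2, seed=5)
        c2, m2 = tr.init_consequents(4, 3, 2, seed=5)
        np.testing.assert_array_equal(c1.coefficients, c2.coefficients)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        for arr in (c1.coefficients, c1.intercepts, m1.weights):
            assert (np.abs(arr) <= 1.0).all()

    def test_different_seeds_differ(self):
        c1, _ = tr.init_consequents(4, 3, 2, seed=5)
        c2, _ = tr.init_consequents(4, 3, 2, seed=6)
        assert not np.array_equal(c1.coefficients, c2.coefficients)


class TestErrorsAndRmse:
    def test_sample_error_cases(self):
        assert tr.sample_error([1.0, 0.0], [1.0, 0.0]) == 0.0
        assert tr.sample_error([0.0, 0.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_rmse_single_value(self):
        assert tr.rmse([[0.5]], [[0.0]]) == pytest.approx(0.5)

    def test_rmse_consistent_with_half_sum_error(self, rng):
        U = rng.normal(0, 1, (7, 3))
        T = rng.normal(0, 1, (7, 3))
        total = sum(tr.sample_error(u, t) for u, t in zip(U, T))
        assert tr.rmse(U, T) ** 2 * U.size / 2 == pytest.approx(total)


class TestGridRuleCount:
    def test_exhaustive_partition_explodes(self):
        assert tr.grid_rule_count(100, 2) == 2 ** 100
        assert tr.grid_rule_count(3, 6) == 216

    def test_invalid_dims_raise(self):
        with pytest.raises(ConfigError):
            tr.grid_rule_count(0, 2)


class TestGradients:
    def test_zero_error_gives_zero_gradients(self):
        model = make_model(3, 2, 2, seed=1)
        x = np.array([0.1, -0.2, 0.4])
        u = fb.forward(x, model)
        g = tr.gradients(x, u, model)
        for arr in (g.mixing, g.coefficients, g.intercepts, g.centers, g.widths):
            np.testing.assert_allclose(arr, 0.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_central_differences(self, trial):
        g_rng = np.random.default_rng(1000 + trial)
        model = make_model(3, 2, 2, seed=trial)
        x = g_rng.normal(0, 1, 3)
        u_d = g_rng.normal(0, 1, 2)
        analytic = tr.gradients(x, u_d, model)
        numeric = numerical_gradients(x, u_d, model)
        for name in numeric:
            a = getattr(analytic, name)
            n = numeric[name]
            scale = np.maximum(np.abs(n), 1.0)
            np.testing.assert_allclose(a / scale, n / scale, atol=1e-5)

    def test_mixing_gradient_sign(self, rng):
        model = make_model(2, 2, 2, seed=4)
        x = rng.normal(0, 1, 2)
        u_d = rng.normal(0, 1, 2)
        g = tr.gradients(x, u_d, model)
        u = fb.forward(x, model)
        mu = fb.firing_strengths(x, model.antecedents)
        y = fb.consequent_outputs(x, model.consequents)
        expected_sign = np.sign(np.outer(mu * y, u - u_d))
        assert (np.sign(g.mixing) == expected_sign).all()


class TestKernelEquivalence:
    def test_jit_and_python_paths_agree(self, rng):
        X = rng.random((12, 3))
        T = rng.random((12, 2))
        order = np.arange(12, dtype=np.int64)
        model = make_model(3, 2, 2, seed=8)
        state_a = [model.antecedents.centers.copy(), model.antecedents.widths.copy(),
                   model.consequents.coefficients.copy(), model.consequents.intercepts.copy(),
                   model.mixing.weights.copy()]
        state_b = [arr.copy() for arr in state_a]
        prev_a = [arr.copy() for arr in state_a]
        prev_b = [arr.copy() for arr in state_a]
        sse_jit = _kernels.sgd_epoch(X, T, order, *state_a, *prev_a, 0.01, 0.9, 1e-2)
        sse_py = _kernels._sgd_epoch_impl(X, T, order, *state_b, *prev_b, 0.01, 0.9, 1e-2)
        assert sse_jit == pytest.approx(sse_py, rel=1e-12)
        for a, b in zip(state_a, state_b):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_one_sgd_step_matches_analytic_gradients(self):
        model = make_model(3, 2, 2, seed=2)
        x = np.array([[0.2, -0.1, 0.3]])
        t = np.array([[1.0, 0.0]])
        g = tr.gradients(x[0], t[0], model)
        gamma = 0.01
        expect = {
            "c": model.antecedents.centers - gamma * g.centers,
            "s": model.antecedents.widths - gamma * g.widths,
            "a": model.consequents.coefficients - gamma * g.coefficients,
            "b": model.consequents.intercepts - gamma * g.intercepts,
            "w": model.mixing.weights - gamma * g.mixing,
        }
        state = [model.antecedents.centers.copy(), model.antecedents.widths.copy(),
                 model.consequents.coefficients.copy(),
                 model.consequents.intercepts.copy(), model.mixing.weights.copy()]
        prev = [arr.copy() for arr in state]
        _kernels.sgd_epoch(x, t, np.zeros(1, dtype=np.int64), *state, *prev,
                           gamma, 0.9, 1e-6)
        for got, key in zip(state, ("c", "s", "a", "b", "w")):
            np.testing.assert_allclose(got, expect[key], atol=1e-12)


class TestTrainLoop:
    def test_zero_epochs_returns_initialised_model(self, small_selected):
        scaled = fb.scale_features(small_selected)
        cfg = fb.TrainingConfig(epochs=0, rules=3, seed=4)
        model, history = fb.train(scaled, cfg)
        assert len(history) == 0
        # consequents must still be the untouched uniform [-1, 1] draw
        assert (np.abs(model.consequents.coefficients) <= 1).all()
        assert (np.abs(model.mixing.weights) <= 1).all()

    def test_fixed_seed_reproduces_history_bitwise(self, small_selected):
        scaled = fb.scale_features(small_selected)
        cfg = fb.TrainingConfig(epochs=25, rules=4, seed=7)
        _, h1 = fb.train(scaled, cfg)
        _, h2 = fb.train(scaled, cfg)
        np.testing.assert_array_equal(h1.train_rmse, h2.train_rmse)
        np.testing.assert_array_equal(h1.eval_rmse, h2.eval_rmse)
        np.testing.assert_array_equal(h1.learning_rate, h2.learning_rate)

    def test_recorded_rmse_never_increases_beyond_start(self, small_selected):
        scaled = fb.scale_features(small_selected)
        cfg = fb.TrainingConfig(epochs=60, rules=6, seed=2)
        _, history = fb.train(scaled, cfg)
        assert history.train_rmse[-1] <= history.train_rmse[0] + 1e-12

    def test_batch_mode_also_learns(self, small_selected):
        scaled = fb.scale_features(small_selected)
        cfg = fb.TrainingConfig(epochs=150, rules=6, seed=2,
                                update_mode="batch", learning_rate=0.05)
        _, history = fb.train(scaled, cfg)
        assert history.train_rmse[-1] < history.train_rmse[0]

    def test_min_tnorm_cannot_be_gradient_trained(self):
        model = make_model(2, 2, 2, seed=0)
        model.tnorm = "min"
        with pytest.raises(ConfigError):
            tr.gradients(np.zeros(2), np.zeros(2), model)

    def test_teacher_student_function_recovery(self):
        # noise-free targets from a same-shape network whose rules sit on
        # an identifiable three-cluster input structure
        g = np.random.default_rng(5)
        m, r, n = 5, 3, 2
        blob_centers = g.uniform(0.1, 0.9, (r, m))
        X = np.vstack([bc + g.normal(0, 0.08, (70, m)) for bc in blob_centers])
        fcm = tr.fcm_cluster(X, r, seed=123)
        ants = tr.init_antecedents(fcm, 0.5, 1e-2, X)
        teacher = fb.FNNModel(
            ants,
            fb.ConsequentSet(g.uniform(-1, 1, (m, r)), g.uniform(-1, 1, r)),
            fb.MixingWeights(g.uniform(-1, 1, (r, n))),
        )
        T = fb.forward(X, teacher)
        cfg = fb.TrainingConfig(epochs=1000, rules=r, seed=0)
        _, history = tr.fit(X, T, cfg)
        assert history.train_rmse[-1] < 0.05


@pytest.fixture(scope="module")
def quick_cv(small_selected):
    cfg = fb.TrainingConfig(epochs=40, rules=6, seed=3)
    return fb.cross_validate(small_selected, cfg, folds=5, seed=3)


class TestCrossValidation:
    def test_every_window_tested_once(self, quick_cv, small_selected):
        assert quick_cv.confusion.sum() == small_selected.n_samples
        assert quick_cv.n_total == small_selected.n_samples

    def test_confusion_row_sums_match_class_sizes(self, quick_cv, small_selected):
        np.testing.assert_array_equal(
            quick_cv.confusion.sum(axis=1),
            np.bincount(small_selected.labels,
                        minlength=len(small_selected.class_names)),
        )

    def test_accuracy_consistent_with_confusion(self, quick_cv):
        diag = np.trace(quick_cv.confusion)
        assert quick_cv.n_correct == diag
        assert quick_cv.accuracy == pytest.approx(diag / quick_cv.n_total)

    def test_stratified_fold_sizes_balanced(self, small_selected):
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(5, shuffle=True, random_state=3)
        sizes = []
        for _, te in skf.split(small_selected.values, small_selected.labels):
            per_class = np.bincount(small_selected.labels[te], minlength=6)
            sizes.append(per_class)
        sizes = np.array(sizes)
        assert (sizes.max(axis=0) - sizes.min(axis=0) <= 1).all()

    def test_small_class_triggers_warning_and_fold_adjustment(self, small_selected):
        cfg = fb.TrainingConfig(epochs=1, rules=2, seed=0)
        with pytest.warns(SmallClassWarning):
            result = fb.cross_validate(small_selected, cfg, folds=25, seed=0)
        assert result.folds <= 9
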