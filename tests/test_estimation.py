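"""Estimation layer: scaling, surrogate forward pass, NLS, training corpus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from nanodox import (ConfigurationError, InputError, MLPSurrogate,
                     NLSTrajectoryEstimator, SurrogateModel, load_defaults,
                     make_training_set, minmax_scale, minmax_unscale,
                     mlp_predict, regularized_loss, rmse, train_surrogate)
from nanodox.estimation import TrainingSet, default_fit_grid


class TestMinMaxScaling:
    def test_bounds_map_to_unit_interval(self):
        lo, hi = np.array([0.0, 1.0]), np.array([2.0, 3.0])
        assert np.allclose(minmax_scale(lo, lo, hi), 0.0)
        assert np.allclose(minmax_scale(hi, lo, hi), 1.0)
        assert np.allclose(minmax_scale((lo + hi) / 2, lo, hi), 0.5)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            minmax_scale([1.0], [2.0], [2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(y=st.floats(-1e6, 1e6), lo=st.floats(-1e3, 0.0),
           width=st.floats(1e-3, 1e3))
    def test_scale_unscale_round_trip(self, y, lo, width):
        hi = lo + width
        back = minmax_unscale(minmax_scale(y, lo, hi), lo, hi)
        assert back == pytest.approx(y, abs=1e-12 * max(1.0, abs(y)))


def identity_bounds(n):
    return np.zeros(n), np.ones(n)


class TestMlpPredict:
    def net(self, w_in, b_in, w_out, b_out):
        m, n = np.atleast_2d(w_in).shape
        k = len(np.atleast_1d(b_out))
        xm, xM = identity_bounds(n)
        ym, yM = identity_bounds(k)
        return SurrogateModel(np.atleast_2d(w_in), np.atleast_1d(b_in),
                              np.atleast_2d(w_out), np.atleast_1d(b_out),
                              xm, xM, ym, yM)

    def test_zero_weights_output_is_bias_plus_half_output_weight(self):
        # hidden activation sigmoid(0)=0.5 everywhere
        net = self.net(np.zeros((3, 2)), np.zeros(3), np.zeros((1, 3)),
                       np.array([0.4]))
        assert mlp_predict(np.zeros(2), net)[0] == pytest.approx(0.4)

    def test_single_hidden_unit_hand_computation(self):
        # x=0.3 -> pre-act 1*0.3+0 -> sigmoid(0.3); out = 2*sig+0.1
        net = self.net([[1.0]], [0.0], [[2.0]], [0.1])
        sig = 1.0 / (1.0 + np.exp(-0.3))
        assert mlp_predict(np.array([0.3]), net)[0] == pytest.approx(
            2.0 * sig + 0.1, rel=1e-14)

    def test_matches_independent_matrix_forward_pass(self, rng):
        for _ in range(20):
            n, m, k = rng.integers(1, 6, size=3)
            w_in = rng.normal(size=(m, n))
            b_in = rng.normal(size=m)
            w_out = rng.normal(size=(k, m))
            b_out = rng.normal(size=k)
            x_min = rng.normal(size=n)
            x_max = x_min + rng.uniform(0.5, 2.0, size=n)
            y_min = rng.normal(size=k)
            y_max = y_min + rng.uniform(0.5, 2.0, size=k)
            net = SurrogateModel(w_in, b_in, w_out, b_out, x_min, x_max,
                                 y_min, y_max)
            x = rng.normal(size=n)
            # independent by-hand pass
            xs = (x - x_min) / (x_max - x_min)
            hidden = 1.0 / (1.0 + np.exp(-(w_in @ xs + b_in)))
            z = w_out @ hidden + b_out
            expected = y_min + z * (y_max - y_min)
            assert np.allclose(mlp_predict(x, net), expected, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        net = self.net([[1.0, 2.0]], [0.0], [[1.0]], [0.0])
        with pytest.raises(InputError):
            mlp_predict(np.zeros(3), net)

    def test_inconsistent_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            SurrogateModel(np.zeros((3, 2)), np.zeros(4), np.zeros((1, 3)),
                           np.zeros(1), *identity_bounds(2),
                           *identity_bounds(1))


class TestLossesAndMetrics:
    def test_perfect_prediction_zero_loss(self):
        assert regularized_loss([1, 2], [1, 2], [], 0.0) == 0.0

    def test_weight_penalty_only(self):
        assert regularized_loss([1.0], [1.0], [np.array([1.0, 1.0])],
                                0.5) == pytest.approx(1.0)

    def test_sse_term(self):
        assert regularized_loss([1, 2], [0, 0], [], 0.0) == pytest.approx(5.0)

    def test_rmse_examples(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([2.0], [0.0]) == 2.0

    def test_rmse_length_mismatch(self):
        with pytest.raises(InputError):
            rmse([1, 2], [1])


class TestNLSEstimator:
    def test_sklearn_protocol(self):
        est = NLSTrajectoryEstimator(model="forward", bound_factor=5.0)
        params = est.get_params()
        assert params["bound_factor"] == 5.0
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_start_at_optimum_converges_immediately(self, defaults):
        est = NLSTrajectoryEstimator(free=("k12", "omega0"), base=defaults,
                                     ode_rtol=1e-6, ode_atol=1e-8)
        grid = default_fit_grid(25, 800.0)
        prob = est._problem(grid, np.zeros_like(grid))
        from nanodox.estimation import make_simulator

        truth = np.array([defaults.get("k12"), defaults.get("omega0")])
        clean = make_simulator(prob)(truth)
        est.fit(grid, clean)
        assert est.result_.success
        assert est.result_.residual_norm < 1e-8

    def test_noiseless_recovery_from_perturbed_start(self, defaults):
        free = ("k12", "omega0")
        truth = np.array([defaults.get(n) for n in free])
        est0 = NLSTrajectoryEstimator(free=free, base=defaults,
                                      ode_rtol=1e-8, ode_atol=1e-10)
        grid = default_fit_grid(25, 800.0)
        from nanodox.estimation import make_simulator

        clean = make_simulator(est0._problem(grid, np.zeros_like(grid)))(truth)
        est = NLSTrajectoryEstimator(
            free=free, base=defaults, ode_rtol=1e-8, ode_atol=1e-10,
            x0={n: v * 1.8 for n, v in zip(free, truth)})
        est.fit(grid, clean)
        for name, tv in zip(free, truth):
            assert abs(est.params_[name] - tv) / tv < 1e-5

    def test_predict_reproduces_fitted_series(self, defaults):
        free = ("k12",)
        est = NLSTrajectoryEstimator(free=free, base=defaults, ode_rtol=1e-6,
                                     ode_atol=1e-8)
        grid = default_fit_grid(15, 500.0)
        from nanodox.estimation import make_simulator

        clean = make_simulator(est._problem(grid, np.zeros_like(grid)))(
            np.array([defaults.get("k12")]))
        est.fit(grid, clean)
        assert np.allclose(est.predict(grid), clean, atol=1e-8)

    def test_problem_validation(self, defaults):
        est = NLSTrajectoryEstimator(free=("k12", "k21", "k10", "omega0"),
                                     base=defaults)
        with pytest.raises(InputError):
            est._problem(np.array([0.0, 1.0]), np.array([0.0, 1.0]))  # M < n


class TestTrainingSet:
    def test_zero_noise_labels_match_truth(self, defaults):
        ds = make_training_set(2, noise_var=0.0, seed=3, base=defaults,
                               grid=default_fit_grid(25, 800.0),
                               ranges={"k12": (4.7e-3, 1.88e-2),
                                       "omega0": (0.35, 1.4)})
        rel = np.abs(ds.Y_fit - ds.Y_true) / ds.Y_true
        assert rel.max() < 1e-3

    def test_same_seed_reproduces_dataset(self, defaults):
        kwargs = dict(noise_var=0.05, seed=11, base=defaults,
                      grid=default_fit_grid(20, 600.0),
                      ranges={"omega0": (0.35, 1.4)})
        a = make_training_set(2, **kwargs)
        b = make_training_set(2, **kwargs)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.Y_fit, b.Y_fit)

    def test_disjoint_seeds_draw_distinct_parameters(self, defaults):
        kwargs = dict(noise_var=0.0, base=defaults,
                      grid=default_fit_grid(20, 600.0),
                      ranges={"omega0": (0.35, 1.4)})
        a = make_training_set(1, seed=1, **kwargs)
        b = make_training_set(1, seed=2, **kwargs)
        assert not np.array_equal(a.Y_true, b.Y_true)


def linear_map_training_set(n=120, seed=0):
    """Synthetic fixture: labels are an exact affine map of one feature."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, 5))
    y = 0.2 + 0.6 * X[:, 2]
    return TrainingSet(X=X, Y_true=y[:, None], Y_fit=y[:, None],
                       param_names=("s1",), ranges={"s1": (0.2, 0.8)},
                       t=np.arange(5.0), noise_var=0.0, seed=seed,
                       fit_times=np.zeros(n))


class TestSurrogate:
    def test_learns_exact_linear_map(self):
        ds = linear_map_training_set()
        net, report = train_surrogate(ds, hidden_units=10, lam=1e-4,
                                      seed=0)
        assert report["holdout_rmse_scaled"]["s1"] < 0.05

    def test_training_is_seed_deterministic(self):
        ds = linear_map_training_set()
        net1, _ = train_surrogate(ds, seed=4)
        net2, _ = train_surrogate(ds, seed=4)
        assert np.array_equal(net1.w_in, net2.w_in)
        assert np.array_equal(net1.w_out, net2.w_out)

    def test_huge_penalty_collapses_predictions_to_constant(self):
        ds = linear_map_training_set()
        net, _ = train_surrogate(ds, lam=1e6, seed=0)
        preds = mlp_predict(ds.X, net)
        assert np.std(preds) < 1e-3 * np.std(ds.Y_fit)

    def test_forward_pass_consistent_with_sklearn(self):
        from sklearn.neural_network import MLPRegressor

        ds = linear_map_training_set()
        est = MLPSurrogate(hidden_units=6, lam=1e-4, seed=1)
        est.fit(ds.X, ds.Y_fit)
        # rebuild the sklearn view of the same weights and compare
        reg = MLPRegressor(hidden_layer_sizes=(6,), activation="logistic",
                           solver="lbfgs", alpha=1e-4, random_state=1,
                           max_iter=2000, tol=1e-9)
        Xs = minmax_scale(ds.X, est.net_.x_min, est.net_.x_max)
        ys = minmax_scale(ds.Y_fit, est.net_.y_min, est.net_.y_max).ravel()
        reg.fit(Xs, ys)
        ours = est.predict(ds.X).ravel()
        theirs = minmax_unscale(reg.predict(Xs), est.net_.y_min[0],
                                est.net_.y_max[0])
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_degenerate_features_rejected(self):
        X = np.ones((10, 3))
        y = np.linspace(0, 1, 10)[:, None]
        with pytest.raises(ConfigurationError):
            MLPSurrogate().fit(X, y)

    def test_json_round_trip(self, tmp_path):
        ds = linear_map_training_set()
        net, _ = train_surrogate(ds, seed=0)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = SurrogateModel.from_json(path)
        assert np.array_equal(back.w_in, net.w_in)
        assert np.array_equal(back.y_max, net.y_max)
        x = ds.X[0]
        assert np.allclose(mlp_predict(x, back), mlp_predict(x, net))
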