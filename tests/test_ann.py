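"""Network core: forward pass, error, classic per-sample updates,
normalization and the fit/predict protocol."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pm25risk import ann


def random_params(n, l, m, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return ann.NetworkParams(
        rng.normal(scale=scale, size=(n, l)),
        rng.normal(scale=scale, size=(l, m)),
        rng.normal(scale=scale, size=l),
        rng.normal(scale=scale, size=m),
    )


def scalar_forward(params, x):
    """Independent loop-based oracle for the forward pass."""
    n, l, m = params.n_in, params.n_hidden, params.n_out
    H = np.zeros(l)
    for j in range(l):
        net = sum(params.w_in[i, j] * x[i] for i in range(n))
        net -= params.theta_hidden[j]
        H[j] = 1.0 / (1.0 + np.exp(-net))
    O = np.zeros(m)
    for k in range(m):
        O[k] = sum(H[j] * params.w_out[j, k] for j in range(l))
        O[k] -= params.theta_out[k]
    return H, O


class TestForward:
    def test_all_zero_parameters_give_half_activations_and_zero_output(self):
        p = ann.NetworkParams(np.zeros((3, 4)), np.zeros((4, 2)),
                              np.zeros(4), np.zeros(2))
        H, O = ann.forward(p, [1.0, -2.0, 0.5])
        np.testing.assert_array_equal(H, 0.5)
        np.testing.assert_array_equal(O, 0.0)

    def test_logistic_at_zero(self):
        p = ann.NetworkParams([[1.0]], [[1.0]], [0.0], [0.0])
        H, _ = ann.forward(p, [0.0])
        assert H[0] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, l, m = rng.integers(1, 5, size=3)
        p = random_params(n, l, m, seed)
        x = rng.normal(size=n)
        H, O = ann.forward(p, x)
        H2, O2 = scalar_forward(p, x)
        np.testing.assert_allclose(H, H2, atol=1e-12)
        np.testing.assert_allclose(O, O2, atol=1e-12)

    def test_hidden_activations_strictly_inside_unit_interval(self, rng):
        p = random_params(4, 9, 2, seed=7, scale=3.0)
        H, _ = ann.forward_batch(p, rng.normal(size=(50, 4)))
        assert np.all((H > 0) & (H < 1))

    def test_nonfinite_input_rejected(self):
        p = random_params(2, 3, 1)
        with pytest.raises(ValueError, match="finite"):
            ann.forward(p, [1.0, np.nan])

    def test_inconsistent_shapes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent shapes"):
            ann.NetworkParams(np.zeros((2, 3)), np.zeros((4, 1)),
                              np.zeros(3), np.zeros(1))


class TestOutputError:
    def test_perfect_prediction_gives_zero_error(self):
        assert np.all(ann.output_error([1.0, 2.0], [1.0, 2.0]) == 0.0)

    def test_direct_subtraction(self):
        assert ann.output_error([0.25], [1.0])[0] == 0.75

    def test_matches_loop_oracle(self, rng):
        O, Y = rng.normal(size=8), rng.normal(size=8)
        expected = np.array([Y[k] - O[k] for k in range(8)])
        np.testing.assert_array_equal(ann.output_error(O, Y), expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ann.output_error([1.0], [1.0, 2.0])


class TestGdStep:
    def test_zero_error_is_a_fixed_point(self):
        p = random_params(2, 3, 1, seed=1)
        x = np.array([0.3, -0.7])
        _, O = ann.forward(p, x)
        p2 = ann.gd_step(p, x, O, eta=0.5)
        for a, b in zip(
            (p.w_in, p.w_out, p.theta_hidden, p.theta_out),
            (p2.w_in, p2.w_out, p2.theta_hidden, p2.theta_out),
        ):
            np.testing.assert_array_equal(a, b)

    def test_output_weight_update_descends_the_numerical_gradient(self):
        """The w_out update has positive inner product with the negative
        finite-difference gradient of SSE/2 with respect to w_out."""
        p = random_params(3, 4, 2, seed=2)
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=3), rng.normal(size=2)
        p2 = ann.gd_step(p, x, y, eta=1e-3)
        dw = p2.w_out - p.w_out

        h = 1e-6
        g = np.zeros_like(p.w_out)
        for j in range(p.n_hidden):
            for k in range(p.n_out):
                for sgn in (+1, -1):
                    q = p.copy()
                    q.w_out[j, k] += sgn * h
                    _, O = ann.forward(q, x)
                    g[j, k] += sgn * 0.5 * np.sum((y - O) ** 2) / (2 * h)
        assert np.sum(dw * (-g)) > 0

    def test_sse_decreases_over_first_epochs_for_small_eta(self, rng):
        # uses the learning-rated output-threshold variant; the verbatim
        # rule (no learning rate on the output threshold) diverges
        X = rng.uniform(0.3, 1.0, size=(30, 3))
        y = 0.2 + 0.3 * X[:, 0] - 0.2 * X[:, 1] + 0.1 * X[:, 2]
        cfg = ann.TrainConfig(eta=1e-3, max_epochs=5, seed=1,
                              strict_bias_update=False, clip_nonneg=False)
        fr = ann.fit(X, y, cfg, optimizer="gd")
        assert all(a > b for a, b in zip(fr.trace, fr.trace[1:]))

    def test_verbatim_output_threshold_update_has_no_learning_rate(self):
        p = random_params(2, 3, 1, seed=4)
        x, y = np.array([0.1, 0.2]), np.array([5.0])
        _, O = ann.forward(p, x)
        e = y - O
        strict = ann.gd_step(p, x, y, eta=1e-4, strict_bias_update=True)
        scaled = ann.gd_step(p, x, y, eta=1e-4, strict_bias_update=False)
        np.testing.assert_allclose(strict.theta_out - p.theta_out, e)
        np.testing.assert_allclose(scaled.theta_out - p.theta_out, 1e-4 * e)


class TestGradient:
    @pytest.mark.parametrize("seed", range(6))
    def test_analytic_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        n, l, m = rng.integers(1, 5, size=3)
        p = random_params(n, l, m, seed, scale=0.8)
        X = rng.normal(size=(7, n))
        Y = rng.normal(size=(7, m))
        _, g = ann.sse_and_gradient(p, X, Y)
        z = ann.pack(p)
        h = 1e-6
        for i in range(len(z)):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fp = ann.sse_and_gradient(ann.unpack(zp, n, l, m), X, Y)[0] / 2
            fm = ann.sse_and_gradient(ann.unpack(zm, n, l, m), X, Y)[0] / 2
            fd = (fp - fm) / (2 * h)
            assert abs(g[i] - fd) <= 1e-5 * max(abs(fd), 1e-3)

    def test_jacobian_consistent_with_gradient(self, rng):
        p = random_params(3, 5, 2, seed=11)
        X, Y = rng.normal(size=(9, 3)), rng.normal(size=(9, 2))
        _, g = ann.sse_and_gradient(p, X, Y)
        r, J = ann.residuals_and_jacobian(p, X, Y)
        np.testing.assert_allclose(-J.T @ r, -g, atol=1e-12)

    def test_pack_unpack_round_trip(self):
        p = random_params(3, 4, 2, seed=5)
        q = ann.unpack(ann.pack(p), 3, 4, 2)
        np.testing.assert_array_equal(ann.pack(p), ann.pack(q))


class TestNormalizer:
    def test_round_trip(self, rng):
        X = rng.normal(size=(20, 4)) * [1, 10, 100, 0.1]
        nz = ann.Normalizer(lo=0.1, hi=0.9).fit(X)
        np.testing.assert_allclose(nz.inverse(nz.transform(X)), X, atol=1e-12)

    def test_degenerate_feature_dropped_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            nz = ann.Normalizer().fit(X)
        assert nz.dropped == [1]
        assert nz.transform(X).shape == (5, 1)


class TestFit:
    def test_recovers_noise_free_linear_function(self, rng):
        X = rng.uniform(size=(120, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        cfg = ann.TrainConfig(max_epochs=100, seed=0, n_hidden=4,
                              clip_nonneg=False)
        fr = ann.fit(X, y, cfg, optimizer="trainlm")
        resid = fr.y_norm.transform(ann.predict(fr, X)[:, None]) \
            - fr.y_norm.transform(y[:, None])
        assert np.sqrt(np.mean(resid ** 2)) < 1e-2

    def test_identical_seed_gives_identical_trace(self, rng):
        X = rng.uniform(size=(50, 3))
        y = X @ [1.0, -1.0, 0.5]
        cfg = ann.TrainConfig(max_epochs=20, seed=3, clip_nonneg=False)
        t1 = ann.fit(X, y, cfg, optimizer="trainrp").trace
        t2 = ann.fit(X, y, cfg, optimizer="trainrp").trace
        assert t1 == t2

    def test_infinite_tol_stops_after_one_epoch(self, rng):
        X = rng.uniform(size=(30, 2))
        y = X.sum(axis=1)
        cfg = ann.TrainConfig(max_epochs=50, tol=np.inf, seed=0)
        for algo in ("gd", "trainrp", "trainlm"):
            fr = ann.fit(X, y, cfg, optimizer=algo)
            assert len(fr.trace) == 1, algo

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            ann.fit(X, np.array([1.0]), ann.TrainConfig())

    def test_unknown_optimizer_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown optimizer"):
            ann.fit(rng.uniform(size=(5, 2)), np.arange(5.0),
                    ann.TrainConfig(), optimizer="adam")


class TestPredict:
    @pytest.fixture()
    def fitted(self, rng):
        X = rng.uniform(10, 50, size=(80, 3))
        y = 5.0 + X[:, 0] - 0.5 * X[:, 1] + 0.1 * X[:, 2]
        cfg = ann.TrainConfig(max_epochs=60, seed=1, clip_nonneg=False)
        return X, y, ann.fit(X, y, cfg, optimizer="trainlm")

    def test_training_row_prediction_equals_fitted_value(self, fitted):
        X, y, fr = fitted
        full = ann.predict(fr, X)
        one = ann.predict_ptpt(fr, X[5:6])
        assert one[0] == pytest.approx(full[5], abs=1e-12)

    def test_constant_future_block_gives_constant_prediction(self, fitted):
        X, _, fr = fitted
        P = np.tile(X[3], (7, 1))
        pred = ann.predict_ptpt(fr, P)
        assert np.ptp(pred) == 0.0

    def test_wrong_feature_count_rejected(self, fitted):
        _, _, fr = fitted
        with pytest.raises(ValueError, match="feature columns"):
            ann.predict_ptpt(fr, np.ones((2, 5)))

    def test_concentration_predictions_clipped_nonnegative(self, rng):
        X = rng.uniform(size=(60, 2))
        y = X[:, 0] - X[:, 1]  # straddles zero
        fr = ann.fit(X, y, ann.TrainConfig(max_epochs=40, seed=0),
                     optimizer="trainlm")
        wild = rng.uniform(-2, 3, size=(40, 2))
        assert np.all(ann.predict(fr, wild) >= 0.0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=1, max_size=6))
def test_forward_hidden_layer_bounded_property(xs):
    p = random_params(len(xs), 3, 1, seed=0)
    H, _ = ann.forward(p, np.asarray(xs))
    assert np.all((H > 0.0) & (H < 1.0))
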