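import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from caehar import nn_core as nc


def det_act(**kw):
    kw.setdefault("sigma", 0.0)
    return nc.ActivationConfig(**kw)


class TestImprovedSigmoid:
    def test_zero_maps_to_zero(self):
        assert nc.improved_sigmoid(0.0, det_act()) == 0.0

    def test_closed_form_ln3(self):
        # 2 * (expit(ln 3) - 0.5) = 2 * (0.75 - 0.5) = 0.5
        got = nc.improved_sigmoid(np.log(3.0), det_act(k=2.0))
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_saturation(self):
        assert abs(nc.improved_sigmoid(40.0, det_act()) - 0.5) < 1e-12

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            nc.improved_sigmoid(np.nan, det_act())
        with pytest.raises(ValueError):
            nc.improved_sigmoid(np.inf, det_act())

    @given(a=st.floats(-1e6, 1e6), k=st.floats(0.1, 10), c=st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None)
    def test_range_bound(self, a, k, c):
        v = nc.improved_sigmoid(a, det_act(k=k, c=c))
        assert -0.5 * k < v < 0.5 * k

    @given(a=st.floats(-100, 100), k=st.floats(0.1, 10), c=st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None)
    def test_odd_symmetry(self, a, k, c):
        act = det_act(k=k, c=c)
        assert nc.improved_sigmoid(-a, act) == -nc.improved_sigmoid(a, act)

    def test_elementwise_on_vectors(self):
        a = np.array([-1.0, 0.0, 2.0])
        act = det_act(k=2.0, c=0.5)
        out = nc.improved_sigmoid(a, act)
        assert out.shape == a.shape
        for i in range(3):
            assert out[i] == nc.improved_sigmoid(a[i], act)

    def test_invalid_config_rejected(self):
        for kw in ({"k": 0.0}, {"c": -1.0}, {"sigma": -0.1}):
            with pytest.raises(ValueError):
                nc.ActivationConfig(**kw)


class TestTaylorReference:
    def test_odd_series_is_zero_at_zero(self):
        assert nc.taylor_reference(0.0, det_act(k=3, c=7), order=5) == 0.0

    def test_first_order_hand_value(self):
        # 3 * (2 * 0.2) / 4 = 0.3
        got = nc.taylor_reference(0.2, det_act(k=3.0, c=2.0), order=1)
        assert got == pytest.approx(0.3, abs=1e-15)

    def test_matches_sigmoid_near_zero(self):
        act = det_act()
        got = nc.taylor_reference(0.1, act, order=5)
        assert got == pytest.approx(nc.improved_sigmoid(0.1, act), abs=1e-8)

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            nc.taylor_reference(0.1, det_act(), order=2)

    @given(a=st.floats(-0.1, 0.1))
    @settings(max_examples=200, deadline=None)
    def test_agreement_property(self, a):
        act = det_act()
        err = abs(nc.improved_sigmoid(a, act) - nc.taylor_reference(a, act, 5))
        assert err <= 1e-6


class TestNoisyPreactivation:
    def test_zero_sigma_exact(self, rng):
        W = rng.random((3, 2))
        x = rng.random(2)
        b = rng.random(3)
        out = nc.noisy_preactivation(W, x, b, det_act(), rng)
        np.testing.assert_array_equal(out, W @ x + b)

    def test_identity(self):
        out = nc.noisy_preactivation(np.eye(2), np.array([1.0, 2.0]),
                                     np.zeros(2), det_act())
        np.testing.assert_array_equal(out, [1.0, 2.0])

    def test_noise_moments(self):
        act = nc.ActivationConfig(sigma=1.0, train_mode=True)
        rng = np.random.default_rng(2024)
        W = np.zeros((100_000, 1))
        draws = nc.noisy_preactivation(W, np.zeros(1), np.zeros(100_000),
                                       act, rng)
        assert abs(draws.mean()) < 3 * 10 ** -2.5
        assert abs(draws.std() - 1.0) < 0.01

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            nc.noisy_preactivation(np.eye(2), np.zeros(3), np.zeros(2), det_act())

    def test_eval_mode_ignores_sigma(self):
        act = nc.ActivationConfig(sigma=5.0, train_mode=False)
        W = np.ones((2, 2))
        out = nc.noisy_preactivation(W, np.ones(2), np.zeros(2), act)
        np.testing.assert_array_equal(out, [2.0, 2.0])


class TestEncodeDecode:
    def test_zero_params_zero_output(self):
        p = nc.CAEParams(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)),
                         np.zeros(3), det_act())
        np.testing.assert_array_equal(nc.encode(np.ones(3), p), np.zeros(2))
        np.testing.assert_array_equal(nc.reconstruct(np.ones(3), p), np.zeros(3))

    def test_shape_contract(self, rng):
        p = nc.init_params(5, 3, det_act(), seed=1)
        assert nc.encode(rng.random(5), p).shape == (3,)
        assert nc.decode(rng.random(3), p).shape == (5,)

    def test_batch_matches_single(self, rng):
        p = nc.init_params(4, 2, det_act(), seed=3)
        X = rng.random((6, 4))
        H = nc.encode(X, p)
        for i in range(6):
            np.testing.assert_allclose(H[i], nc.encode(X[i], p), rtol=1e-12)

    def test_plain_sigmoid_matches_basic_autoencoder(self, rng):
        """Compatibility mode must agree bitwise with a hand-rolled basic AE."""
        act = det_act(plain_sigmoid=True)
        p = nc.init_params(4, 3, act, seed=11)
        x = rng.random(4)
        ref_h = expit(p.W_enc @ x + p.b_enc)
        ref_r = expit(p.W_dec @ ref_h + p.b_dec)
        np.testing.assert_array_equal(nc.encode(x, p), ref_h)
        np.testing.assert_array_equal(nc.reconstruct(x, p), ref_r)

    def test_reduction_is_shifted_sigmoid(self, rng):
        a = rng.standard_normal(10)
        got = nc.improved_sigmoid(a, det_act())
        np.testing.assert_allclose(got, expit(a) - 0.5, atol=1e-15)


class TestLosses:
    def test_perfect_reconstruction_zero(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=4)
        x = rng.random(3)
        y = nc.reconstruct(x, p)
        assert nc.sample_loss(x, y, p) == 0.0

    def test_sample_loss_formula(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=4)
        x, y = rng.random(3), rng.random(3)
        expected = 0.5 * np.sum((nc.reconstruct(x, p) - y) ** 2)
        assert nc.sample_loss(x, y, p) == pytest.approx(expected, rel=1e-15)
        assert nc.sample_loss(x, y, p) >= 0.0

    def test_length_mismatch(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=4)
        with pytest.raises(ValueError):
            nc.sample_loss(rng.random(4), rng.random(4), p)

    def test_total_loss_zero_lambda_is_mean(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=4)
        X, Y = rng.random((5, 3)), rng.random((5, 3))
        per = [nc.sample_loss(X[i], Y[i], p) for i in range(5)]
        got = nc.total_loss(X, Y, p, nc.LossConfig(0.0))
        assert got == pytest.approx(np.mean(per), rel=1e-12)

    def test_decay_term_exact(self, rng):
        # lambda=2 with 4 unit weights adds (2/2)*4 = 4 to the data loss
        p = nc.CAEParams(np.ones((1, 2)), np.zeros(1), np.ones((2, 1)),
                         np.zeros(2), det_act())
        X = rng.random((3, 2))
        base = nc.total_loss(X, X, p, nc.LossConfig(0.0))
        with_decay = nc.total_loss(X, X, p, nc.LossConfig(2.0))
        assert with_decay - base == pytest.approx(4.0, abs=1e-12)

    def test_monotone_in_lambda(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=4)
        X = rng.random((4, 3))
        losses = [nc.total_loss(X, X, p, nc.LossConfig(lam))
                  for lam in (0.0, 0.1, 1.0)]
        assert losses == sorted(losses)

    def test_empty_batch_rejected(self):
        p = nc.init_params(3, 2, det_act(), seed=4)
        with pytest.raises(ValueError):
            nc.total_loss(np.empty((0, 3)), np.empty((0, 3)), p, nc.LossConfig())


def finite_difference_grads(X, Y, p, lc, eps=1e-5):
    fd = []
    for arr in p.arrays():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + eps
            lp = nc.total_loss(X, Y, p, lc)
            arr[i] = old - eps
            lm = nc.total_loss(X, Y, p, lc)
            arr[i] = old
            g[i] = (lp - lm) / (2 * eps)
        fd.append(g)
    return fd


class TestGradients:
    @pytest.mark.parametrize("trial", range(20))
    def test_finite_difference_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        v, h = int(rng.integers(2, 5)), int(rng.integers(1, 4))
        act = det_act(k=float(rng.uniform(0.5, 2)), c=float(rng.uniform(0.5, 2)))
        p = nc.init_params(v, h, act, seed=int(rng.integers(1e6)))
        lc = nc.LossConfig(float(rng.uniform(0, 1e-2)))
        X = rng.random((3, v))
        Y = rng.random((3, v)) - 0.5
        analytic = nc.gradients(X, Y, p, lc).arrays()
        fd = finite_difference_grads(X, Y, p, lc)
        for a, f in zip(analytic, fd):
            denom = np.maximum(np.abs(f), 1e-6)
            assert np.max(np.abs(a - f) / denom) < 1e-5

    def test_decay_part_is_lambda_w(self, rng):
        p = nc.init_params(3, 2, det_act(), seed=7)
        X = rng.random((4, 3))
        Y = rng.random((4, 3)) - 0.5
        g0 = nc.gradients(X, Y, p, nc.LossConfig(0.0))
        g1 = nc.gradients(X, Y, p, nc.LossConfig(0.5))
        np.testing.assert_allclose(g1.W_enc - g0.W_enc, 0.5 * p.W_enc,
                                   atol=1e-15)
        np.testing.assert_allclose(g1.W_dec - g0.W_dec, 0.5 * p.W_dec,
                                   atol=1e-15)
        np.testing.assert_array_equal(g1.b_enc, g0.b_enc)

    def test_gradient_small_at_fitted_minimum(self):
        # train a tiny CAE to (near) convergence, then check the gradient
        from caehar import optim

        rng = np.random.default_rng(0)
        X = rng.random((20, 2)) * 0.2 - 0.1
        cae = nc.CAE.new(2, 4, det_act(), nc.LossConfig(0.0), seed=1)
        cfg = optim.FSGDConfig(n=400, alpha=0.3, epsilon=1e-12, K=1, seed=2)
        optim.sgd_train(cae, X, cfg=cfg)
        g = nc.gradients(X, X, cae.params, cae.loss_cfg)
        norm = np.sqrt(sum(float(np.sum(a ** 2)) for a in g.arrays()))
        assert norm < 1e-3  # flat region around the fitted optimum

    def test_noise_reused_between_passes(self):
        # gradient with sigma>0 must be the exact gradient of the noisy
        # forward pass: check against finite differences with frozen noise
        act = nc.ActivationConfig(sigma=0.3, train_mode=True)
        p = nc.init_params(3, 2, act, seed=9)
        rng = np.random.default_rng(42)
        X = rng.random((2, 3))
        g = nc.gradients(X, X, p, nc.LossConfig(0.0),
                         np.random.default_rng(7))
        assert all(np.all(np.isfinite(a)) for a in g.arrays())


class TestInitParams:
    def test_reproducible(self):
        a = nc.init_params(4, 3, det_act(), seed=5)
        b = nc.init_params(4, 3, det_act(), seed=5)
        for x, y in zip(a.arrays(), b.arrays()):
            np.testing.assert_array_equal(x, y)

    def test_bound(self):
        p = nc.init_params(4, 3, det_act(), seed=5)
        r = np.sqrt(6.0 / 7.0)
        assert np.all(np.abs(p.W_enc) < r)
        assert np.all(np.abs(p.W_dec) < r)
        assert np.all(p.b_enc == 0) and np.all(p.b_dec == 0)

    def test_seeds_differ(self):
        a = nc.init_params(4, 3, det_act(), seed=5)
        b = nc.init_params(4, 3, det_act(), seed=6)
        assert not np.array_equal(a.W_enc, b.W_enc)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            nc.init_params(0, 3)


class TestTargetMapping:
    @given(y=st.floats(0, 1), k=st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, y, k):
        act = det_act(k=k)
        back = nc.from_activation_range(nc.to_activation_range(y, act), act)
        assert back == pytest.approx(y, abs=1e-12)

    def test_range_endpoints(self):
        act = det_act(k=2.0)
        assert nc.to_activation_range(0.0, act) == -1.0
        assert nc.to_activation_range(1.0, act) == 1.0
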