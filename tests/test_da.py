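import numpy as np
import pytest

from dasurv.da import (
    OneInputDA,
    TrainConfig,
    TwoInputDA,
    bce_loss,
    corrupt,
    sigmoid,
    train_one_input,
    train_two_input,
)
from dasurv.preprocess import ScaledMatrix
import pandas as pd

from .oracles import bce_by_loop


def _scaled(rng, g, p, tag="expression"):
    vals = rng.random((g, p))
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(g)],
                      columns=[f"p{i}" for i in range(p)])
    return ScaledMatrix(df, tag)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry(self):
        assert sigmoid(-3.7) == pytest.approx(1 - sigmoid(3.7), abs=1e-12)

    def test_stable_at_extremes(self):
        out = sigmoid(np.array([-50.0, 50.0, -500.0, 500.0]))
        assert (out > 0).all() and (out < 1).all()
        assert np.isfinite(out).all()


class TestCorrupt:
    def test_zero_noise_is_identity(self):
        x = np.random.default_rng(0).random((10, 4))
        out, mask = corrupt(x, 0.0, 1)
        np.testing.assert_array_equal(out, x)
        assert not mask.any()

    def test_quarter_of_eight_genes_is_two_per_patient(self):
        x = np.ones((8, 5))
        out, mask = corrupt(x, 0.25, 3)
        np.testing.assert_array_equal(mask.sum(axis=0), 2)
        assert (out[mask] == 0).all()

    def test_total_masked_fraction_exact(self):
        x = np.ones((1000, 50))
        _, mask = corrupt(x, 0.25, 7)
        assert mask.mean() == 0.25

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(1).random((40, 6))
        a, ma = corrupt(x, 0.3, 99)
        b, mb = corrupt(x, 0.3, 99)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ma, mb)

    def test_row_mode_zeroes_whole_genes(self):
        x = np.ones((12, 5))
        _, mask = corrupt(x, 0.25, 2, rows=True)
        per_gene = mask.sum(axis=1)
        assert set(per_gene) <= {0, 5} and (per_gene == 5).sum() == 3

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            corrupt(np.ones((4, 2)), 1.0, 0)


class TestBCE:
    def test_perfect_binary_reconstruction_is_zero(self):
        t = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(t, np.clip(t, 1e-12, 1 - 1e-12)) == pytest.approx(0, abs=1e-10)

    def test_half_half_is_log_two(self):
        assert bce_loss(np.full(6, 0.5), np.full(6, 0.5)) == pytest.approx(np.log(2))

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(3)
        t, o = rng.random(10), rng.uniform(0.01, 0.99, 10)
        assert bce_loss(t, o) == pytest.approx(bce_by_loop(t, o), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.ones(3), np.ones(4) * 0.5)


class TestForwardOne:
    def test_zero_parameters_give_half_everywhere(self):
        m = OneInputDA(6, 3, seed=0)
        m.W[:] = 0
        h, r = m.forward(np.random.default_rng(0).random(6))
        np.testing.assert_allclose(h, 0.5)
        np.testing.assert_allclose(r, 0.5)

    def test_inference_mode_deterministic(self):
        m = OneInputDA(5, 2, seed=1)
        x = np.random.default_rng(1).random(5)
        h1, r1 = m.forward(x)
        h2, r2 = m.forward(x)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(r1, r2)

    def test_matches_hand_matrix_arithmetic(self):
        m = OneInputDA(3, 2, seed=0)
        m.W = np.array([[0.5, -0.2], [0.1, 0.3], [-0.4, 0.2]])
        m.b = np.array([0.1, -0.1])
        m.b_dec = np.array([0.0, 0.2, -0.2])
        x = np.array([0.2, 0.8, 0.5])
        h_exp = 1 / (1 + np.exp(-(m.W.T @ x + m.b)))
        r_exp = 1 / (1 + np.exp(-(m.W @ h_exp + m.b_dec)))
        h, r = m.forward(x)
        np.testing.assert_allclose(h.ravel(), h_exp, rtol=1e-12)
        np.testing.assert_allclose(r.ravel(), r_exp, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            OneInputDA(4, 2).forward(np.ones(5))

    def test_tied_weights_parameter_count(self):
        g, h = 7, 3
        m = OneInputDA(g, h)
        untied = 2 * g * h + h + g  # separate decode matrix would add g*h
        assert m.n_params() == g * h + h + g == untied - g * h


class TestForwardTwo:
    def test_zero_parameters_give_half_everywhere(self):
        m = TwoInputDA(4, 4, hidden1=2, hidden2=2, seed=0)
        for name in ("W1_a", "W1_b", "W2"):
            getattr(m, name)[:] = 0
        e, ra, rb = m.forward(np.ones(4) * 0.3, np.ones(4) * 0.6)
        for arr in (e, ra, rb):
            np.testing.assert_allclose(arr, 0.5)

    def test_swapping_sources_and_weights_swaps_reconstructions(self):
        rng = np.random.default_rng(5)
        m = TwoInputDA(4, 4, hidden1=3, hidden2=2, seed=2)
        xa, xb = rng.random(4), rng.random(4)
        e1, ra1, rb1 = m.forward(xa, xb)
        # swap the two sources' roles
        m.W1_a, m.W1_b = m.W1_b.copy(), m.W1_a.copy()
        m.b1_a, m.b1_b = m.b1_b.copy(), m.b1_a.copy()
        m.b_dec_a, m.b_dec_b = m.b_dec_b.copy(), m.b_dec_a.copy()
        m.W2 = np.vstack([m.W2[3:], m.W2[:3]])
        m.b_dec_mid = np.concatenate([m.b_dec_mid[3:], m.b_dec_mid[:3]])
        e2, ra2, rb2 = m.forward(xb, xa)
        np.testing.assert_allclose(e1, e2, rtol=1e-12)
        np.testing.assert_allclose(ra1, rb2, rtol=1e-12)
        np.testing.assert_allclose(rb1, ra2, rtol=1e-12)

    def test_matches_hand_computed_chain(self):
        m = TwoInputDA(4, 4, hidden1=2, hidden2=2, seed=3)
        rng = np.random.default_rng(4)
        xa, xb = rng.random(4), rng.random(4)
        s = lambda v: 1 / (1 + np.exp(-v))
        ha = s(m.W1_a.T @ xa + m.b1_a)
        hb = s(m.W1_b.T @ xb + m.b1_b)
        cc = np.concatenate([ha, hb])
        e = s(m.W2.T @ cc + m.b2)
        mid = s(m.W2 @ e + m.b_dec_mid)
        ra = s(m.W1_a @ mid[:2] + m.b_dec_a)
        rb = s(m.W1_b @ mid[2:] + m.b_dec_b)
        e_got, ra_got, rb_got = m.forward(xa, xb)
        np.testing.assert_allclose(e_got.ravel(), e, rtol=1e-12)
        np.testing.assert_allclose(ra_got.ravel(), ra, rtol=1e-12)
        np.testing.assert_allclose(rb_got.ravel(), rb, rtol=1e-12)


class TestTraining:
    def test_zero_epochs_returns_initialized_features(self):
        rng = np.random.default_rng(0)
        sm = _scaled(rng, 20, 10)
        model, hist, feats = train_one_input(sm, TrainConfig(epochs=0, seed=1), n_features=5)
        assert hist == []
        assert feats.activity.shape == (10, 5)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(1)
        sm = _scaled(rng, 30, 12)
        cfg = TrainConfig(epochs=4, batch_size=5, seed=77)
        _, h1, f1 = train_one_input(sm, cfg, n_features=6)
        _, h2, f2 = train_one_input(sm, cfg, n_features=6)
        assert h1 == h2
        np.testing.assert_array_equal(f1.activity.to_numpy(), f2.activity.to_numpy())

    def test_loss_descends_on_structured_data(self, scaled_pair):
        se, _, _ = scaled_pair
        _, hist, _ = train_one_input(se, TrainConfig(epochs=8, seed=3), n_features=20)
        assert hist[-1] < hist[0]

    def test_two_input_loss_descends(self, scaled_pair):
        se, sc, _ = scaled_pair
        _, hist, _ = train_two_input(se, sc, TrainConfig(epochs=6, seed=3),
                                     hidden1=30, hidden2=10)
        assert hist[-1] < hist[0]

    def test_activity_strictly_inside_unit_interval(self, trained_one):
        _, _, feats = trained_one
        vals = feats.activity.to_numpy()
        assert (vals > 0).all() and (vals < 1).all()
        assert feats.activity.shape[1] == 100

    def test_noiseless_dropout_free_config_reaches_lower_loss(self):
        rng = np.random.default_rng(9)
        sm = _scaled(rng, 40, 30)
        noisy = TrainConfig(epochs=15, seed=4)
        plain = TrainConfig(epochs=15, seed=4, noise_factor=0.0, dropout_rate=0.0)
        _, h_noisy, _ = train_one_input(sm, noisy, n_features=8)
        _, h_plain, _ = train_one_input(sm, plain, n_features=8)
        assert h_plain[-1] <= h_noisy[-1]

    def test_mismatched_patients_rejected(self):
        rng = np.random.default_rng(2)
        a, b = _scaled(rng, 10, 8), _scaled(rng, 10, 8)
        b.values.columns = [f"q{i}" for i in range(8)]
        with pytest.raises(ValueError):
            train_two_input(a, b, TrainConfig(epochs=1))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(noise_factor=1.5).validate()
        with pytest.raises(ValueError):
            TrainConfig(dropout_rate=1.0).validate()


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Exact backprop through encode/dropout/decode vs central differences."""
        rng = np.random.default_rng(12)
        G, H, B = 5, 3, 4
        m = OneInputDA(G, H, seed=2)
        x = rng.random((B, G))
        xn, _ = corrupt(x.T, 0.25, 5)
        xn = xn.T
        _, grads = m.loss_and_grads(x, xn)

        def loss_at(W, b, b_dec):
            probe = OneInputDA(G, H)
            probe.W, probe.b, probe.b_dec = W, b, b_dec
            _, recon = probe.forward(xn)
            return bce_loss(x, recon)

        eps = 1e-6
        for name, arr in (("W", m.W), ("b", m.b), ("b_dec", m.b_dec)):
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                hi = {k: getattr(m, k).copy() for k in ("W", "b", "b_dec")}
                lo = {k: getattr(m, k).copy() for k in ("W", "b", "b_dec")}
                hi[name][idx] += eps
                lo[name][idx] -= eps
                num[idx] = (loss_at(**hi) - loss_at(**lo)) / (2 * eps)
            rel = np.abs(grads[name] - num) / (np.abs(num) + 1e-10)
            assert rel.max() < 1e-5
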