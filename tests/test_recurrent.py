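"""Recurrent-cell tests: each step function is checked against an
independently coded transcription of its equations, and the BPTT gradients
against central finite differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquilens.recurrent import (SequenceClassifier, bilstm_forward,
                                featurize_sequence, gru_step, lstm_step,
                                make_cell_spec, rnn_step)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_rnn(x, h, w):
    h_t = sigmoid(w["P_h"] @ h + w["P_x"] @ x + w["B_a"])
    return h_t, np.tanh(w["P_o"] @ h_t + w["B_o"])


def oracle_gru(x, h, w):
    r = sigmoid(w["W_r"] @ x + w["U_r"] @ h + w["b_r"])
    z = sigmoid(w["W_z"] @ x + w["U_z"] @ h + w["b_z"])
    cand = np.tanh(w["W_h"] @ x + w["U_h"] @ (r * h) + w["b_h"])
    return (1 - z) * h + z * cand


def oracle_bilstm(seq, spec):
    """Two explicit passes + per-step combination, coded independently."""
    w = spec.weights
    H = spec.hidden_units
    T = len(seq)

    def scan(idx_order, prefix):
        h = np.zeros(H)
        c = np.zeros(H)
        out = {}
        for t in idx_order:
            i = sigmoid(w[f"{prefix}W_i"] @ seq[t] + w[f"{prefix}U_i"] @ h
                        + w[f"{prefix}b_i"])
            f = sigmoid(w[f"{prefix}W_f"] @ seq[t] + w[f"{prefix}U_f"] @ h
                        + w[f"{prefix}b_f"])
            o = sigmoid(w[f"{prefix}W_o"] @ seq[t] + w[f"{prefix}U_o"] @ h
                        + w[f"{prefix}b_o"])
            g = np.tanh(w[f"{prefix}W_g"] @ seq[t] + w[f"{prefix}U_g"] @ h
                        + w[f"{prefix}b_g"])
            c = f * c + i * g
            h = o * np.tanh(c)
            out[t] = h
        return out

    fwd = scan(range(T), "f_")
    bwd = scan(range(T - 1, -1, -1), "b_")
    return np.stack([np.tanh(w["w4"] @ fwd[t] + w["w6"] @ bwd[t] + w["b_y"])
                     for t in range(T)])


class TestFeaturize:
    def test_even_reshape(self):
        seq, pad = featurize_sequence(np.arange(128.0), 8)
        assert seq.shape == (8, 16) and pad == 0
        np.testing.assert_array_equal(seq.ravel(), np.arange(128.0))

    def test_single_step_equals_vector(self):
        v = np.arange(5.0)
        seq, pad = featurize_sequence(v, 1)
        assert pad == 0
        np.testing.assert_array_equal(seq[0], v)

    @settings(derandomize=True, max_examples=60)
    @given(n=st.integers(1, 200), timesteps=st.integers(1, 16))
    def test_property_flatten_inverts_reshape(self, n, timesteps):
        v = np.arange(float(n))
        seq, pad = featurize_sequence(v, timesteps)
        assert seq.shape[0] == timesteps
        assert seq.size == n + pad and pad < timesteps
        np.testing.assert_array_equal(seq.ravel()[:n], v)

    def test_padding_recorded_and_invertible(self):
        v = np.arange(130.0)
        seq, pad = featurize_sequence(v, 8)
        assert seq.shape == (8, 17) and pad == 6
        np.testing.assert_array_equal(seq.ravel()[:130], v)
        assert (seq.ravel()[130:] == 0).all()


class TestElman:
    def test_zero_weights_closed_form(self):
        spec = make_cell_spec("elman", 3, 4, seed=0, output_dim=2)
        for k in spec.weights:
            spec.weights[k] = np.zeros_like(spec.weights[k])
        h, y = rnn_step(np.ones(3), np.zeros(4), spec)
        np.testing.assert_allclose(h, 0.5)
        np.testing.assert_allclose(y, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = make_cell_spec("elman", 3, 2, seed=seed)
        for k in spec.weights:
            spec.weights[k] = rng.normal(size=spec.weights[k].shape)
        x, h0 = rng.normal(size=3), rng.normal(size=2)
        got_h, got_y = rnn_step(x, h0, spec)
        want_h, want_y = oracle_rnn(x, h0, spec.weights)
        np.testing.assert_allclose(got_h, want_h, rtol=1e-12)
        np.testing.assert_allclose(got_y, want_y, rtol=1e-12)

    def test_hidden_state_bounded_by_sigmoid(self):
        rng = np.random.default_rng(1)
        spec = make_cell_spec("elman", 4, 6, seed=1)
        h = rng.normal(size=6)
        for _ in range(5):
            h, _ = rnn_step(rng.normal(size=4) * 10, h, spec)
            assert ((h > 0) & (h < 1)).all()


class TestGRU:
    def test_update_gate_endpoints(self):
        spec = make_cell_spec("gru", 2, 3, seed=0)
        h_prev = np.array([0.3, -0.2, 0.7])
        x = np.ones(2)
        spec.weights["W_z"][:] = 0
        spec.weights["U_z"][:] = 0
        spec.weights["b_z"][:] = -50.0  # z → 0: state carried through
        np.testing.assert_allclose(gru_step(x, h_prev, spec), h_prev,
                                   atol=1e-12)
        spec.weights["b_z"][:] = 50.0  # z → 1: state replaced by candidate
        w = spec.weights
        r = sigmoid(w["W_r"] @ x + w["U_r"] @ h_prev + w["b_r"])
        cand = np.tanh(w["W_h"] @ x + w["U_h"] @ (r * h_prev) + w["b_h"])
        np.testing.assert_allclose(gru_step(x, h_prev, spec), cand, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        spec = make_cell_spec("gru", 4, 3, seed=seed)
        for k in spec.weights:
            spec.weights[k] = rng.normal(size=spec.weights[k].shape)
        x, h0 = rng.normal(size=4), rng.normal(size=3)
        np.testing.assert_allclose(gru_step(x, h0, spec),
                                   oracle_gru(x, h0, spec.weights),
                                   rtol=1e-12)


class TestBiLSTM:
    def test_empty_sequence_empty_output(self):
        spec = make_cell_spec("bilstm", 3, 4, seed=0)
        out = bilstm_forward(np.empty((0, 3)), spec)
        assert out.shape[0] == 0

    def test_length_one_directions_see_same_step(self):
        spec = make_cell_spec("bilstm", 3, 4, seed=1)
        # tie backward weights to forward so both directions compute the same
        for k in list(spec.weights):
            if k.startswith("f_"):
                spec.weights["b_" + k[2:]] = spec.weights[k].copy()
        x = np.random.default_rng(2).normal(size=(1, 3))
        h1, c1 = lstm_step(x[0], np.zeros(4), np.zeros(4), spec.weights, "f_")
        w = spec.weights
        want = np.tanh(w["w4"] @ h1 + w["w6"] @ h1 + w["b_y"])
        np.testing.assert_allclose(bilstm_forward(x, spec)[0], want,
                                   rtol=1e-12)

    def test_palindrome_symmetry_with_tied_weights(self):
        spec = make_cell_spec("bilstm", 2, 3, seed=3)
        for k in list(spec.weights):
            if k.startswith("f_"):
                spec.weights["b_" + k[2:]] = spec.weights[k].copy()
        spec.weights["w6"] = spec.weights["w4"].copy()
        rng = np.random.default_rng(4)
        half = rng.normal(size=(3, 2))
        seq = np.vstack([half, half[::-1]])  # palindromic input
        y = bilstm_forward(seq, spec)
        np.testing.assert_allclose(y, y[::-1], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        spec = make_cell_spec("bilstm", 3, 4, seed=seed)
        seq = rng.normal(size=(6, 3))
        np.testing.assert_allclose(bilstm_forward(seq, spec),
                                   oracle_bilstm(seq, spec), rtol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("kind", ["elman", "gru", "bilstm"])
    def test_bptt_matches_finite_differences(self, kind):
        rng = np.random.default_rng(0)
        clf = SequenceClassifier(kind, n_features=12, n_classes=3,
                                 hidden_units=4, timesteps=3, seed=1)
        X = rng.standard_normal((5, 12))
        y = rng.integers(0, 3, 5)
        _, cell_grads, head_grads = clf.loss_and_grads(X, y)
        eps = 1e-6
        for params, grads in ((clf.spec.weights, cell_grads),
                              (clf.head, head_grads)):
            for name, v in params.items():
                flat = v.ravel()
                for idx in rng.choice(flat.size, size=min(4, flat.size),
                                      replace=False):
                    old = flat[idx]
                    flat[idx] = old + eps
                    lp, *_ = clf.loss_and_grads(X, y)
                    flat[idx] = old - eps
                    lm, *_ = clf.loss_and_grads(X, y)
                    flat[idx] = old
                    num = (lp - lm) / (2 * eps)
                    ana = grads[name].ravel()[idx]
                    assert num == pytest.approx(ana, rel=1e-4, abs=1e-8), \
                        f"{kind} {name}[{idx}]"

    def test_training_separates_shifted_gaussians(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (40, 16)), rng.normal(2, 1, (40, 16))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        clf = SequenceClassifier("gru", 16, 2, hidden_units=8, timesteps=4,
                                 seed=0, epochs=15)
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) > 0.95
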