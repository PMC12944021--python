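"""Unit tests for the sequence labellers: equation oracles, length contracts,
layer/scan equivalence, hybrid composition, and serialisation."""

import numpy as np
import pytest

from densehar.models import (
    FAMILIES,
    ConvLayerSpec,
    DenseLabeller,
    GRUCellParams,
    GRULayer,
    ModelConfig,
    assemble_hybrid,
    conv1d,
    forward,
    gru_step,
    reduced_family_preset,
    reduced_gru_preset,
    sigmoid,
)
from densehar.io import SignalWindow


def brute_force_conv(x, W, b, stride):
    """Independent transcription of the convolution formula: for every kernel
    and valid position, the kernel-window inner product + bias through ReLU."""
    n, T = x.shape
    O, _, k = W.shape
    out = []
    for o in range(O):
        row = []
        for t0 in range(0, T - k + 1, stride):
            s = b[o]
            for i in range(k):
                for c in range(n):
                    s += W[o, c, i] * x[c, t0 + i]
            row.append(max(s, 0.0))
        out.append(row)
    return np.array(out)


def brute_force_gru_step(x, h, p):
    """Direct transcription of the gate equations."""
    z = p.activation(p.Wz @ x + p.Uz @ h + p.bz)
    r = p.activation(p.Wr @ x + p.Ur @ h + p.br)
    hc = np.tanh(p.Wh @ x + p.Uh @ (r * h) + p.bh)
    return (1 - z) * h + z * hc, z, r, hc


def random_cell_params(rng, H, F):
    g = lambda *s: rng.normal(scale=0.5, size=s)
    return GRUCellParams(
        Wz=g(H, F), Wr=g(H, F), Wh=g(H, F),
        Uz=g(H, H), Ur=g(H, H), Uh=g(H, H),
        bz=g(H), br=g(H), bh=g(H),
    )


class TestConv1d:
    def test_identity_kernel_applies_relu(self):
        spec = ConvLayerSpec(1, 1, 1, weights=np.array([1.0]), bias=np.array([0.0]))
        out = conv1d(np.array([0.5, -0.3, 2.0]), spec)
        np.testing.assert_allclose(out, [[0.5, 0.0, 2.0]])

    def test_sum_kernel_hand_arithmetic(self):
        spec = ConvLayerSpec(1, 2, 1, weights=np.array([1.0, 1.0]), bias=np.array([0.0]))
        out = conv1d(np.array([1.0, 2.0, 3.0]), spec, pad=False)
        np.testing.assert_allclose(out, [[3.0, 5.0]])

    @pytest.mark.parametrize("stride,k", [(1, 3), (2, 5), (3, 4), (5, 11)])
    def test_matches_brute_force_loop(self, rng, stride, k):
        x = rng.normal(size=(6, 50))
        W = rng.normal(size=(4, 6, k))
        b = rng.normal(size=4)
        spec = ConvLayerSpec(4, k, stride, weights=W, bias=b)
        np.testing.assert_allclose(
            conv1d(x, spec, pad=False), brute_force_conv(x, W, b, stride), atol=1e-6
        )

    def test_padded_length_is_ceil_t_over_stride(self, rng):
        x = rng.normal(size=(3, 47))
        spec = ConvLayerSpec(2, 5, 3, weights=rng.normal(size=(2, 3, 5)))
        assert conv1d(x, spec).shape == (2, -(-47 // 3))

    def test_window_shorter_than_kernel_rejected(self, rng):
        spec = ConvLayerSpec(1, 9, 1, weights=rng.normal(size=(1, 2, 9)))
        with pytest.raises(ValueError, match="minimum window length"):
            conv1d(rng.normal(size=(2, 5)), spec)


class TestGruStep:
    def test_zero_weights_collapse_to_half_interpolation(self):
        H, F = 2, 3
        p = GRUCellParams(*[np.zeros((H, F))] * 3, *[np.zeros((H, H))] * 3,
                          *[np.zeros(H)] * 3)
        h, z, r, hc = gru_step(np.ones(F), np.array([1.0, -2.0]), p)
        np.testing.assert_allclose(z, [0.5, 0.5])
        np.testing.assert_allclose(r, [0.5, 0.5])
        np.testing.assert_allclose(hc, [0.0, 0.0])
        np.testing.assert_allclose(h, [0.5, -1.0])

    def test_closed_update_gate_preserves_hidden_state(self, rng):
        H, F = 3, 2
        p = random_cell_params(rng, H, F)
        p = GRUCellParams(p.Wz * 0, p.Wr, p.Wh, p.Uz * 0, p.Ur, p.Uh,
                          np.full(H, -1e4), p.br, p.bh)
        h_prev = rng.normal(size=H)
        h, z, _, _ = gru_step(rng.normal(size=F), h_prev, p)
        np.testing.assert_allclose(h, h_prev, atol=1e-12)

    def test_matches_equation_oracle(self, rng):
        for _ in range(20):
            p = random_cell_params(rng, 4, 3)
            x, h = rng.normal(size=3), rng.normal(size=4)
            got = gru_step(x, h, p)
            want = brute_force_gru_step(x, h, p)
            for g, w in zip(got, want):
                np.testing.assert_allclose(g, w, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        p = random_cell_params(rng, 4, 3)
        with pytest.raises(ValueError):
            gru_step(np.zeros(5), np.zeros(4), p)


class TestGruLayer:
    def test_forward_equals_step_scan_both_directions(self, rng):
        layer = GRULayer(3, 5, bidirectional=True, rng=rng)
        x = rng.normal(size=(1, 25, 3))
        out = layer.forward(x, training=False, rng=None)[0]
        # forward direction scan
        p = layer.fwd.cell_params()
        h = np.zeros(5)
        for t in range(25):
            h, *_ = gru_step(x[0, t], h, p)
            np.testing.assert_allclose(out[t, :5], h, atol=1e-9)
        # backward direction: scan over reversed time
        p = layer.bwd.cell_params()
        h = np.zeros(5)
        for t in range(24, -1, -1):
            h, *_ = gru_step(x[0, t], h, p)
            np.testing.assert_allclose(out[t, 5:], h, atol=1e-9)


class TestForwardContract:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_output_rows_equal_input_frames(self, rng, family):
        model = DenseLabeller(reduced_family_preset(family), seed=0)
        for T in (11, 57, 200, 433):
            window = rng.normal(size=(6, T))
            fp = forward(model, window)
            assert fp.probabilities.shape == (T, model.config.class_count)
            np.testing.assert_allclose(fp.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform_rows(self, rng):
        model = DenseLabeller(reduced_gru_preset(), seed=0)
        head = model.net.layers[-1]
        head.params["W"][...] = 0.0
        head.params["b"][...] = 0.0
        fp = forward(model, rng.normal(size=(6, 40)))
        np.testing.assert_allclose(fp.probabilities, 1.0 / 9.0, atol=1e-12)

    def test_evaluation_forward_is_deterministic(self, rng):
        model = DenseLabeller(reduced_gru_preset(), seed=0)
        window = rng.normal(size=(6, 100))
        a = forward(model, window).probabilities
        b = forward(model, window).probabilities
        assert np.array_equal(a, b)

    def test_channel_mismatch_rejected(self, rng):
        model = DenseLabeller(reduced_gru_preset(input_channels=6), seed=0)
        with pytest.raises(ValueError, match="channels"):
            forward(model, rng.normal(size=(3, 50)))

    def test_short_window_rejected_for_conv_family(self, rng):
        model = DenseLabeller(reduced_family_preset("cnn"), seed=0)
        with pytest.raises(ValueError, match="minimum window length"):
            forward(model, rng.normal(size=(6, 3)))

    def test_argmax_tie_breaks_to_lowest_class(self):
        from densehar.models import FramePredictions

        fp = FramePredictions(probabilities=np.array([[0.4, 0.4, 0.2]]))
        assert fp.argmax_labels[0] == 0


class TestHybrids:
    def test_identity_conv_hybrid_matches_pure_gru(self, rng):
        """ConvRec with a k=1 identity kernel bank (and no conv-side batch
        norm) must reproduce the pure GRU once the recurrent block and head
        share weights; requires a non-negative window so ReLU is transparent."""
        n, C = 4, 3
        eye = np.eye(n)[:, :, None]
        cfg_hybrid = ModelConfig(
            family="convrec", input_channels=n, class_count=C,
            conv_specs=(ConvLayerSpec(n, 1, 1, dropout_rate=0.0, batch_norm=False,
                                      weights=eye, bias=np.zeros(n)),),
            gru_units=(6,), bidirectional=True,
        )
        cfg_gru = ModelConfig(family="gru", input_channels=n, class_count=C,
                              gru_units=(6,), bidirectional=True)
        hybrid = assemble_hybrid("convrec", cfg_hybrid, seed=0)
        pure = DenseLabeller(cfg_gru, seed=1)
        # copy the shared (GRU block + head) parameters across
        shared_h = [l for l in hybrid.net.layers if l.params][1:]  # skip conv
        shared_p = [l for l in pure.net.layers if l.params]
        assert len(shared_h) == len(shared_p)
        for lh, lp in zip(shared_h, shared_p):
            for k in lh.params:
                lh.params[k][...] = lp.params[k]
        window = np.abs(rng.normal(size=(n, 60)))
        np.testing.assert_allclose(
            hybrid.predict(window).probabilities,
            pure.predict(window).probabilities,
            atol=1e-6,
        )

    def test_reconv_preserves_length(self, rng):
        model = assemble_hybrid("reconv", reduced_family_preset("reconv"), seed=0)
        assert forward(model, rng.normal(size=(6, 50))).n_frames == 50

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="convrec or reconv"):
            assemble_hybrid("cnn", reduced_family_preset("cnn"))

    def test_stride_shortening_restored_before_recurrent_block(self, rng):
        cfg = ModelConfig(
            family="convrec", input_channels=6, class_count=9,
            conv_specs=(ConvLayerSpec(8, 3, 2),), gru_units=(8,),
        )
        model = DenseLabeller(cfg, seed=0)
        conv = model.net.layers[0]
        x = rng.normal(size=(1, 200, 6))
        assert conv.forward(x, training=False, rng=None).shape == (1, 200, 8)


class TestTranslationCovariance:
    def test_stride_one_conv_shifts_with_input(self, rng):
        k, s = 5, 7
        cfg = ModelConfig(
            family="cnn", input_channels=2, class_count=3,
            conv_specs=(ConvLayerSpec(4, k, 1, dropout_rate=0.0, batch_norm=False),),
        )
        model = DenseLabeller(cfg, seed=0)
        base = rng.normal(size=(2, 80))
        shifted = np.roll(base, s, axis=1)
        a = model.predict(base).probabilities
        b = model.predict(shifted).probabilities
        # interior of the valid region, excluding edge padding and roll wrap
        np.testing.assert_allclose(a[k : 80 - k - s], b[k + s : 80 - k], atol=1e-9)


class TestSerialisation:
    def test_save_load_roundtrip(self, rng, tmp_path):
        model = DenseLabeller(reduced_family_preset("convrec"), seed=0)
        window = rng.normal(size=(6, 64))
        before = model.predict(window).probabilities
        path = model.save(tmp_path / "model.npz")
        after = DenseLabeller.load(path).predict(window).probabilities
        np.testing.assert_allclose(before, after, atol=0)


class TestConfigValidation:
    def test_hybrid_requires_both_blocks(self):
        with pytest.raises(ValueError, match="gru_units"):
            ModelConfig(family="convrec", input_channels=6, class_count=9,
                        conv_specs=(ConvLayerSpec(8, 3),))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelConfig(family="lstm", input_channels=6, class_count=9)
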