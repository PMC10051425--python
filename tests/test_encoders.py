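"""Dual-view network: shapes, determinism, attention and gradient flow."""

import numpy as np
import pytest

from tripledare import DualViewNet, ModelConfig, fuse
from tripledare import autodiff as ad

SMALL_CFG = ModelConfig(cnn_channels=[4, 6, 8], cnn_combined_channels=[8, 8, 12],
                        cnn_strides=[2, 1, 1], cnn_combined_strides=[1, 1, 1])


def make_model(n_features=10, n_labels=5, T=60, seed=0, **overrides):
    cfg = SMALL_CFG.model_copy(update=overrides) if overrides else SMALL_CFG
    return DualViewNet(n_features, n_labels, T, cfg, seed=seed, dtype=np.float64)


class TestEncodeMlp:
    def test_zero_parameters_give_zero_vector(self, rng):
        model = make_model()
        for p in model.mlp1.parameters() + model.mlp2.parameters():
            p.data = np.zeros_like(p.data)
        out = model.encode_mlp(rng.standard_normal((3, 10)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_deterministic_and_seed_reproducible(self, rng):
        x = rng.standard_normal((4, 10))
        a = make_model(seed=3).encode_mlp(x).data
        b = make_model(seed=3).encode_mlp(x).data
        np.testing.assert_array_equal(a, b)

    def test_default_hidden_dim_is_16(self, rng):
        model = DualViewNet(10, 5, 60, SMALL_CFG, seed=0)
        assert model.encode_mlp(rng.standard_normal((2, 10))).data.shape == (2, 16)


class TestEncodeCnn:
    def test_attention_weights_sum_to_one(self, rng):
        model = make_model()
        raw = rng.standard_normal((3, 3, 3, 60))
        _, weights = model.encode_cnn(raw, return_attention=True)
        np.testing.assert_allclose(weights.data.sum(axis=1), 1.0, atol=1e-6)

    def test_constant_in_time_equals_mean_pooling(self):
        """A signal constant over time yields uniform attention, so attention
        pooling coincides with plain mean pooling."""
        model_att = make_model(seed=1)
        model_mean = make_model(seed=1, attention=False)
        raw = np.tile(np.linspace(-1, 1, 9).reshape(1, 3, 3, 1), (2, 1, 1, 60))
        a = model_att.encode_cnn(raw).data
        b = model_mean.encode_cnn(raw).data
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_translation_changes_output_less_than_permutation(self):
        """Locality sanity: shifting the input by one sample perturbs an
        untrained stride-1 encoder far less than shuffling the time axis
        (statistical over 50 seeds).  Stride 1 matters: a strided first conv
        resamples a shifted signal on the other grid parity."""
        wins_shift = 0
        base_rng = np.random.default_rng(99)
        raw = base_rng.standard_normal((1, 3, 3, 60))
        shifted = np.roll(raw, 1, axis=-1)
        for seed in range(50):
            model = make_model(seed=seed, cnn_strides=[1, 1, 1])
            perm = np.random.default_rng([seed, 1]).permutation(60)
            out = model.encode_cnn(raw).data
            d_shift = np.linalg.norm(model.encode_cnn(shifted).data - out)
            d_perm = np.linalg.norm(model.encode_cnn(raw[..., perm]).data - out)
            wins_shift += d_shift < d_perm
        assert wins_shift >= 45

    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            make_model().encode_cnn(rng.standard_normal((2, 2, 3, 60)))


class TestFuse:
    def test_dimensions_add(self, rng):
        a = rng.standard_normal((3, 16))
        b = rng.standard_normal((3, 32))
        assert fuse(a, b).shape == (3, 48)

    def test_zero_inputs_give_zero(self):
        np.testing.assert_array_equal(fuse(np.zeros((2, 4)), np.zeros((2, 6))),
                                      np.zeros((2, 10)))

    def test_slicing_recovers_inputs(self, rng):
        a = rng.standard_normal((5, 7))
        b = rng.standard_normal((5, 9))
        out = fuse(a, b)
        np.testing.assert_array_equal(out[:, :7], a)
        np.testing.assert_array_equal(out[:, 7:], b)


class TestPredictContexts:
    def test_zero_logits_give_half(self, rng):
        model = make_model()
        model.head2.w.data = np.zeros_like(model.head2.w.data)
        model.head2.b.data = np.zeros_like(model.head2.b.data)
        probs = model.predict_contexts(rng.standard_normal((3, 16 + 12)))
        np.testing.assert_allclose(probs.data, 0.5)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        model = make_model()
        probs = model.predict_contexts(rng.standard_normal((8, 28)) * 5).data
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_monotone_in_logit_bias(self, rng):
        model = make_model()
        x = rng.standard_normal((4, 28))
        before = model.predict_contexts(x).data
        model.head2.b.data = model.head2.b.data + 1.0
        after = model.predict_contexts(x).data
        assert np.all(after > before)


def test_forward_deterministic_and_consistent(rng):
    model = make_model()
    feats = rng.standard_normal((4, 10))
    raw = rng.standard_normal((4, 3, 3, 60))
    out1 = model.forward(feats, raw)
    out2 = model.forward(feats, raw)
    for k in out1:
        np.testing.assert_array_equal(out1[k].data, out2[k].data)
    np.testing.assert_array_equal(
        out1["e_fused"].data,
        np.concatenate([out1["e_mlp"].data, out1["e_cnn"].data], axis=1))


def test_gradient_flows_to_both_encoders(rng):
    model = make_model()
    feats = rng.standard_normal((6, 10))
    raw = rng.standard_normal((6, 3, 3, 60))
    out = model.forward(feats, raw)
    loss = ad.sum_(ad.mul(out["logits"], out["logits"]))
    model.zero_grad()
    loss.backward()
    mlp_norm = sum(np.abs(p.grad).sum() for p in model.mlp1.parameters())
    cnn_norm = sum(np.abs(p.grad).sum()
                   for stack in model.sensor_stacks for p in stack.parameters())
    assert mlp_norm > 0 and cnn_norm > 0


def test_checkpoint_round_trip(tmp_path, rng):
    model = make_model(seed=5)
    feats = rng.standard_normal((3, 10))
    raw = rng.standard_normal((3, 3, 3, 60))
    want = model.forward(feats, raw)["logits"].data
    path = model.save(tmp_path / "model.npz")
    loaded = DualViewNet.load(path)
    got = loaded.forward(feats, raw)["logits"].data
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_window_too_short_rejected():
    with pytest.raises(ValueError):
        DualViewNet(10, 5, 4, SMALL_CFG, seed=0)
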