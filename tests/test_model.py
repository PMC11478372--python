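"""Architecture conformance, SE block semantics, LSTM reference cell."""

import numpy as np
import pytest

from ecgpipe import nn
from ecgpipe.model import (
    ArchitectureConfig,
    LSTMCellWeights,
    SEBlockSpec,
    build_model,
    layer_output_shapes,
    load_model,
    lstm_reference_step,
    save_model,
    se_block_forward,
)

# sequence-axis / feature dimensions of the published layer table
TABLE_SHAPES = {
    "conv1": (120, 128),
    "pool1": (40, 128),
    "conv2": (40, 32),
    "pool2": (20, 32),
    "conv3": (20, 32),
    "se": (20, 32),
    "pool3": (10, 32),
    "lstm": (100,),
    "dense1": (20,),
    "dense2": (10,),
    "output": (5,),
}


class TestArchitecture:
    def test_default_chain_matches_published_table(self):
        model = build_model(seed=0)
        assert dict(layer_output_shapes(model)) == TABLE_SHAPES

    def test_config_chain_computed_without_building(self):
        assert dict(ArchitectureConfig().expected_shapes()) == TABLE_SHAPES

    def test_output_is_probability_vector(self):
        model = build_model(seed=1)
        x = np.random.default_rng(0).normal(scale=5.0, size=(7, 360, 1))
        p = model.predict_proba(x)
        assert p.shape == (7, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p > 0)

    def test_build_determinism(self):
        a, b = build_model(seed=9), build_model(seed=9)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(dropout=1.5) and build_model(
                ArchitectureConfig(dropout=1.5))

    def test_json_roundtrip(self):
        cfg = ArchitectureConfig(se_reduction=4, l2=5e-4)
        assert ArchitectureConfig.from_json(cfg.to_json()) == cfg

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(seed=2)
        save_model(model, ArchitectureConfig(), tmp_path / "w.npz")
        loaded, cfg = load_model(tmp_path / "w.npz")
        x = np.random.default_rng(1).normal(size=(3, 360, 1))
        np.testing.assert_array_equal(loaded.forward(x), model.forward(x))


class TestSEBlock:
    def _weights(self, spec, rng):
        return {
            "W1": rng.normal(size=(spec.channels, spec.bottleneck)),
            "b1": rng.normal(size=spec.bottleneck),
            "W2": rng.normal(size=(spec.bottleneck, spec.channels)),
            "b2": rng.normal(size=spec.channels),
        }

    def test_squeeze_of_constant_channel(self):
        """A channel constant at v contributes exactly v to the squeeze."""
        spec = SEBlockSpec(channels=4, reduction=2)
        fmap = np.zeros((10, 4))
        fmap[:, 2] = 3.5
        # zero excitation weights: every channel weight is sigmoid(0) = 0.5
        weights = {"W1": np.zeros((4, 2)), "b1": np.zeros(2),
                   "W2": np.zeros((2, 4)), "b2": np.zeros(4)}
        out = se_block_forward(fmap, spec, weights)
        np.testing.assert_allclose(out[:, 2], 3.5 * 0.5)
        # and the squeeze value itself is the channel mean
        assert fmap[:, 2].mean() == 3.5

    def test_unit_weights_scale_is_identity(self):
        """Forcing the channel weights to one reduces scaling to identity."""
        spec = SEBlockSpec(channels=6, reduction=2)
        rng = np.random.default_rng(0)
        fmap = rng.normal(size=(20, 6))
        # saturate the restoring sigmoid: weights -> 1 within float precision
        weights = {"W1": np.zeros((6, 3)), "b1": np.zeros(3),
                   "W2": np.zeros((3, 6)), "b2": np.full(6, 500.0)}
        np.testing.assert_allclose(se_block_forward(fmap, spec, weights), fmap)

    def test_shape_preserved_and_weights_bounded(self):
        spec = SEBlockSpec(channels=32, reduction=8)
        rng = np.random.default_rng(1)
        fmap = rng.normal(size=(20, 32))
        out = se_block_forward(fmap, spec, self._weights(spec, rng))
        assert out.shape == (20, 32)
        ratio = out / fmap
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_layer_weights_strictly_in_unit_interval(self):
        layer = nn.SEBlock(reduction=8)
        rng = np.random.default_rng(2)
        layer.build((20, 32), rng)
        x = rng.normal(size=(5, 20, 32))
        layer.forward(x)
        _, _, _, _, w, _ = layer._cache
        assert np.all(w > 0) and np.all(w < 1)

    def test_shape_mismatch_rejected(self):
        spec = SEBlockSpec(channels=4, reduction=2)
        with pytest.raises(ValueError):
            se_block_forward(np.zeros((10, 5)), spec,
                             self._weights(spec, np.random.default_rng(0)))


class TestLSTMReferenceCell:
    def test_zero_weight_closed_form(self):
        """With all weights zero: C_t = 0.5 C, h_t = 0.5 tanh(0.5 C)."""
        h_dim, x_dim = 3, 2
        zeros = np.zeros((h_dim, h_dim + x_dim))
        weights = LSTMCellWeights(
            Wi=zeros, Wf=zeros.copy(), Wo=zeros.copy(), Wc=zeros.copy(),
            bi=np.zeros(h_dim), bf=np.zeros(h_dim), bo=np.zeros(h_dim),
            bc=np.zeros(h_dim))
        c_prev = np.array([0.2, -1.0, 2.0])
        h_t, c_t = lstm_reference_step(
            np.zeros(x_dim), (np.zeros(h_dim), c_prev), weights)
        np.testing.assert_allclose(c_t, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h_t, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_scalar_closed_form_value(self):
        zeros = np.zeros((1, 2))
        weights = LSTMCellWeights(
            Wi=zeros, Wf=zeros.copy(), Wo=zeros.copy(), Wc=zeros.copy(),
            bi=np.zeros(1), bf=np.zeros(1), bo=np.zeros(1), bc=np.zeros(1))
        h_t, c_t = lstm_reference_step(
            np.zeros(1), (np.zeros(1), np.ones(1)), weights)
        assert h_t[0] == pytest.approx(0.23105858, abs=1e-6)

    @pytest.mark.parametrize("hidden", range(1, 9))
    def test_agrees_with_production_layer(self, hidden):
        """Per-step reference vs batched BPTT layer on random instances."""
        rng = np.random.default_rng(hidden)
        for trial in range(13):
            x_dim = int(rng.integers(1, 5))
            t_steps = int(rng.integers(2, 11))
            layer = nn.LSTM(hidden)
            layer.build((t_steps, x_dim), rng)
            layer.params["W"] = rng.normal(scale=0.5, size=(x_dim, 4 * hidden))
            layer.params["U"] = rng.normal(scale=0.5, size=(hidden, 4 * hidden))
            layer.params["b"] = rng.normal(scale=0.5, size=4 * hidden)
            x = rng.normal(size=(1, t_steps, x_dim))
            produced = layer.forward(x)[0]
            weights = LSTMCellWeights.from_fused(
                layer.params["W"], layer.params["U"], layer.params["b"])
            h = np.zeros(hidden)
            c = np.zeros(hidden)
            for k in range(t_steps):
                h, c = lstm_reference_step(x[0, k], (h, c), weights)
            np.testing.assert_allclose(h, produced, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        zeros = np.zeros((2, 5))
        weights = LSTMCellWeights(
            Wi=zeros, Wf=zeros.copy(), Wo=zeros.copy(), Wc=zeros.copy(),
            bi=np.zeros(2), bf=np.zeros(2), bo=np.zeros(2), bc=np.zeros(2))
        with pytest.raises(ValueError):
            lstm_reference_step(np.zeros(9), (np.zeros(2), np.zeros(2)), weights)
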