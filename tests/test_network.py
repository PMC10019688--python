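"""Attention block and encoder-decoder network contracts.

Checks the attention head against direct softmax evaluation, the block
against a hand-computed scalar chain, the shape contract of the
encoder-decoder, and gradient flow through the residual concatenation
path.
"""

import numpy as np
import pytest

from fundusenhance.nn import autograd as ag
from fundusenhance.nn.autograd import Tensor
from fundusenhance.nn.model import (
    AttOpBlk,
    ModelConfig,
    build_model,
    load_model,
    make_near_identity,
    save_model,
)


class TestChannelAverage:
    def test_constant_map(self):
        x = Tensor(np.full((1, 3, 4, 4), 0.7))
        assert np.allclose(ag.spatial_mean(x).data, 0.7)

    def test_two_by_two_mean(self):
        x = Tensor(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2))
        assert ag.spatial_mean(x).data[0, 0] == pytest.approx(2.5)

    def test_linearity(self, rng):
        x = rng.normal(size=(2, 4, 5, 5))
        y = rng.normal(size=(2, 4, 5, 5))
        lhs = ag.spatial_mean(Tensor(2.0 * x + 3.0 * y)).data
        rhs = 2.0 * ag.spatial_mean(Tensor(x)).data + 3.0 * ag.spatial_mean(Tensor(y)).data
        assert np.allclose(lhs, rhs)

    def test_empty_map_refused(self):
        with pytest.raises(ValueError):
            ag.spatial_mean(Tensor(np.zeros((1, 3, 0, 4))))


class TestAttentionWeights:
    def _weights_from_logits(self, logits):
        blk = AttOpBlk(np.random.default_rng(0), 4, 4, dtype=np.float64)
        return ag.softmax(Tensor(np.asarray(logits, float)[None]), axis=-1).data[0]

    def test_zero_logits_uniform(self):
        w = self._weights_from_logits([0, 0, 0, 0, 0])
        assert np.allclose(w, 0.2)

    def test_one_hot_logit_softmax_value(self):
        w = self._weights_from_logits([1, 0, 0, 0, 0])
        e = np.e
        assert w[0] == pytest.approx(e / (e + 4), abs=1e-12)
        assert np.allclose(w[1:], 1 / (e + 4), atol=1e-12)

    def test_probability_vector_from_block(self, rng):
        blk = AttOpBlk(np.random.default_rng(7), 8, 8, dtype=np.float64)
        for _ in range(20):
            x = Tensor(rng.normal(size=(3, 8, 6, 6)))
            _, _, w = blk.attention(x)
            assert np.allclose(w.data.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(w.data > 0)

    def test_all_negative_preactivations_collapse_to_uniform(self):
        # ReLU before softmax: nonpositive logits all clamp to 0
        blk = AttOpBlk(np.random.default_rng(1), 4, 4, dtype=np.float64)
        blk.mlp[-1].w.data[...] = 0.0
        blk.mlp[-1].b.data[...] = -5.0
        _, logits, w = blk.attention(Tensor(np.random.default_rng(2).normal(size=(2, 4, 3, 3))))
        assert np.all(logits.data == 0.0)
        assert np.allclose(w.data, 0.2)


class TestAttOpBlk:
    def test_spatial_shape_preserved(self, rng):
        for h, w in [(5, 5), (8, 12), (1, 1)]:
            blk = AttOpBlk(np.random.default_rng(0), 6, 6, dtype=np.float64)
            s, _ = blk(Tensor(rng.normal(size=(2, 6, h, w))))
            assert s.data.shape == (2, 6, h, w)

    def test_channel_mismatch_refused(self, rng):
        blk = AttOpBlk(np.random.default_rng(0), 6, 6)
        with pytest.raises(ValueError, match="channels"):
            blk(Tensor(rng.normal(size=(1, 4, 5, 5)).astype(np.float32)))

    def test_one_hot_attention_selects_branch(self, rng):
        blk = AttOpBlk(np.random.default_rng(3), 4, 4, dtype=np.float64)
        x = Tensor(rng.normal(size=(1, 4, 6, 6)))
        s, _ = blk(x, attention_override=np.array([1.0, 0, 0, 0, 0]))
        # with one-hot attention, G is exactly the 1x1-conv branch output
        y0 = blk.ops[0](x)
        expected = blk.fusion(ag.concat([y0, x], axis=1))
        assert np.allclose(s.data, expected.data, atol=1e-12)

    def test_scalar_chain_oracle_on_1x1_input(self):
        """Hand-computed chain through attention, branches and fusion."""
        rng = np.random.default_rng(5)
        blk = AttOpBlk(rng, 3, 2, dtype=np.float64)
        x = rng.normal(size=(1, 3, 1, 1))
        s, trace = blk(Tensor(x))
        v = x[0, :, 0, 0]
        # attention head: 3-layer MLP with ReLU, final ReLU, softmax
        h = v.copy()
        for layer in blk.mlp[:-1]:
            h = np.maximum(h @ layer.w.data + layer.b.data, 0.0)
        logits = np.maximum(h @ blk.mlp[-1].w.data + blk.mlp[-1].b.data, 0.0)
        e = np.exp(logits - logits.max())
        weights = e / e.sum()
        # each conv on a 1x1 map with full reflection padding sees a
        # constant field: output = (sum of kernel taps) @ v + bias
        ys = [op.w.data.sum(axis=(2, 3)) @ v + op.b.data for op in blk.ops]
        ys.append(v)  # 3x3 max pool of a single value
        g = sum(wi * yi for wi, yi in zip(weights, ys))
        out = blk.fusion.w.data[:, :, 0, 0] @ np.concatenate([g, v]) + blk.fusion.b.data
        assert np.allclose(trace.weights[0], weights, atol=1e-12)
        assert np.allclose(s.data[0, :, 0, 0], out, atol=1e-10)

    def test_gradient_reaches_input_through_residual_path(self, rng):
        # zero the fusion weights on the G half: gradients must still
        # flow to the input via the concatenated X half
        blk = AttOpBlk(np.random.default_rng(2), 4, 4, dtype=np.float64)
        blk.fusion.w.data[:, :4] = 0.0
        x = Tensor(rng.normal(size=(1, 4, 5, 5)), requires_grad=True)
        s, _ = blk(x)
        ag.sum_(s).backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0


class TestModel:
    def test_reduced_latent_and_output_shapes(self, rng):
        cfg = ModelConfig.desk_small()  # 64x64 input, base 8
        model = build_model(cfg, seed=0)
        x = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        from fundusenhance.nn import no_grad
        with no_grad():
            y, traces, latent = model.forward(x, return_latent=True)
        assert latent.data.shape == (1, 128, 4, 4)  # 64/2^4 and 8*2^4
        assert y.data.shape == x.shape
        assert len(traces) == 8  # 4 encoder + 4 decoder blocks

    def test_attention_probability_at_every_block(self, rng):
        model = build_model(ModelConfig(n_levels=2, base_channels=4, patch_size=32), seed=1)
        from fundusenhance.nn import no_grad
        with no_grad():
            _, traces = model.forward(rng.uniform(0, 1, (2, 3, 32, 32)).astype(np.float32))
        for tr in traces:
            assert np.allclose(tr.weights.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(tr.weights >= 0)

    def test_deterministic_build_and_forward(self, rng):
        cfg = ModelConfig(n_levels=2, base_channels=4, patch_size=32)
        x = rng.uniform(0, 1, (1, 3, 32, 32)).astype(np.float32)
        from fundusenhance.nn import no_grad
        with no_grad():
            y1, _ = build_model(cfg, seed=5).forward(x)
            y2, _ = build_model(cfg, seed=5).forward(x)
            y3, _ = build_model(cfg, seed=6).forward(x)
        assert np.array_equal(y1.data, y2.data)
        assert not np.array_equal(y1.data, y3.data)

    def test_near_identity_preset_reproduces_input(self, rng):
        model = make_near_identity(build_model(ModelConfig.desk_small(), seed=0))
        x = rng.uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        from fundusenhance.nn import no_grad
        with no_grad():
            y, _ = model.forward(x)
        assert np.allclose(y.data, x, atol=1e-5)

    def test_invalid_configs_refused(self):
        with pytest.raises(ValueError):
            ModelConfig(n_levels=4, base_channels=8, patch_size=100)  # not /16
        with pytest.raises(ValueError):
            ModelConfig(attention_layers=2)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        cfg = ModelConfig(n_levels=2, base_channels=4, patch_size=32)
        model = build_model(cfg, seed=9)
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        x = rng.uniform(0, 1, (1, 3, 32, 32)).astype(np.float32)
        from fundusenhance.nn import no_grad
        with no_grad():
            y1, _ = model.forward(x)
            y2, _ = clone.forward(x)
        assert np.array_equal(y1.data, y2.data)


class TestAutogradNumerics:
    """Spot numeric gradient checks for the composite ops the model uses."""

    @staticmethod
    def _numgrad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            fp = f()
            x[i] -= 2 * eps
            fm = f()
            x[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("op_name", ["conv_s1", "conv_s2", "convT", "maxpool", "softmax"])
    def test_matches_finite_differences(self, op_name, rng):
        x = rng.normal(size=(1, 2, 4, 4))
        w = rng.normal(size=(3, 2, 3, 3)) * 0.4
        wt = rng.normal(size=(2, 3, 3, 3)) * 0.4
        probe = rng.normal(size=None)

        def build(xa):
            t = Tensor(xa)
            if op_name == "conv_s1":
                return ag.conv2d(ag.reflect_pad2d(t, 1), Tensor(w))
            if op_name == "conv_s2":
                return ag.conv2d(ag.zero_pad2d(t, 1), Tensor(w), stride=2)
            if op_name == "convT":
                return ag.conv_transpose2d(t, Tensor(wt))
            if op_name == "maxpool":
                return ag.maxpool2d_3x3(t)
            return ag.softmax(ag.spatial_mean(t), axis=-1)

        xt = Tensor(x.copy(), requires_grad=True)
        if op_name == "conv_s1":
            out = ag.conv2d(ag.reflect_pad2d(xt, 1), Tensor(w))
        elif op_name == "conv_s2":
            out = ag.conv2d(ag.zero_pad2d(xt, 1), Tensor(w), stride=2)
        elif op_name == "convT":
            out = ag.conv_transpose2d(xt, Tensor(wt))
        elif op_name == "maxpool":
            out = ag.maxpool2d_3x3(xt)
        else:
            out = ag.softmax(ag.spatial_mean(xt), axis=-1)
        weights = np.random.default_rng(1).normal(size=out.data.shape)
        ag.sum_(ag.mul(out, Tensor(weights))).backward()
        ng = self._numgrad(lambda: float((build(x).data * weights).sum()), x)
        assert np.abs(xt.grad - ng).max() < 1e-5
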