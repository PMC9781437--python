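"""Split-attention blocks and the two-branch U-shaped network."""

import numpy as np
import pytest

from octaseg.backbone import (BackboneConfig, SplitAttentionBlock,
                              TwoBranchUNet, global_pool_stats,
                              split_attention, split_attention_weights)
from octaseg.nn import Tensor


class TestGlobalPoolStats:
    def test_constant_field(self):
        fused = np.full((4, 3, 5), 2.5)  # sum of R constant splits
        assert np.allclose(global_pool_stats(fused), 2.5)

    def test_degenerate_1x1(self):
        fused = np.arange(4, dtype=float).reshape(4, 1, 1)
        assert np.allclose(global_pool_stats(fused), np.arange(4))

    def test_matches_double_loop(self, rng):
        fused = rng.normal(size=(4, 3, 3))
        ref = np.array([sum(fused[c, i, j] for i in range(3) for j in range(3)) / 9
                        for c in range(4)])
        assert np.allclose(global_pool_stats(fused), ref, atol=1e-12)

    def test_empty_spatial_rejected(self):
        with pytest.raises(ValueError):
            global_pool_stats(np.empty((3, 0, 4)))


class TestSplitAttention:
    def test_identical_logits_give_mean(self, rng):
        splits = [rng.normal(size=(4, 3, 3)) for _ in range(2)]
        logits = np.tile(rng.normal(size=4), (2, 1))
        v = split_attention(splits, logits)
        assert np.allclose(v, 0.5 * (splits[0] + splits[1]))

    def test_radix1_sigmoid_at_zero(self, rng):
        u = rng.normal(size=(4, 3, 3))
        v = split_attention([u], np.zeros((1, 4)))
        assert np.allclose(v, 0.5 * u)

    def test_matches_direct_softmax(self, rng):
        logits = rng.normal(size=(3, 6))
        alpha = split_attention_weights(logits, radix=3)
        ref = np.exp(logits) / np.exp(logits).sum(axis=0)
        assert np.allclose(alpha, ref, atol=1e-12)
        assert np.allclose(alpha.sum(axis=0), 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            split_attention([rng.normal(size=(2, 3, 3)),
                             rng.normal(size=(2, 4, 4))], np.zeros((2, 2)))


class TestSplitAttentionBlock:
    def test_zero_weights_identity_shortcut(self, rng):
        block = SplitAttentionBlock(8, 8, rng, radix=2)
        for p in block.parameters():
            if p.data.ndim >= 2:  # conv and linear weights
                p.data[...] = 0.0
        x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
        y = block(Tensor(x))
        assert np.allclose(y.data, x, atol=1e-6)

    def test_spatial_shape_preserved(self, rng):
        block = SplitAttentionBlock(4, 12, rng, radix=2)
        y = block(Tensor(rng.normal(size=(1, 4, 10, 10)).astype(np.float32)))
        assert y.shape == (1, 12, 10, 10)

    def test_attention_weights_sum_to_one(self, rng):
        block = SplitAttentionBlock(8, 8, rng, radix=2)
        block(Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32)))
        alpha = block.attn[0].last_alpha
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-5)
        assert (alpha >= 0).all()

    def test_radix1_degrades_to_sigmoid_gate(self, rng):
        block = SplitAttentionBlock(4, 4, rng, radix=1)
        y = block(Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32)))
        assert y.shape == (1, 4, 6, 6)
        alpha = block.attn[0].last_alpha
        assert ((alpha > 0) & (alpha < 1)).all()

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            SplitAttentionBlock(4, 6, rng, radix=2, cardinality=4)


@pytest.fixture(scope="module")
def tiny_model():
    return TwoBranchUNet(BackboneConfig.tiny(), np.random.default_rng(0))


class TestTwoBranchUNet:
    def test_output_contracts(self, tiny_model, rng):
        x = Tensor(rng.uniform(size=(1, 1, 64, 64)).astype(np.float32))
        tiny_model.eval()
        out = tiny_model(x)
        assert out.svc_prob.shape == (1, 1, 64, 64)
        assert out.dvc_prob.shape == (1, 1, 64, 64)
        for prob in (out.svc_prob, out.dvc_prob):
            assert prob.data.min() >= 0 and prob.data.max() <= 1
        for emb in (out.svc_embed, out.dvc_embed):
            assert emb.shape == (1, 16, 32, 32)
            norms = np.linalg.norm(emb.data, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-5)

    def test_eval_forward_is_deterministic(self, tiny_model, rng):
        x = Tensor(rng.uniform(size=(1, 1, 64, 64)).astype(np.float32))
        tiny_model.eval()
        a = tiny_model(x)
        b = tiny_model(x)
        assert np.array_equal(a.svc_prob.data, b.svc_prob.data)
        assert np.array_equal(a.dvc_embed.data, b.dvc_embed.data)

    def test_every_attention_unit_normalised(self, tiny_model, rng):
        tiny_model.eval()
        tiny_model(Tensor(rng.uniform(size=(1, 1, 64, 64)).astype(np.float32)))
        weights = tiny_model.attention_weights()
        assert len(weights) > 0
        for alpha in weights:
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-5)

    def test_gradient_reaches_every_encoder_parameter(self, rng):
        model = TwoBranchUNet(BackboneConfig.tiny(), np.random.default_rng(1))
        model.train()
        x = Tensor(rng.uniform(size=(2, 1, 64, 64)).astype(np.float32))
        out = model(x)
        loss = (out.svc_prob.sum() + out.dvc_prob.sum()
                + out.svc_embed.sum() + out.dvc_embed.sum())
        model.zero_grad()
        loss.backward()
        for enc in model.encoders:
            for p in enc.parameters():
                assert p.grad is not None
                assert np.linalg.norm(p.grad) > 0

    def test_forward_image_pads_odd_sizes(self, tiny_model, rng):
        img = rng.uniform(size=(70, 70))
        out = tiny_model.forward_image(img)
        assert out["svc_prob"].shape == (70, 70)
        assert out["dvc_prob"].shape == (70, 70)

    def test_single_branch_modes(self, rng):
        dvc_only = TwoBranchUNet(BackboneConfig.tiny(),
                                 np.random.default_rng(0), svc_enabled=False)
        out = dvc_only(Tensor(rng.uniform(size=(1, 1, 64, 64)).astype(np.float32)))
        assert out.svc_prob is None and out.dvc_prob is not None

    def test_shared_levels_must_cover_deep_branch(self):
        cfg = BackboneConfig(shared_levels=2)
        with pytest.raises(ValueError, match="shared"):
            TwoBranchUNet(cfg, np.random.default_rng(0))
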