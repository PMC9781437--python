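"""Local propagation refinement: weights, aggregation, Dice loss."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from octaseg.finetune import (FinetuneConfig, FinetuneNet, combine_binary,
                              dice_loss, fuse_channels, neighbourhoods,
                              propagate, propagation_weights)
from octaseg.nn import Tensor


class TestPropagationWeights:
    def test_uniform_for_zero_logits(self):
        w = propagation_weights(np.zeros((9, 4, 4)))
        assert np.allclose(w, 1.0 / 9)

    def test_saturation(self):
        h = np.zeros((9, 2, 2))
        h[3] = 50.0
        w = propagation_weights(h)
        assert np.allclose(w[3], 1.0, atol=1e-12)

    def test_matches_per_pixel_softmax(self, rng):
        h = rng.normal(size=(9, 5, 5))
        w = propagation_weights(h)
        for i in range(5):
            for j in range(5):
                e = np.exp(h[:, i, j])
                assert np.allclose(w[:, i, j], e / e.sum(), atol=1e-6)
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-12)


class TestPropagate:
    def test_constant_preserved(self):
        omega = propagation_weights(np.random.default_rng(0).normal(size=(9, 6, 6)))
        out = propagate(omega, np.full((6, 6), 0.37))
        assert np.allclose(out, 0.37)

    def test_uniform_weights_equal_box_filter(self, rng):
        conf = rng.uniform(size=(8, 8))
        omega = np.full((9, 8, 8), 1.0 / 9)
        out = propagate(omega, conf)
        ref = uniform_filter(conf, size=3, mode="mirror")
        assert np.allclose(out, ref, atol=1e-10)

    def test_center_one_hot_is_identity(self, rng):
        conf = rng.uniform(size=(6, 6))
        omega = np.zeros((9, 6, 6))
        omega[4] = 1.0  # center of the 3x3 neighbourhood
        assert np.array_equal(propagate(omega, conf), conf)

    def test_output_within_input_range(self, rng):
        conf = rng.uniform(0.2, 0.9, size=(7, 7))
        omega = propagation_weights(rng.normal(size=(9, 7, 7)))
        out = propagate(omega, conf)
        assert out.min() >= conf.min() - 1e-12
        assert out.max() <= conf.max() + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            propagate(np.full((9, 4, 4), 1 / 9), np.zeros((5, 5)))

    def test_even_neighbourhood_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            neighbourhoods(np.zeros((4, 4)), m=2)


class TestDiceLoss:
    def test_perfect_prediction(self, rng):
        g = (rng.uniform(size=(6, 6)) > 0.6).astype(float)
        assert dice_loss(g, g, 1e-6) == pytest.approx(0.0, abs=1e-9)

    def test_empty_masks_stable(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z, 1e-6) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        p = np.array([1.0, 0.0, 0.5])
        g = np.array([1.0, 0.0, 1.0])
        expected = 1.0 - (2 * 1.5 + 1e-6) / (1.25 + 2.0 + 1e-6)
        assert dice_loss(p, g, 1e-6) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.07692, abs=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dice_loss(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            dice_loss(np.ones(3), np.ones(3), sigma=0.0)


class TestCombineBinary:
    def test_all_zero(self):
        assert combine_binary(np.zeros((3, 3)), np.zeros((3, 3))).sum() == 0

    def test_dominant_branch(self):
        out = combine_binary(np.full((3, 3), 0.9), np.full((3, 3), 0.1), 0.5)
        assert out.all()

    def test_matches_pixel_loop(self, rng):
        a, b = rng.uniform(size=(5, 5)), rng.uniform(size=(5, 5))
        out = combine_binary(a, b, 0.5)
        for i in range(5):
            for j in range(5):
                assert out[i, j] == (1 if max(a[i, j], b[i, j]) >= 0.5 else 0)


@pytest.fixture()
def ftnet():
    return FinetuneNet(FinetuneConfig.tiny(), np.random.default_rng(0))


class TestFinetuneNet:
    def fused(self, rng):
        return fuse_channels(rng.uniform(size=(16, 16)),
                             rng.uniform(size=(16, 16)),
                             rng.uniform(size=(16, 16)))

    def test_shape_and_convexity_bound(self, ftnet, rng):
        f = self.fused(rng)
        for branch, chan in (("svc", 0), ("dvc", 1)):
            out = ftnet.refine(f, branch)
            assert out.shape == (16, 16)
            assert out.min() >= f[chan].min() - 1e-6
            assert out.max() <= f[chan].max() + 1e-6

    def test_zero_logits_reduce_to_box_filter(self, ftnet, rng):
        for p in ftnet.parameters():
            p.data[...] = 0.0
        f = self.fused(rng)
        out = ftnet.refine(f, "dvc")
        assert np.allclose(out, uniform_filter(f[1], size=3, mode="mirror"),
                           atol=1e-6)

    def test_unknown_branch_rejected(self, ftnet, rng):
        with pytest.raises(ValueError, match="branch"):
            ftnet.forward_t(Tensor(self.fused(rng)[None].astype(np.float32)),
                            "mid")

    def test_fuse_channels_validates_shapes(self, rng):
        with pytest.raises(ValueError, match="svc_prob"):
            fuse_channels(rng.uniform(size=(4, 4)), rng.uniform(size=(5, 5)),
                          rng.uniform(size=(5, 5)))
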