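"""Memory bank, hybrid sampling and the global pixel contrastive loss."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octaseg.contrastive import (ContrastiveBatch, LossWeights, MemoryBank,
                                 branch_objective, class_mean_embeddings,
                                 contrastive_grad, hybrid_sample, mse_loss,
                                 pixel_contrastive_loss, rank_hardness,
                                 sample_batch_pixels, total_loss, update_bank)


def unit(v):
    return v / np.linalg.norm(v)


def unit_rows(rng, n, d):
    if n == 0:
        return np.empty((0, d))
    return np.stack([unit(rng.normal(size=d)) for _ in range(n)])


def loop_contrastive_loss(batch: ContrastiveBatch) -> float:
    """Literal translation of the loss definition, one exp at a time."""
    tau = batch.temperature
    terms = []
    for (a, _cls), pos, neg in zip(batch.anchors, batch.positives,
                                   batch.negatives):
        if len(pos) == 0:
            continue
        inner = 0.0
        for p in pos:
            num = math.exp(float(np.dot(a, p)) / tau)
            den = num + sum(math.exp(float(np.dot(a, nv)) / tau) for nv in neg)
            inner += -math.log(num / den)
        terms.append(inner / len(pos))
    return sum(terms) / len(terms) if terms else 0.0


class TestMseLoss:
    def test_identity_and_offset(self):
        x = np.ones((2, 2))
        assert mse_loss(x, x) == 0.0
        assert mse_loss(np.ones(4), np.zeros(4)) == 1.0

    def test_matches_element_loop(self, rng):
        a, b = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        ref = sum((a[i, j] - b[i, j]) ** 2 for i in range(8)
                  for j in range(8)) / 64
        assert abs(mse_loss(a, b) - ref) < 1e-7

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.ones(3), np.ones(4))


class TestSampling:
    def test_single_class_map(self, rng):
        emb = rng.normal(size=(4, 6, 6))
        labels = np.zeros((6, 6), dtype=int)
        out = sample_batch_pixels(emb, labels, 5, rng)
        assert len(out) == 5 and all(cls == 0 for _, cls, _ in out)

    def test_exhausted_class(self, rng):
        labels = np.zeros((6, 6), dtype=int)
        labels[0, :3] = 1
        out = sample_batch_pixels(rng.normal(size=(4, 6, 6)), labels, 10, rng)
        assert sum(cls == 1 for _, cls, _ in out) == 3

    def test_deterministic(self):
        emb = np.random.default_rng(3).normal(size=(4, 6, 6))
        labels = (emb[0] > 0).astype(int)
        a = sample_batch_pixels(emb, labels, 4, np.random.default_rng(9))
        b = sample_batch_pixels(emb, labels, 4, np.random.default_rng(9))
        assert all(np.array_equal(x[0], y[0]) and x[1] == y[1]
                   for x, y in zip(a, b))


class TestMemoryBank:
    def test_fifo_semantics(self):
        bank = MemoryBank(n_classes=1, dim=2, queue_len=5, n_images=1)
        vecs = [unit(np.array([1.0, i])) for i in range(7)]
        for v in vecs:
            update_bank(bank, [(v, 0, 0)])
        stored = list(bank.pixel_queues[0])
        assert len(stored) == 5
        assert all(np.array_equal(s, v) for s, v in zip(stored, vecs[2:]))

    def test_image_table_overwrites(self):
        bank = MemoryBank(n_classes=1, dim=2, queue_len=4, n_images=2)
        update_bank(bank, [], {(0, 7): np.array([1.0, 0.0])})
        update_bank(bank, [], {(0, 7): np.array([0.0, 1.0])})
        assert len(bank.image_embeddings[0]) == 1
        assert np.array_equal(bank.image_embeddings[0][7], [0.0, 1.0])

    def test_capacity_bound_after_random_updates(self, rng):
        bank = MemoryBank(n_classes=2, dim=8, queue_len=16, n_images=4)
        for _ in range(100):
            cls = int(rng.integers(2))
            img = int(rng.integers(4))
            update_bank(bank, [(unit(rng.normal(size=8)), cls, img)],
                        {(cls, img): unit(rng.normal(size=8))})
        assert bank.stored_scalars() <= (4 + 16) * 2 * 8
        bank.validate()

    def test_unknown_class_rejected(self):
        bank = MemoryBank(n_classes=2, dim=2, queue_len=2, n_images=1)
        with pytest.raises(ValueError, match="class"):
            update_bank(bank, [(np.array([1.0, 0.0]), 5, 0)])

    def test_state_roundtrip(self, rng):
        bank = MemoryBank(n_classes=2, dim=4, queue_len=3, n_images=2)
        for i in range(5):
            update_bank(bank, [(unit(rng.normal(size=4)), i % 2, i % 2)])
        clone = MemoryBank.from_state(bank.to_state())
        for c in range(2):
            assert np.array_equal(np.array(list(bank.pixel_queues[c])),
                                  np.array(list(clone.pixel_queues[c])))


class TestRankHardness:
    def test_negative_extremes(self):
        e = unit(np.array([1.0, 0.0]))
        out = rank_hardness(np.stack([-e, e]), e, "negative")
        assert np.array_equal(out[0], e) and np.array_equal(out[1], -e)

    def test_positive_extremes(self):
        e = unit(np.array([1.0, 0.0]))
        out = rank_hardness(np.stack([e, -e]), e, "positive")
        assert np.array_equal(out[0], -e) and np.array_equal(out[1], e)

    def test_matches_brute_force_sort(self, rng):
        anchor = unit(rng.normal(size=6))
        cands = unit_rows(rng, 20, 6)
        out = rank_hardness(cands, anchor, "negative")
        ref = cands[np.argsort([-c @ anchor for c in cands], kind="stable")]
        assert np.allclose(out, ref)

    def test_empty(self):
        out = rank_hardness(np.empty((0, 3)), unit(np.ones(3)), "positive")
        assert out.shape == (0, 3)


class TestHybridSample:
    def make_bank(self, rng, n0=10, n1=10):
        bank = MemoryBank(n_classes=2, dim=4, queue_len=32, n_images=2)
        for _ in range(n0):
            update_bank(bank, [(unit(rng.normal(size=4)), 0, 0)])
        for _ in range(n1):
            update_bank(bank, [(unit(rng.normal(size=4)), 1, 0)])
        return bank

    def test_exhaustion_returns_everything(self, rng):
        bank = self.make_bank(rng, n0=3, n1=2)
        anchor = (unit(rng.normal(size=4)), 0)
        pos, neg = hybrid_sample(bank, anchor, n_pos=8, n_neg=8, rng=rng)
        assert len(pos) == 3 and len(neg) == 2

    def test_empty_class_signals_skip(self, rng):
        bank = MemoryBank(n_classes=2, dim=4, queue_len=8, n_images=1)
        assert hybrid_sample(bank, (unit(rng.normal(size=4)), 0), 4, 4,
                             rng) is None

    def test_degenerate_identical_pool(self, rng):
        bank = MemoryBank(n_classes=2, dim=4, queue_len=32, n_images=1)
        v = unit(np.ones(4))
        for _ in range(10):
            update_bank(bank, [(v, 0, 0)])
        pos, neg = hybrid_sample(bank, (v, 0), 6, 6, rng)
        assert len(pos) == 6 and np.allclose(pos, v)

    def test_hard_half_matches_oracle_ranking(self, rng):
        bank = self.make_bank(rng, n0=4, n1=10)
        anchor = (unit(rng.normal(size=4)), 0)
        _, neg = hybrid_sample(bank, anchor, n_pos=2, n_neg=6, rng=rng)
        pool = bank.entries(1)
        hardest = pool[np.argsort([-c @ anchor[0] for c in pool],
                                  kind="stable")][:3]
        assert np.allclose(neg[:3], hardest)


class TestPixelContrastiveLoss:
    def test_no_negatives_gives_zero(self, rng):
        a = unit(rng.normal(size=4))
        batch = ContrastiveBatch([(a, 1)], [a[None]], [np.empty((0, 4))])
        assert pixel_contrastive_loss(batch) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.07, 0.5, 3.0])
    def test_equal_similarity_gives_log2(self, tau):
        a = unit(np.array([1.0, 0.0, 0.0]))
        p = unit(np.array([0.0, 1.0, 0.0]))
        n = unit(np.array([0.0, 0.0, 1.0]))  # a.p == a.n == 0
        batch = ContrastiveBatch([(a, 1)], [p[None]], [n[None]],
                                 temperature=tau)
        assert pixel_contrastive_loss(batch) == pytest.approx(math.log(2),
                                                              abs=1e-9)

    def test_matches_loop_oracle(self, rng):
        anchors = [(unit(rng.normal(size=8)), int(rng.integers(2)))
                   for _ in range(5)]
        pos = [unit_rows(rng, int(rng.integers(1, 6)), 8) for _ in range(5)]
        neg = [unit_rows(rng, int(rng.integers(0, 8)), 8) for _ in range(5)]
        batch = ContrastiveBatch(anchors, pos, neg, temperature=0.07)
        assert pixel_contrastive_loss(batch) == pytest.approx(
            loop_contrastive_loss(batch), abs=1e-6)

    def test_invariant_to_pair_order(self, rng):
        a = unit(rng.normal(size=6))
        pos = unit_rows(rng, 4, 6)
        neg = unit_rows(rng, 5, 6)
        b1 = ContrastiveBatch([(a, 0)], [pos], [neg])
        b2 = ContrastiveBatch([(a, 0)], [pos[::-1].copy()], [neg[::-1].copy()])
        assert pixel_contrastive_loss(b1) == pytest.approx(
            pixel_contrastive_loss(b2), abs=1e-12)

    def test_harder_negative_never_decreases_loss(self, rng):
        a = unit(rng.normal(size=6))
        pos = unit_rows(rng, 3, 6)
        neg = unit_rows(rng, 4, 6)
        base = pixel_contrastive_loss(ContrastiveBatch([(a, 0)], [pos], [neg]))
        harder = np.vstack([neg, a[None]])  # similarity 1, the hardest possible
        more = pixel_contrastive_loss(ContrastiveBatch([(a, 0)], [pos],
                                                       [harder]))
        assert more >= base

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_nonnegative_on_random_batches(self, seed):
        r = np.random.default_rng(seed)
        A = int(r.integers(1, 5))
        anchors = [(unit(r.normal(size=5)), 0) for _ in range(A)]
        pos = [unit_rows(r, int(r.integers(1, 4)), 5) for _ in range(A)]
        neg = [unit_rows(r, int(r.integers(0, 5)), 5) for _ in range(A)]
        assert pixel_contrastive_loss(
            ContrastiveBatch(anchors, pos, neg)) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        anchors = unit_rows(rng, 3, 6)
        pos = [unit_rows(rng, 3, 6) for _ in range(3)]
        neg = [unit_rows(rng, 4, 6) for _ in range(3)]
        loss, grad = contrastive_grad(anchors, pos, neg, 0.07)
        eps = 1e-6
        for i in range(3):
            for d in range(6):
                ap, am = anchors.copy(), anchors.copy()
                ap[i, d] += eps
                am[i, d] -= eps
                num = (contrastive_grad(ap, pos, neg, 0.07)[0]
                       - contrastive_grad(am, pos, neg, 0.07)[0]) / (2 * eps)
                assert grad[i, d] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestObjectives:
    def test_branch_objective_switch_off(self):
        assert branch_objective(0.42, 3.0, 0.0) == 0.42

    def test_branch_objective_arithmetic(self):
        assert branch_objective(0.5, 2.0, 0.1) == pytest.approx(0.7)

    def test_total_loss(self):
        w = LossWeights(lambda_svc=1.0, lambda_dvc=1.0)
        assert total_loss(0.3, 0.2, w) == pytest.approx(0.5)
        assert total_loss(0.3, 99.0, LossWeights(lambda_dvc=0.0)) == \
            pytest.approx(0.3)
        # symmetric swap leaves the sum unchanged
        wa = LossWeights(lambda_svc=2.0, lambda_dvc=3.0)
        wb = LossWeights(lambda_svc=3.0, lambda_dvc=2.0)
        assert total_loss(0.4, 0.6, wa) == pytest.approx(total_loss(0.6, 0.4, wb))


def test_class_mean_embeddings_are_unit_norm(rng):
    emb = rng.normal(size=(6, 5, 5))
    labels = (rng.uniform(size=(5, 5)) > 0.5).astype(int)
    means = class_mean_embeddings(emb, labels)
    for v in means.values():
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
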