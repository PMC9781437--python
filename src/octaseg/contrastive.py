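"""Memory bank and global pixel contrastive loss.

The bank keeps, for each semantic class, (a) a FIFO queue of at most T
pixel embeddings sampled from recent batches and (b) one mean-pooled class
embedding per training image, so its total capacity is (N + T) x C vectors
of dimension D — M = (N + T) x C x D scalars.  Anchors from the current
batch are contrasted against bank entries drawn with a hybrid strategy:
half hardest (most similar negatives, least similar positives), half
uniform, which keeps the loss focused on the confusable thin-vessel pixels
without collapsing onto them.

All loss functions here are pure numpy (float64); the training pipeline
wraps `contrastive_grad` into the autodiff graph.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


def mse_loss(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean squared error over all elements."""
    pred, gt = np.asarray(pred, dtype=np.float64), np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return float(np.mean((pred - gt) ** 2))


@dataclass
class MemoryBank:
    """Per-class pixel queues (length <= T) plus per-image class means."""

    n_classes: int
    dim: int
    queue_len: int
    n_images: int
    pixel_queues: list[deque] = field(default_factory=list)
    image_embeddings: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not self.pixel_queues:
            self.pixel_queues = [deque(maxlen=self.queue_len)
                                 for _ in range(self.n_classes)]
        if not self.image_embeddings:
            self.image_embeddings = [{} for _ in range(self.n_classes)]

    @property
    def capacity_scalars(self) -> int:
        return (self.n_images + self.queue_len) * self.n_classes * self.dim

    def stored_scalars(self) -> int:
        return sum(len(q) for q in self.pixel_queues) * self.dim + \
            sum(len(t) for t in self.image_embeddings) * self.dim

    def entries(self, cls: int) -> np.ndarray:
        """Pixel queue united with the image-embedding table for one class."""
        rows = list(self.pixel_queues[cls]) + \
            list(self.image_embeddings[cls].values())
        return np.array(rows) if rows else np.empty((0, self.dim))

    def validate(self) -> None:
        for c in range(self.n_classes):
            assert len(self.pixel_queues[c]) <= self.queue_len
            assert len(self.image_embeddings[c]) <= self.n_images
            e = self.entries(c)
            if len(e):
                assert np.allclose(np.linalg.norm(e, axis=1), 1.0, atol=1e-4)
        assert self.stored_scalars() <= self.capacity_scalars

    def to_state(self) -> dict:
        return {
            "meta": np.array([self.n_classes, self.dim, self.queue_len,
                              self.n_images]),
            "queues": [np.array(list(q)) if q else np.empty((0, self.dim))
                       for q in self.pixel_queues],
            "tables": [{k: v.copy() for k, v in t.items()}
                       for t in self.image_embeddings],
        }

    @classmethod
    def from_state(cls, state: dict) -> "MemoryBank":
        C, D, T, N = (int(v) for v in state["meta"])
        bank = cls(n_classes=C, dim=D, queue_len=T, n_images=N)
        for c in range(C):
            for row in state["queues"][c]:
                bank.pixel_queues[c].append(np.asarray(row))
            bank.image_embeddings[c] = {int(k): np.asarray(v)
                                        for k, v in state["tables"][c].items()}
        return bank


def sample_batch_pixels(embed_map: np.ndarray, label_map: np.ndarray,
                        n_per_class: int, rng: np.random.Generator,
                        image_id: int = 0) -> list[tuple[np.ndarray, int, int]]:
    """Uniformly sample up to n_per_class pixel embeddings per present class.

    embed_map is [D, H', W']; label_map [H', W'] with integer class ids.
    """
    D = embed_map.shape[0]
    flat_emb = embed_map.reshape(D, -1).T
    flat_lab = label_map.reshape(-1)
    out = []
    for cls in np.unique(flat_lab):
        idx = np.flatnonzero(flat_lab == cls)
        take = min(n_per_class, len(idx))
        chosen = rng.choice(idx, size=take, replace=False)
        out.extend((flat_emb[i].copy(), int(cls), image_id) for i in chosen)
    return out


def class_mean_embeddings(embed_map: np.ndarray,
                          label_map: np.ndarray) -> dict[int, np.ndarray]:
    """Re-normalised per-class mean pooling of an image's pixel embeddings."""
    D = embed_map.shape[0]
    flat_emb = embed_map.reshape(D, -1)
    flat_lab = label_map.reshape(-1)
    means = {}
    for cls in np.unique(flat_lab):
        m = flat_emb[:, flat_lab == cls].mean(axis=1)
        n = np.linalg.norm(m)
        if n > 1e-12:
            means[int(cls)] = m / n
    return means


def update_bank(bank: MemoryBank, samples, per_image_means=None) -> MemoryBank:
    """FIFO-enqueue sampled pixels; overwrite per-image class means."""
    for emb, cls, _img in samples:
        if not 0 <= cls < bank.n_classes:
            raise ValueError(f"unknown class index {cls}")
        bank.pixel_queues[cls].append(np.asarray(emb, dtype=np.float64))
    if per_image_means:
        for (cls, image_id), emb in per_image_means.items():
            if not 0 <= cls < bank.n_classes:
                raise ValueError(f"unknown class index {cls}")
            bank.image_embeddings[cls][int(image_id)] = \
                np.asarray(emb, dtype=np.float64)
    return bank


def rank_hardness(bank_entries: np.ndarray, anchor: np.ndarray,
                  polarity: str) -> np.ndarray:
    """Order candidate embeddings hardest-first.

    Hard negatives are the most similar to the anchor (largest inner
    product); hard positives the least similar.  Returns the reordered
    entries; ties keep their input order (stable sort).
    """
    entries = np.asarray(bank_entries)
    if len(entries) == 0:
        return entries.reshape(0, len(anchor))
    sims = entries @ np.asarray(anchor)
    if polarity == "negative":
        order = np.argsort(-sims, kind="stable")
    elif polarity == "positive":
        order = np.argsort(sims, kind="stable")
    else:
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    return entries[order]


def _hybrid_pick(pool: np.ndarray, anchor: np.ndarray, n: int, polarity: str,
                 rng: np.random.Generator) -> np.ndarray:
    if len(pool) <= n:
        return pool
    n_hard = -(-n // 2)  # ceil
    ranked = rank_hardness(pool, anchor, polarity)
    hard = ranked[:n_hard]
    rest = ranked[n_hard:]
    rand_idx = rng.choice(len(rest), size=n - n_hard, replace=False)
    return np.concatenate([hard, rest[rand_idx]], axis=0)


@dataclass
class ContrastiveBatch:
    """Anchors with their per-anchor positive/negative embedding sets."""

    anchors: list[tuple[np.ndarray, int]]
    positives: list[np.ndarray]   # one [P_i, D] array per anchor
    negatives: list[np.ndarray]   # one [N_i, D] array per anchor
    temperature: float = 0.07


def hybrid_sample(bank: MemoryBank, anchor: tuple[np.ndarray, int],
                  n_pos: int, n_neg: int,
                  rng: np.random.Generator):
    """Draw a positive/negative set for one anchor: half hardest, half random.

    Candidate pools unite the pixel queue and the image-embedding table of
    the relevant classes.  Returns None when the anchor's class has no bank
    entries yet (warm-up); that anchor is skipped, not an error.
    """
    emb, cls = anchor
    pos_pool = bank.entries(cls)
    if len(pos_pool) == 0:
        return None
    neg_pool = np.concatenate([bank.entries(c) for c in range(bank.n_classes)
                               if c != cls and len(bank.entries(c))] or
                              [np.empty((0, bank.dim))], axis=0)
    positives = _hybrid_pick(pos_pool, emb, n_pos, "positive", rng)
    negatives = _hybrid_pick(neg_pool, emb, n_neg, "negative", rng) \
        if len(neg_pool) else np.empty((0, bank.dim))
    return positives, negatives


def pixel_contrastive_loss(batch: ContrastiveBatch) -> float:
    """Global pixel contrastive (InfoNCE-style) loss.

    L = mean_i (1/|P_i|) sum_{p in P_i}
        -log[ exp(a_i.p/tau) / (exp(a_i.p/tau) + sum_{n in N_i} exp(a_i.n/tau)) ]

    computed with max-subtraction for stability; anchors with an empty
    positive set are excluded, and the loss is 0 if every anchor is excluded.
    """
    tau = batch.temperature
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    terms = []
    for (emb, _cls), pos, neg in zip(batch.anchors, batch.positives,
                                     batch.negatives):
        if len(pos) == 0:
            continue
        sp = (np.asarray(pos, dtype=np.float64) @ emb) / tau     # [P]
        sn = (np.asarray(neg, dtype=np.float64) @ emb) / tau \
            if len(neg) else np.empty(0)                          # [N]
        m = max(sp.max(), sn.max() if len(sn) else -np.inf)
        neg_mass = np.exp(sn - m).sum() if len(sn) else 0.0
        ep = np.exp(sp - m)
        terms.append(float(np.mean(-np.log(ep / (ep + neg_mass)))))
    return float(np.mean(terms)) if terms else 0.0


def contrastive_grad(anchors: np.ndarray, positives, negatives,
                     tau: float) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the anchor embeddings.

    Bank entries are constants (no gradient flows into stored vectors).
    For one anchor a with positive p and negatives N, the per-positive term
    has gradient (1/tau) [ (s_p - 1) p + sum_n s_n n ] where s is the
    softmax over the similarity row {p} ∪ N.
    """
    A = len(anchors)
    grads = np.zeros_like(anchors, dtype=np.float64)
    terms = []
    active = 0
    for i in range(A):
        pos, neg = np.asarray(positives[i], float), np.asarray(negatives[i], float)
        if len(pos) == 0:
            continue
        active += 1
        a = anchors[i].astype(np.float64)
        sp = pos @ a / tau
        sn = neg @ a / tau if len(neg) else np.empty(0)
        m = max(sp.max(), sn.max() if len(sn) else -np.inf)
        en = np.exp(sn - m)
        neg_mass = en.sum()
        ep = np.exp(sp - m)                 # [P]
        z = ep + neg_mass
        s_p = ep / z
        terms.append(float(np.mean(-np.log(s_p))))
        g = (s_p - 1.0) @ pos
        if len(neg):
            g = g + (1.0 / z).sum() * (en @ neg)
        grads[i] = g / (tau * len(pos))
    if not terms:
        return 0.0, grads
    loss = float(np.mean(terms))
    grads /= active
    return loss, grads


def branch_objective(mse: float, contrastive: float,
                     lambda_nce: float) -> float:
    """Per-branch objective: MSE plus weighted contrastive term."""
    return mse + lambda_nce * contrastive


@dataclass(frozen=True)
class LossWeights:
    lambda_nce: float = 0.1
    lambda_svc: float = 1.0
    lambda_dvc: float = 1.0


def total_loss(svc_obj: float, dvc_obj: float, weights: LossWeights) -> float:
    """Weighted sum of the two branch objectives."""
    return weights.lambda_svc * svc_obj + weights.lambda_dvc * dvc_obj
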