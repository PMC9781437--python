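"""Local-propagation refinement of vessel confidence maps.

The segmentation stage leaves breakpoints in thin deep vessels.  The
refinement stage fuses the two branch confidence maps with the original
image into a 3-channel input, predicts for every pixel a softmax-normalised
weight over its m x m neighbourhood (the propagation field), and
re-aggregates each pixel as the weighted sum of its neighbours' confidence
values — a convex combination, so refined values stay within the input
range.  Training minimises Dice loss against the clean ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .nn import Conv2d, Module, Tensor, softmax


def propagation_weights(h: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the m^2 neighbour axis of an [m^2, H, W] field."""
    z = h - h.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def neighbourhoods(confidence: np.ndarray, m: int = 3) -> np.ndarray:
    """Stack of the m^2 reflect-padded neighbour values, [m^2, H, W]."""
    if m % 2 == 0:
        raise ValueError("neighbourhood size m must be odd")
    p = m // 2
    padded = np.pad(confidence, p, mode="reflect")
    win = sliding_window_view(padded, (m, m))          # H, W, m, m
    return np.ascontiguousarray(win.transpose(2, 3, 0, 1).reshape(
        m * m, *confidence.shape))


def propagate(omega: np.ndarray, confidence: np.ndarray) -> np.ndarray:
    """Aggregate each pixel from its neighbourhood: Pred_i = sum_P w_i^P f_i^P."""
    if omega.shape[1:] != confidence.shape:
        raise ValueError(f"omega spatial shape {omega.shape[1:]} does not "
                         f"match confidence {confidence.shape}")
    m = int(round(np.sqrt(omega.shape[0])))
    return (omega * neighbourhoods(confidence, m)).sum(axis=0)


def dice_loss(pred: np.ndarray, gt: np.ndarray, sigma: float = 1e-6) -> float:
    """1 - (2 sum(PG) + sigma) / (sum(P^2) + sum(G^2) + sigma)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    num = 2.0 * float((pred * gt).sum()) + sigma
    den = float((pred ** 2).sum()) + float((gt ** 2).sum()) + sigma
    return 1.0 - num / den


def dice_loss_t(pred: Tensor, gt: np.ndarray, sigma: float = 1e-6) -> Tensor:
    """Differentiable Dice loss on the autodiff graph."""
    gt_t = Tensor(np.asarray(gt, dtype=np.float32))
    num = (pred * gt_t).sum() * 2.0 + sigma
    den = (pred * pred).sum() + float((gt.astype(np.float64) ** 2).sum()) + sigma
    return 1.0 - num / den


def combine_binary(svc_refined: np.ndarray, dvc_refined: np.ndarray,
                   threshold: float = 0.5) -> np.ndarray:
    """Merge the refined branch maps into one binary vessel image."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.maximum(svc_refined, dvc_refined) >= threshold).astype(np.uint8)


@dataclass(frozen=True)
class FinetuneConfig:
    m: int = 3
    channels: int = 32
    sigma: float = 1e-6
    threshold: float = 0.5

    @classmethod
    def tiny(cls) -> "FinetuneConfig":
        return cls(channels=8)


class FinetuneNet(Module):
    """Both refinement paths over the shared 3-channel fused input.

    The superficial path has three conv layers, the deep path two; each
    path's final layer emits m^2 propagation logits per pixel.
    """

    def __init__(self, cfg: FinetuneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, m2 = cfg.channels, cfg.m * cfg.m
        self.svc_conv1 = Conv2d(3, c, 3, rng)
        self.svc_conv2 = Conv2d(c, c, 3, rng)
        self.svc_head = Conv2d(c, m2, 3, rng)
        self.dvc_conv1 = Conv2d(3, c, 3, rng)
        self.dvc_head = Conv2d(c, m2, 3, rng)

    def _logits(self, fused: Tensor, branch: str) -> Tensor:
        if branch == "svc":
            return self.svc_head(self.svc_conv2(self.svc_conv1(fused).relu()).relu())
        if branch == "dvc":
            return self.dvc_head(self.dvc_conv1(fused).relu())
        raise ValueError(f"branch must be 'svc' or 'dvc', got {branch!r}")

    def forward_t(self, fused: Tensor, branch: str) -> Tensor:
        """Differentiable refinement of a [B,3,H,W] fused input batch.

        The branch's confidence channel (0 for svc, 1 for dvc) supplies the
        neighbour values; they are treated as constants so gradient flows
        only through the propagation weights.
        """
        logits = self._logits(fused, branch)            # [B, m^2, H, W]
        omega = softmax(logits, axis=1)
        conf = fused.data[:, 0 if branch == "svc" else 1]
        f = np.stack([neighbourhoods(c, self.cfg.m) for c in conf])
        return (omega * Tensor(f.astype(np.float32))).sum(axis=1)

    def refine(self, fused: np.ndarray, branch: str) -> np.ndarray:
        """Numpy convenience wrapper for one [3,H,W] fused input (eval)."""
        out = self.forward_t(Tensor(fused[None].astype(np.float32)), branch)
        return out.data[0].astype(np.float64)

    def refine_pair(self, fused: np.ndarray) -> dict[str, np.ndarray]:
        svc = self.refine(fused, "svc")
        dvc = self.refine(fused, "dvc")
        return {"refined_svc": svc, "refined_dvc": dvc,
                "combined": combine_binary(svc, dvc, self.cfg.threshold)}


def fuse_channels(svc_prob: np.ndarray, dvc_prob: np.ndarray,
                  image: np.ndarray) -> np.ndarray:
    """Stack (svc confidence, dvc confidence, original image) as [3,H,W]."""
    for name, a in (("svc_prob", svc_prob), ("dvc_prob", dvc_prob),
                    ("image", image)):
        if a.shape != image.shape:
            raise ValueError(f"{name} shape {a.shape} differs from image")
    return np.stack([svc_prob, dvc_prob, image]).astype(np.float64)
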