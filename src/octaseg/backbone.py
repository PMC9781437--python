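"""Two-branch U-shaped encoder-decoder with split-attention blocks.

One branch segments the superficial vascular complex (pixel-level labels),
the other the deep complex (centerline labels).  The first `shared_levels`
encoder stages are shared — the deep branch uses exactly those — while the
superficial branch adds two deeper private stages; decoders are private.
Each branch ends in a 1x1-conv segmentation head (sigmoid) at full
resolution and an MLP projection head on the penultimate decoder feature
(half resolution) that emits L2-normalised D-dimensional pixel embeddings
for the contrastive objective.

The basic block follows the split-attention design: the input is processed
by G = K x R grouped conv paths (K cardinal groups, R splits each, each
split a 1x1 conv+BN+ReLU then 3x3 conv+BN+ReLU); within a cardinal group
the R split maps are fused by per-channel soft attention whose weights come
from global average pooling followed by a two-layer bottleneck; a residual
shortcut closes the block (Y = V + shortcut(X)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv2d, ConvBNReLU, Linear, Module, Tensor, avg_pool2,
                 concat, global_avg_pool, l2_normalize, softmax, stack_sum,
                 upsample2)


@dataclass(frozen=True)
class BackboneConfig:
    base_channels: int = 32
    embed_dim: int = 64
    radix: int = 2
    cardinality: int = 1
    shared_levels: int = 3
    svc_levels: int = 5
    dvc_levels: int = 3

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        """CPU-friendly preset for tests and desk-scale experiments."""
        return cls(base_channels=8, embed_dim=16)

    def channels(self) -> list[int]:
        # doubling per level, capped at 8x base to keep the bottleneck lean
        return [min(self.base_channels * 2 ** i, self.base_channels * 8)
                for i in range(self.svc_levels)]


def global_pool_stats(fused: np.ndarray) -> np.ndarray:
    """Channel statistics S_c = spatial mean of the fused split maps [C,H,W] -> [C]."""
    if fused.ndim != 3 or fused.shape[1] < 1 or fused.shape[2] < 1:
        raise ValueError("expected a C x H x W map with nonempty spatial extent")
    return fused.mean(axis=(1, 2))


def split_attention_weights(logits: np.ndarray, radix: int) -> np.ndarray:
    """Attention over R splits from per-channel logits [R, C].

    Softmax across the split axis for R > 1; the sigmoid form for R = 1.
    """
    if radix > 1:
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)
    return 1.0 / (1.0 + np.exp(-logits))


def split_attention(splits: list[np.ndarray], logits: np.ndarray) -> np.ndarray:
    """Fuse R same-shaped [C,H,W] split maps with per-channel attention."""
    shapes = {s.shape for s in splits}
    if len(shapes) != 1:
        raise ValueError(f"splits disagree in shape: {shapes}")
    alpha = split_attention_weights(logits, len(splits))
    return sum(a[:, None, None] * u for a, u in zip(alpha, splits))


class SplitAttentionFuse(Module):
    """Learned attention fusion of R split maps of `channels` channels each."""

    def __init__(self, channels: int, radix: int, rng, reduction: int = 4):
        super().__init__()
        self.radix = radix
        inter = max(channels * radix // reduction, 8)
        self.fc1 = Linear(channels, inter, rng)
        self.fc2 = Linear(inter, channels * radix, rng)
        self.last_alpha: np.ndarray | None = None

    def __call__(self, splits: list[Tensor]) -> Tensor:
        B, C = splits[0].shape[:2]
        fused = stack_sum(splits)
        s = global_avg_pool(fused)                      # [B, C]
        logits = self.fc2(self.fc1(s).relu())           # [B, R*C]
        logits = logits.reshape(B, self.radix, C)
        if self.radix > 1:
            alpha = softmax(logits, axis=1)
        else:
            alpha = logits.sigmoid()
        self.last_alpha = alpha.data.copy()
        parts = [alpha[:, i, :].reshape(B, C, 1, 1) * u
                 for i, u in enumerate(splits)]
        return stack_sum(parts)


class SplitAttentionBlock(Module):
    """Residual block: K cardinal groups x R attention-fused conv splits."""

    def __init__(self, cin: int, cout: int, rng, radix: int = 2,
                 cardinality: int = 1):
        super().__init__()
        if cout % cardinality:
            raise ValueError(f"output channels {cout} not divisible by "
                             f"cardinality {cardinality}")
        self.cardinality = cardinality
        self.radix = radix
        cg = cout // cardinality
        self.splits = [[
            _SplitPath(cin, cg, rng) for _ in range(radix)]
            for _ in range(cardinality)]
        self.attn = [SplitAttentionFuse(cg, radix, rng)
                     for _ in range(cardinality)]
        self.shortcut = None if cin == cout else Conv2d(cin, cout, 1, rng)

    def modules(self):
        yield self
        for group in self.splits:
            for path in group:
                yield from path.modules()
        for a in self.attn:
            yield from a.modules()
        if self.shortcut is not None:
            yield from self.shortcut.modules()

    def named_state(self):
        out = {}
        for k, group in enumerate(self.splits):
            for r, path in enumerate(group):
                for name, v in path.named_state().items():
                    out[f"splits.{k}.{r}.{name}"] = v
        for k, a in enumerate(self.attn):
            for name, v in a.named_state().items():
                out[f"attn.{k}.{name}"] = v
        if self.shortcut is not None:
            for name, v in self.shortcut.named_state().items():
                out[f"shortcut.{name}"] = v
        return out

    def __call__(self, x: Tensor) -> Tensor:
        groups = []
        for paths, attn in zip(self.splits, self.attn):
            groups.append(attn([p(x) for p in paths]))
        v = groups[0] if len(groups) == 1 else concat(groups, axis=1)
        sc = x if self.shortcut is None else self.shortcut(x)
        return v + sc


class _SplitPath(Module):
    """1x1 conv+BN+ReLU followed by 3x3 conv+BN+ReLU."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.reduce = ConvBNReLU(cin, cout, 1, rng)
        self.conv = ConvBNReLU(cout, cout, 3, rng)

    def __call__(self, x):
        return self.conv(self.reduce(x))


class ProjectionHead(Module):
    """Two 1x1 convs (2D -> D) with ReLU, then per-pixel L2 normalisation."""

    def __init__(self, cin: int, dim: int, rng):
        super().__init__()
        self.fc1 = Conv2d(cin, 2 * dim, 1, rng)
        self.fc2 = Conv2d(2 * dim, dim, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return l2_normalize(self.fc2(self.fc1(x).relu()), axis=1)


@dataclass
class NetworkOutput:
    svc_prob: Tensor     # [B,1,H,W] in (0,1)
    dvc_prob: Tensor     # [B,1,H,W]
    svc_embed: Tensor    # [B,D,H/2,W/2], unit columns
    dvc_embed: Tensor


class _Decoder(Module):
    def __init__(self, chans: list[int], rng, radix, cardinality):
        super().__init__()
        self.blocks = [SplitAttentionBlock(chans[i + 1] + chans[i], chans[i],
                                           rng, radix, cardinality)
                       for i in reversed(range(len(chans) - 1))]

    def __call__(self, feats: list[Tensor]):
        cur = feats[-1]
        penult = None
        for j, block in enumerate(self.blocks):
            level = len(feats) - 2 - j
            cur = block(concat([upsample2(cur), feats[level]], axis=1))
            if level == 1:
                penult = cur
        return cur, penult


class TwoBranchUNet(Module):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 svc_enabled: bool = True, dvc_enabled: bool = True):
        super().__init__()
        if cfg.shared_levels != cfg.dvc_levels:
            raise ValueError("the deep branch must be fully shared: "
                             "shared_levels must equal dvc_levels")
        self.cfg = cfg
        self.svc_enabled = svc_enabled
        self.dvc_enabled = dvc_enabled
        ch = cfg.channels()
        rx, kk = cfg.radix, cfg.cardinality
        self.encoders = [SplitAttentionBlock(1 if i == 0 else ch[i - 1], ch[i],
                                             rng, rx, kk)
                         for i in range(cfg.svc_levels)]
        if svc_enabled:
            self.svc_decoder = _Decoder(ch[:cfg.svc_levels], rng, rx, kk)
            self.svc_head = self._make_head(ch[0], rng)
            self.svc_proj = ProjectionHead(ch[1], cfg.embed_dim, rng)
        if dvc_enabled:
            self.dvc_decoder = _Decoder(ch[:cfg.dvc_levels], rng, rx, kk)
            self.dvc_head = self._make_head(ch[0], rng)
            self.dvc_proj = ProjectionHead(ch[1], cfg.embed_dim, rng)

    @staticmethod
    def _make_head(cin: int, rng) -> Conv2d:
        # small-weight init keeps the initial sigmoid output near 0.5:
        # a saturated head at init can trap training in the all-background
        # minimum of the imbalanced MSE objective
        head = Conv2d(cin, 1, 1, rng)
        head.weight.data *= 0.02
        return head

    def modules(self):
        yield self
        for e in self.encoders:
            yield from e.modules()
        for name in ("svc_decoder", "svc_head", "svc_proj",
                     "dvc_decoder", "dvc_head", "dvc_proj"):
            m = getattr(self, name, None)
            if m is not None:
                yield from m.modules()

    def named_state(self):
        out = {}
        for i, e in enumerate(self.encoders):
            for k, v in e.named_state().items():
                out[f"encoders.{i}.{k}"] = v
        for name in ("svc_decoder", "svc_head", "svc_proj",
                     "dvc_decoder", "dvc_head", "dvc_proj"):
            m = getattr(self, name, None)
            if m is None:
                continue
            if isinstance(m, _Decoder):
                for j, b in enumerate(m.blocks):
                    for k, v in b.named_state().items():
                        out[f"{name}.blocks.{j}.{k}"] = v
            else:
                for k, v in m.named_state().items():
                    out[f"{name}.{k}"] = v
        return out

    def __call__(self, x: Tensor) -> NetworkOutput:
        feats = []
        cur = x
        for i, enc in enumerate(self.encoders):
            if i > 0:
                cur = avg_pool2(cur)
            cur = enc(cur)
            feats.append(cur)
        svc_prob = dvc_prob = svc_embed = dvc_embed = None
        if self.svc_enabled:
            d1, penult = self.svc_decoder(feats)
            svc_prob = self.svc_head(d1).sigmoid()
            svc_embed = self.svc_proj(penult)
        if self.dvc_enabled:
            d1, penult = self.dvc_decoder(feats[:self.cfg.dvc_levels])
            dvc_prob = self.dvc_head(d1).sigmoid()
            dvc_embed = self.dvc_proj(penult)
        return NetworkOutput(svc_prob, dvc_prob, svc_embed, dvc_embed)

    # -- inference helpers -------------------------------------------------

    def attention_weights(self) -> list[np.ndarray]:
        """Last-forward attention weights [B,R,C] of every fusion unit."""
        return [m.last_alpha for m in self.modules()
                if isinstance(m, SplitAttentionFuse) and m.last_alpha is not None]

    def forward_image(self, image: np.ndarray) -> dict:
        """Eval-mode forward of one [H,W] image with reflect padding to a
        pool-compatible size; probability maps are cropped back to the
        original size (embeddings stay at the padded half resolution)."""
        self.eval()
        h, w = image.shape
        mult = 2 ** (self.cfg.svc_levels - 1)
        ph = (-h) % mult
        pw = (-w) % mult
        padded = np.pad(image, ((0, ph), (0, pw)), mode="reflect") \
            if (ph or pw) else image
        out = self(Tensor(padded[None, None].astype(np.float32)))
        res = {}
        for key, t in (("svc_prob", out.svc_prob), ("dvc_prob", out.dvc_prob),
                       ("svc_embed", out.svc_embed), ("dvc_embed", out.dvc_embed)):
            if t is None:
                res[key] = None
            elif "prob" in key:
                res[key] = t.data[0, 0, :h, :w].astype(np.float64)
            else:
                res[key] = t.data[0, :, :(h + ph) // 2, :(w + pw) // 2]
        return res
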