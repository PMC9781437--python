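"""Training and inference orchestration.

Two-stage schedule: the segmentation stage trains the two-branch backbone
with the MSE + weighted contrastive objective per branch; the refinement
stage then freezes the backbone and trains the local-propagation network
with Dice loss on the fused confidence maps.  All randomness (weight init,
shuffling, augmentation, pixel sampling) derives from one root seed, so a
fixed seed on CPU reproduces every logged number bit for bit.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve
from skimage.morphology import skeletonize

from . import contrastive as ct
from .backbone import BackboneConfig, TwoBranchUNet
from .finetune import (FinetuneConfig, FinetuneNet, dice_loss_t,
                       fuse_channels)
from .metrics import dice_score
from .nn import Adam, Tensor, gather_pixels
from .phantom import ImageSample
from .preprocess import PreprocessSettings, augment, clahe_fixed_region

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class BankSettings:
    queue_len: int = 400            # T, per class
    pixels_per_class: int = 32      # enqueued per image per class
    n_pos: int = 64
    n_neg: int = 64
    anchors_per_class: int = 16
    temperature: float = 0.07
    warmup_epochs: int = 1


@dataclass(frozen=True)
class TrainConfig:
    epochs_seg: int = 200
    epochs_finetune: int = 200
    batch_size: int = 16
    lr: float = 5e-4
    weight_decay: float = 1e-4
    seed: int = 0
    annotation_mode: str = "svc_dvc"    # svc_dvc | svc_only | dvc_only
    augment: bool = True
    clahe: bool = False
    dvc_tolerance: int = 2

    def __post_init__(self):
        if self.epochs_seg < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size and lr must be positive")

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "TrainConfig":
        """Desk-scale preset: small batches, few epochs, CPU-sized network."""
        kw.setdefault("epochs_seg", 30)
        kw.setdefault("epochs_finetune", 30)
        kw.setdefault("batch_size", 4)
        # the small-batch, randomly-initialised desk-scale regime trains
        # faster at a higher Adam step size than the full-scale default
        kw.setdefault("lr", 2e-3)
        return cls(seed=seed, **kw)


@dataclass
class Checkpoint:
    model_cfg: BackboneConfig
    ft_cfg: FinetuneConfig
    train_cfg: TrainConfig
    model_state: dict
    ft_state: dict | None
    bank_states: dict
    log: list
    version: int = CHECKPOINT_VERSION

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump({
                "version": self.version,
                "model_cfg": asdict(self.model_cfg),
                "ft_cfg": asdict(self.ft_cfg),
                "train_cfg": asdict(self.train_cfg),
                "model_state": self.model_state,
                "ft_state": self.ft_state,
                "bank_states": self.bank_states,
                "log": self.log,
            }, fh)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        if d["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {d['version']}")
        return cls(model_cfg=BackboneConfig(**d["model_cfg"]),
                   ft_cfg=FinetuneConfig(**d["ft_cfg"]),
                   train_cfg=TrainConfig(**d["train_cfg"]),
                   model_state=d["model_state"], ft_state=d["ft_state"],
                   bank_states=d["bank_states"], log=d["log"])

    def build_model(self) -> TwoBranchUNet:
        mode = self.train_cfg.annotation_mode
        model = TwoBranchUNet(self.model_cfg, np.random.default_rng(0),
                              svc_enabled=mode != "dvc_only",
                              dvc_enabled=mode != "svc_only")
        model.load_state_dict(self.model_state)
        return model.eval()

    def build_finetune(self) -> FinetuneNet | None:
        if self.ft_state is None:
            return None
        net = FinetuneNet(self.ft_cfg, np.random.default_rng(0))
        net.load_state_dict(self.ft_state)
        return net.eval()


# -- dataset I/O -----------------------------------------------------------


def load_dataset(root: str | Path,
                 annotation_mode: str = "svc_dvc") -> list[ImageSample]:
    """Read the on-disk layout <root>/{train,val}/{img,gt_svc,gt_dvc}/<id>.png.

    Images are scaled to [0,1], masks binarised at 128.  In svc_only /
    dvc_only mode the absent annotation directory may be missing entirely
    and the corresponding masks are all-zero.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    samples = []
    shape = None
    for split in ("train", "val"):
        img_dir = root / split / "img"
        if not img_dir.exists():
            continue
        for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.tif*")):
            image = np.asarray(Image.open(img_path).convert("L"),
                               dtype=np.float64) / 255.0
            if shape is None:
                shape = image.shape
            elif image.shape != shape:
                raise ValueError(f"mixed resolutions: {img_path.name} is "
                                 f"{image.shape}, expected {shape}")
            masks = {}
            for kind, needed in (("gt_svc", annotation_mode != "dvc_only"),
                                 ("gt_dvc", annotation_mode != "svc_only")):
                mpath = root / split / kind / img_path.name
                if not mpath.exists():
                    if needed:
                        raise FileNotFoundError(
                            f"missing {kind} mask for image: {mpath}")
                    masks[kind] = np.zeros(shape, dtype=np.uint8)
                else:
                    masks[kind] = (np.asarray(Image.open(mpath).convert("L"))
                                   >= 128).astype(np.uint8)
            try:
                sid = int(img_path.stem)
            except ValueError:
                sid = len(samples)
            samples.append(ImageSample(image=image, svc_mask=masks["gt_svc"],
                                       dvc_mask=masks["gt_dvc"],
                                       sample_id=sid, split=split))
    if not samples:
        raise FileNotFoundError(f"no images found under {root}")
    return samples


# -- segmentation-stage training -------------------------------------------


def _contrastive_node(anchors_t: Tensor, positives, negatives,
                      tau: float) -> tuple[Tensor, float]:
    """Wrap the contrastive loss (+ its anchor gradient) as a graph node."""
    loss, grad = ct.contrastive_grad(anchors_t.data, positives, negatives, tau)
    grad32 = grad.astype(np.float32)

    def bwd(g):
        anchors_t._accum(float(g) * grad32)

    node = Tensor._make(np.float32(loss), (anchors_t,), bwd)
    return node, loss


def _branch_contrastive(embed: Tensor, labels_half: np.ndarray,
                        bank: ct.MemoryBank, bank_cfg: BankSettings,
                        rng: np.random.Generator) -> tuple[Tensor | None, float]:
    """Anchor sampling + hybrid pair construction for one branch's batch."""
    B = labels_half.shape[0]
    idx_rows, anchor_classes = [], []
    for b in range(B):
        for cls in (0, 1):
            coords = np.argwhere(labels_half[b] == cls)
            if len(coords) == 0:
                continue
            take = min(bank_cfg.anchors_per_class, len(coords))
            sel = coords[rng.choice(len(coords), size=take, replace=False)]
            for r, c in sel:
                idx_rows.append((b, r, c))
                anchor_classes.append(cls)
    if not idx_rows:
        return None, 0.0
    anchors_t = gather_pixels(embed, np.array(idx_rows))
    positives, negatives = [], []
    for i, cls in enumerate(anchor_classes):
        drawn = ct.hybrid_sample(bank, (anchors_t.data[i].astype(np.float64), cls),
                                 bank_cfg.n_pos, bank_cfg.n_neg, rng)
        if drawn is None:
            positives.append(np.empty((0, bank.dim)))
            negatives.append(np.empty((0, bank.dim)))
        else:
            positives.append(drawn[0])
            negatives.append(drawn[1])
    return _contrastive_node(anchors_t, positives, negatives,
                             bank_cfg.temperature)


def _half_labels(masks: np.ndarray) -> np.ndarray:
    """Downsample [B,H,W] masks to the half-resolution embedding grid.

    A cell is labelled vessel if any of its four pixels is vessel
    (occupancy pooling).  Nearest-neighbour subsampling would drop about
    half of a 1-px centerline and, worse, label cells that do contain
    centerline pixels as background — contradictory supervision for the
    contrastive term on the deep branch.
    """
    m = masks.astype(np.int64)
    return (m[:, ::2, ::2] | m[:, 1::2, ::2] | m[:, ::2, 1::2]
            | m[:, 1::2, 1::2])


def _mse_t(prob: Tensor, gt: np.ndarray) -> Tensor:
    diff = prob - Tensor(gt[:, None].astype(np.float32))
    return (diff * diff).mean()


def validate_model(model: TwoBranchUNet, val: list[ImageSample],
                   tolerance: int = 2) -> dict[str, float]:
    """Held-out Dice per branch (pixel-level SVC, tolerance-band DVC)."""
    svc, dvc = [], []
    for s in val:
        out = model.forward_image(s.image)
        if out["svc_prob"] is not None and s.svc_mask.any():
            svc.append(dice_score(out["svc_prob"] >= 0.5, s.svc_mask))
        if out["dvc_prob"] is not None and s.dvc_mask.any():
            dvc.append(dice_score(out["dvc_prob"] >= 0.5, s.dvc_mask,
                                  centerline=True, tolerance=tolerance))
    return {"val_dice_svc": float(np.mean(svc)) if svc else float("nan"),
            "val_dice_dvc": float(np.mean(dvc)) if dvc else float("nan")}


def train(config: TrainConfig, data: list[ImageSample],
          model_cfg: BackboneConfig | None = None,
          loss_weights: ct.LossWeights | None = None,
          bank_cfg: BankSettings | None = None,
          ft_cfg: FinetuneConfig | None = None,
          pre_cfg: PreprocessSettings | None = None,
          log_path: str | Path | None = None,
          run_finetune: bool = True) -> Checkpoint:
    """Run the full two-stage schedule and return the best-validation checkpoint."""
    model_cfg = model_cfg or BackboneConfig.tiny()
    weights = loss_weights or ct.LossWeights()
    bank_cfg = bank_cfg or BankSettings()
    ft_cfg = ft_cfg or FinetuneConfig.tiny()
    pre_cfg = pre_cfg or PreprocessSettings()
    mode = config.annotation_mode
    use_svc, use_dvc = mode != "dvc_only", mode != "svc_only"

    train_set = [s for s in data if s.split == "train"]
    val_set = [s for s in data if s.split == "val"] or train_set
    if not train_set:
        raise ValueError("empty train split")

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, sample_rng, aug_rng, ft_rng = \
        (np.random.default_rng(c) for c in ss.spawn(5))

    model = TwoBranchUNet(model_cfg, init_rng, svc_enabled=use_svc,
                          dvc_enabled=use_dvc)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    D = model_cfg.embed_dim
    banks = {}
    if use_svc:
        banks["svc"] = ct.MemoryBank(2, D, bank_cfg.queue_len, len(train_set))
    if use_dvc:
        banks["dvc"] = ct.MemoryBank(2, D, bank_cfg.queue_len, len(train_set))

    roi = pre_cfg.resolve_roi(*train_set[0].image.shape) if config.clahe \
        else None
    log: list[dict] = []
    best = (-np.inf, None)
    for epoch in range(config.epochs_seg):
        order = shuffle_rng.permutation(len(train_set))
        ep_mse = ep_nce = ep_total = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            if config.augment:
                batch = [augment(s, int(aug_rng.integers(2 ** 31)),
                                 crop_size=pre_cfg.crop_size)
                         for s in batch]
            imgs = np.stack([s.image for s in batch])
            if roi is not None:
                imgs = np.stack([clahe_fixed_region(im, roi,
                                                    pre_cfg.clip_limit,
                                                    pre_cfg.tile_grid)
                                 for im in imgs])
            x = Tensor(imgs[:, None].astype(np.float32))
            model.train()
            out = model(x)

            contrast_on = (weights.lambda_nce > 0
                           and epoch >= bank_cfg.warmup_epochs)
            total_t = None
            batch_mse = batch_nce = 0.0
            branch_data = []
            if use_svc:
                branch_data.append(("svc", out.svc_prob, out.svc_embed,
                                    np.stack([s.svc_mask for s in batch]),
                                    weights.lambda_svc))
            if use_dvc:
                branch_data.append(("dvc", out.dvc_prob, out.dvc_embed,
                                    np.stack([s.dvc_mask for s in batch]),
                                    weights.lambda_dvc))
            for name, prob, embed, masks, lam in branch_data:
                mse_t = _mse_t(prob, masks)
                batch_mse += float(mse_t.data)
                obj = mse_t
                if contrast_on:
                    node, nce_val = _branch_contrastive(
                        embed, _half_labels(masks), banks[name], bank_cfg,
                        sample_rng)
                    if node is not None:
                        obj = obj + weights.lambda_nce * node
                        batch_nce += nce_val
                term = lam * obj
                total_t = term if total_t is None else total_t + term

            if not np.isfinite(total_t.data):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss={float(total_t.data)}")
            model.zero_grad()
            total_t.backward()
            opt.step()

            # refresh the banks from the just-computed embeddings (constants)
            for name, _prob, embed, masks, _lam in branch_data:
                labels = _half_labels(masks)
                for b, s in enumerate(batch):
                    emb_np = embed.data[b].astype(np.float64)
                    picked = ct.sample_batch_pixels(
                        emb_np, labels[b], bank_cfg.pixels_per_class,
                        sample_rng, image_id=s.sample_id)
                    means = ct.class_mean_embeddings(emb_np, labels[b])
                    ct.update_bank(banks[name], picked,
                                   {(c, s.sample_id): v for c, v in means.items()})
            ep_mse += batch_mse
            ep_nce += batch_nce
            ep_total += float(total_t.data)
            n_batches += 1

        model.eval()
        record = {"stage": "seg", "epoch": epoch,
                  "loss_mse": ep_mse / n_batches,
                  "loss_nce": ep_nce / n_batches,
                  "loss_total": ep_total / n_batches}
        record.update(validate_model(model, val_set, config.dvc_tolerance))
        log.append(record)
        score = np.nansum([record["val_dice_svc"], record["val_dice_dvc"]])
        if score > best[0]:
            best = (score, model.state_dict())

    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()

    ft_state = None
    if run_finetune and config.epochs_finetune > 0 and use_svc and use_dvc:
        ftnet = FinetuneNet(ft_cfg, ft_rng)
        fused, svc_gts, dvc_gts = [], [], []
        for s in train_set:
            out = model.forward_image(s.image)
            fused.append(fuse_channels(out["svc_prob"], out["dvc_prob"],
                                       s.image))
            svc_gts.append(s.svc_mask)
            dvc_gts.append(s.dvc_mask)
        ft_log = train_finetune(ftnet, fused, svc_gts, dvc_gts,
                                epochs=config.epochs_finetune, lr=config.lr,
                                batch_size=config.batch_size, rng=ft_rng,
                                sigma=ft_cfg.sigma)
        log.extend(ft_log)
        ft_state = ftnet.state_dict()

    ckpt = Checkpoint(model_cfg=model_cfg, ft_cfg=ft_cfg, train_cfg=config,
                      model_state=model.state_dict(), ft_state=ft_state,
                      bank_states={k: b.to_state() for k, b in banks.items()},
                      log=log)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return ckpt


def train_finetune(ftnet: FinetuneNet, fused: list[np.ndarray],
                   svc_gts: list[np.ndarray], dvc_gts: list[np.ndarray],
                   epochs: int, lr: float, batch_size: int,
                   rng: np.random.Generator, sigma: float = 1e-6,
                   weight_decay: float = 0.0) -> list[dict]:
    """Train the propagation network on precomputed fused inputs."""
    opt = Adam(ftnet.parameters(), lr=lr, weight_decay=weight_decay)
    log = []
    n = len(fused)
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            fb = Tensor(np.stack([fused[i] for i in idx]).astype(np.float32))
            svc_b = np.stack([svc_gts[i] for i in idx]).astype(np.float64)
            dvc_b = np.stack([dvc_gts[i] for i in idx]).astype(np.float64)
            ftnet.train()
            loss = dice_loss_t(ftnet.forward_t(fb, "svc"), svc_b, sigma) + \
                dice_loss_t(ftnet.forward_t(fb, "dvc"), dvc_b, sigma)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"fine-tune diverged at epoch {epoch}")
            ftnet.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        log.append({"stage": "finetune", "epoch": epoch,
                    "loss_dice": ep_loss / nb})
    ftnet.eval()
    return log


# -- inference -------------------------------------------------------------


def predict(ckpt: Checkpoint, images: list[np.ndarray]) -> list[dict]:
    """Per-image probability maps, refined maps and the combined binary mask."""
    model = ckpt.build_model()
    ftnet = ckpt.build_finetune()
    results = []
    for image in images:
        out = model.forward_image(image)
        rec = {"svc_prob": out["svc_prob"], "dvc_prob": out["dvc_prob"]}
        if ftnet is not None and out["svc_prob"] is not None \
                and out["dvc_prob"] is not None:
            fused = fuse_channels(out["svc_prob"], out["dvc_prob"], image)
            ref = ftnet.refine_pair(fused)
            rec["refined_svc"] = ref["refined_svc"]
            rec["refined_dvc"] = ref["refined_dvc"]
            rec["combined_binary"] = ref["combined"]
        results.append(rec)
    return results


_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def breakpoint_count(binary_vessels: np.ndarray) -> int:
    """Endpoints of the morphological skeleton (pixels with one skeleton
    neighbour); more endpoints mean more vessel breaks."""
    sk = skeletonize(np.asarray(binary_vessels).astype(bool))
    nb = convolve(sk.astype(int), _NEIGHBOUR_KERNEL, mode="constant")
    return int(np.sum(sk & (nb == 1)))
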