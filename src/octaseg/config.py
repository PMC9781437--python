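"""YAML configuration mapped onto the typed settings objects.

The file uses dotted sections, e.g.::

    train: {epochs_seg: 30, batch_size: 4, seed: 1}
    model: {base_channels: 8, embed_dim: 16, radix: 2, cardinality: 1}
    loss:  {lambda_nce: 0.1, lambda_svc: 1.0, lambda_dvc: 1.0, temperature: 0.07}
    bank:  {size: 400, pixels_per_class: 32, n_pos: 64, n_neg: 64}
    finetune: {m: 3, channels: 32}

CLI flags override file values; unknown keys are rejected early.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .contrastive import LossWeights
from .finetune import FinetuneConfig
from .pipeline import BankSettings, TrainConfig
from .preprocess import PreprocessSettings

_ALIASES = {("bank", "size"): "queue_len", ("bank", "T"): "queue_len"}


def _build(cls, section: str, values: dict, extra_targets: dict | None = None):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, val in (values or {}).items():
        name = _ALIASES.get((section, key), key)
        if name in valid:
            kwargs[name] = tuple(val) if isinstance(val, list) else val
        elif extra_targets is not None and name in extra_targets:
            extra_targets[name] = val
        else:
            raise ValueError(f"unknown config key {section}.{key}")
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Return {'train', 'model', 'loss', 'bank', 'finetune'} settings objects."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for section, vals in (overrides or {}).items():
        raw.setdefault(section, {}).update(
            {k: v for k, v in vals.items() if v is not None})
    loss_extra = {"temperature": None}
    # `augment` keys (crop_size) live on the same settings object as CLAHE
    pre_raw = {**raw.get("preprocess", {}), **raw.get("augment", {})}
    cfg = {
        "train": _build(TrainConfig, "train", raw.get("train", {})),
        "model": _build(BackboneConfig, "model", raw.get("model", {})),
        "loss": _build(LossWeights, "loss", raw.get("loss", {}),
                       extra_targets=loss_extra),
        "bank": _build(BankSettings, "bank", raw.get("bank", {})),
        "finetune": _build(FinetuneConfig, "finetune", raw.get("finetune", {})),
        "preprocess": _build(PreprocessSettings, "preprocess", pre_raw),
    }
    if loss_extra["temperature"] is not None:
        cfg["bank"] = replace(cfg["bank"],
                              temperature=float(loss_extra["temperature"]))
    return cfg
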