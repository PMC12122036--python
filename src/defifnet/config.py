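"""Run configuration: a structured YAML schema binding all modules together.

Schema (version 1) — all sections optional, defaults follow the study
protocol (200 epochs, batch 8, lr 1e-4, decay one half, loss weights
0.7/0.3, split 7:2:1)::

    model:   {channels, bottleneck_width, num_classes, seed, fif_norm_act}
    loss:    {alpha, beta}
    train:   {epochs, batch_size, lr, lr_decay, patience}
    data:    {dir, image_size, synthetic: {mode, image_size, count, seed, ...}}
    split:   {ratio, seed}
    augment: {enabled, rotation_deg, p_hflip, p_vflip, crop_fraction,
              hair_strokes, hair_thickness, hair_darkness, hair_curvature, seed}
    output_dir: str
    seed: int

Unknown keys raise a validation error naming every offender.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .data import AugmentConfig, SplitSpec
from .network import ModelConfig
from .objective import LossWeights
from .synth import SyntheticSpec
from .train import TrainSettings

_SCHEMA: dict[str, set[str] | None] = {
    "model": {"channels", "bottleneck_width", "num_classes", "seed",
              "fif_norm_act", "depth", "input_size", "in_channels"},
    "loss": {"alpha", "beta"},
    "train": {"epochs", "batch_size", "lr", "lr_decay", "patience"},
    "data": {"dir", "image_size", "synthetic"},
    "split": {"ratio", "seed"},
    "augment": {"enabled", "rotation_deg", "p_hflip", "p_vflip",
                "crop_fraction", "hair_strokes", "hair_thickness",
                "hair_darkness", "hair_curvature", "seed"},
    "output_dir": None,
    "seed": None,
    "version": None,
}

_SYNTH_KEYS = {
    "mode", "image_size", "count", "seed", "center_jitter",
    "mean_radius_frac", "irregularity", "harmonics", "blur_sigma",
    "noise_sigma", "hair_prob", "blob_count", "blob_radius",
    "min_separation",
}


class ConfigError(ValueError):
    pass


def _tup(v):
    return tuple(v) if isinstance(v, (list, tuple)) else v


def validate(raw: dict) -> None:
    offenders = []
    for key, value in raw.items():
        if key not in _SCHEMA:
            offenders.append(key)
            continue
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(value, dict):
            for sub in value:
                if sub not in allowed:
                    offenders.append(f"{key}.{sub}")
    synth = (raw.get("data") or {}).get("synthetic") or {}
    offenders += [f"data.synthetic.{k}" for k in synth if k not in _SYNTH_KEYS]
    if offenders:
        raise ConfigError("unknown configuration keys: " + ", ".join(sorted(offenders)))


class RunConfig:
    """Parsed run configuration with typed sub-configs."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        validate(raw)
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        m = dict(raw.get("model") or {})
        if "channels" in m:
            m["channels"] = _tup(m["channels"])
            m.setdefault("depth", len(m["channels"]))
        if "input_size" in m:
            m["input_size"] = _tup(m["input_size"])
        m.setdefault("seed", self.seed)
        self.model = ModelConfig(**m)
        lo = raw.get("loss") or {}
        self.loss = LossWeights(float(lo.get("alpha", 0.7)),
                                float(lo.get("beta", 0.3)))
        tr = raw.get("train") or {}
        self.train = TrainSettings(
            epochs=int(tr.get("epochs", 200)),
            batch_size=int(tr.get("batch_size", 8)),
            lr=float(tr.get("lr", 1e-4)),
            lr_decay=float(tr.get("lr_decay", 0.5)),
            patience=int(tr.get("patience", 10)),
            weights=self.loss,
            seed=self.seed,
        )
        sp = raw.get("split") or {}
        self.split = SplitSpec(ratio=_tup(sp.get("ratio", (7.0, 2.0, 1.0))),
                               seed=int(sp.get("seed", self.seed)))
        au = dict(raw.get("augment") or {})
        self.augment_enabled = bool(au.pop("enabled", False))
        for k in ("crop_fraction", "hair_strokes", "hair_thickness",
                  "hair_darkness"):
            if k in au:
                au[k] = _tup(au[k])
        au.setdefault("seed", self.seed)
        self.augment = AugmentConfig(**au)
        d = raw.get("data") or {}
        self.data_dir = d.get("dir")
        self.image_size = _tup(d.get("image_size")) if d.get("image_size") else None
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            for k in ("image_size", "blob_count", "blob_radius"):
                if k in syn:
                    syn[k] = _tup(syn[k])
            syn.setdefault("seed", self.seed)
            self.synthetic = SyntheticSpec(**syn)
        else:
            self.synthetic = None
        self.output_dir = Path(raw.get("output_dir", "runs"))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
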