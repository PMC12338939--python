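"""Single-file experiment configuration (YAML or JSON).

One document covers the training hyperparameters, both encoder recipes,
the shared-head width, and the paths to the manifest and the descriptor
vocabulary. Loss weights may be given either as a named preset
("nt_xent_default", "info_nce_default", "unimodal") or as explicit fields.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .encoders import EncoderSpec
from .losses import LossWeights
from .training import AugmentConfig, TrainConfig

__all__ = ["ExperimentConfig", "load_experiment_config", "save_experiment_config"]


@dataclass
class ExperimentConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    image_encoder: EncoderSpec = field(
        default_factory=lambda: EncoderSpec(kind="small_conv")
    )
    text_encoder: EncoderSpec = field(
        default_factory=lambda: EncoderSpec(kind="small_text")
    )
    head_width: int = 16
    manifest_path: Optional[str] = None
    vocab_path: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "train": asdict(self.train),
            "image_encoder": _spec_dict(self.image_encoder),
            "text_encoder": _spec_dict(self.text_encoder),
            "head_width": self.head_width,
            "manifest_path": self.manifest_path,
            "vocab_path": self.vocab_path,
        }
        d["train"]["loss_weights"] = asdict(self.train.loss_weights)
        d["train"]["augmentation"] = asdict(self.train.augmentation)
        return d


def _spec_dict(spec: EncoderSpec) -> dict:
    return {
        "kind": spec.kind,
        "d": spec.d,
        "init_seed": spec.init_seed,
        "channels": list(spec.channels),
        "vocab_buckets": spec.vocab_buckets,
    }


def _parse_weights(obj) -> LossWeights:
    if obj is None:
        return LossWeights.nt_xent_default()
    if isinstance(obj, str):
        return LossWeights.preset(obj)
    if isinstance(obj, dict):
        if "preset" in obj:
            return LossWeights.preset(obj["preset"])
        return LossWeights(**obj)
    raise TypeError("loss_weights must be a preset name or a mapping")


def _parse_spec(obj: dict) -> EncoderSpec:
    obj = dict(obj)
    if "channels" in obj:
        obj["channels"] = tuple(obj["channels"])
    return EncoderSpec(**obj)


def load_experiment_config(path: Union[str, Path]) -> ExperimentConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    train_doc = dict(doc.get("train", {}))
    train_doc["loss_weights"] = _parse_weights(train_doc.get("loss_weights"))
    if "augmentation" in train_doc:
        aug = train_doc["augmentation"]
        if "rotation_angles" in aug:
            aug["rotation_angles"] = tuple(aug["rotation_angles"])
        train_doc["augmentation"] = AugmentConfig(**aug)
    return ExperimentConfig(
        train=TrainConfig(**train_doc),
        image_encoder=_parse_spec(
            doc.get("image_encoder", {"kind": "small_conv"})
        ),
        text_encoder=_parse_spec(
            doc.get("text_encoder", {"kind": "small_text"})
        ),
        head_width=int(doc.get("head_width", 16)),
        manifest_path=doc.get("manifest_path"),
        vocab_path=doc.get("vocab_path"),
    )


def save_experiment_config(cfg: ExperimentConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
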