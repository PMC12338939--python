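"""Modality encoders and the shared projection + classification head.

The two branches map images and report texts to a common embedding width
d; a single head (linear projection d -> h, then affine classifier
h -> 5) serves both modalities — weight sharing across branches is itself
an alignment mechanism. The L1/cosine/contrastive alignment losses
operate on the width-d encoder outputs (pre-projection), leaving the
shared head free to shape its own classification space.

Reference implementations are deliberately small so a full training run on
a synthetic cohort takes seconds on one CPU:

* image branch — three strided (kernel = stride) convolution blocks with
  ReLU, global average pooling, and a linear map to width d;
* text branch — a token-hash bag-of-words featurizer (CRC32 buckets,
  L2-normalized counts) followed by a linear map to width d.

Heavyweight pretrained backbones (DenseNet-class CNNs, biomedical BERT
encoders) plug in through the ``external_adapter`` kind, which wraps any
callable producing N x d features; nothing in the package requires them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor
from .core_types import LesionClass

__all__ = [
    "EncoderSpec",
    "EmbeddingBatch",
    "ImageEncoder",
    "TextEncoder",
    "AdapterEncoder",
    "SharedHead",
    "build_encoder",
    "encode_images",
    "encode_texts",
    "classify",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Recipe for building one modality encoder.

    ``kind`` selects the reference conv net (``small_conv``), the hash
    bag-of-words text encoder (``small_text``), or an external feature
    callable (``external_adapter`` with ``adapter`` set). ``init_seed``
    makes parameter initialization reproducible across repeats.
    """

    kind: str
    d: int = 32
    init_seed: int = 0
    channels: tuple[int, int, int] = (16, 32, 64)
    vocab_buckets: int = 256
    adapter: Optional[Callable[[Sequence], np.ndarray]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in ("small_conv", "small_text", "external_adapter"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.d < 2:
            raise ValueError("embedding width d must be >= 2")
        if self.kind == "external_adapter" and self.adapter is None:
            raise ValueError("external_adapter requires an adapter callable")


@dataclass
class EmbeddingBatch:
    """Fixed-size per-sample embeddings with modality tag and labels."""

    matrix: np.ndarray
    modality: str
    labels: list[LesionClass]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be N x d")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embeddings must be finite")
        if self.modality not in ("image", "text"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class _Module:
    """Base with a flat, ordered parameter dict of autodiff Tensors."""

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}

    def _add(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self.params[name] = t
        return t

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _patchify(x: Tensor, k: int) -> Tensor:
    """Rearrange (N, H, W, C) into (N, H/k, W/k, k*k*C) patch features."""
    n, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by patch {k}")
    x = x.reshape(n, h // k, k, w // k, k, c)
    x = x.transpose((0, 1, 3, 2, 4, 5))
    return x.reshape(n, h // k, w // k, k * k * c)


class ImageEncoder(_Module):
    """Three kernel-equals-stride conv blocks, global pooling, linear map.

    Accepts uint8 RGB batches of any spatial size divisible by 16; pixel
    values are scaled to [-1, 1] before the first block.
    """

    PATCHES = (4, 2, 2)

    def __init__(self, spec: EncoderSpec) -> None:
        super().__init__()
        if spec.kind != "small_conv":
            raise ValueError("ImageEncoder requires kind='small_conv'")
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        c_in = 3
        for i, (k, c_out) in enumerate(zip(self.PATCHES, spec.channels)):
            self._add(f"conv{i}_w", _glorot(rng, k * k * c_in, c_out))
            self._add(f"conv{i}_b", np.zeros(c_out))
            c_in = c_out
        self._add("out_w", _glorot(rng, c_in, spec.d))
        self._add("out_b", np.zeros(spec.d))

    def forward(self, images: np.ndarray) -> Tensor:
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError("images must be a uniform N x H x W x 3 batch")
        x = Tensor(images.astype(np.float64) / 127.5 - 1.0)
        for i, k in enumerate(self.PATCHES):
            p = _patchify(x, k)
            n, hh, ww, f = p.shape
            w = self.params[f"conv{i}_w"]
            b = self.params[f"conv{i}_b"]
            y = p.reshape(n * hh * ww, f) @ w + b
            x = y.relu().reshape(n, hh, ww, w.shape[1])
        pooled = x.mean(axis=(1, 2))
        return pooled @ self.params["out_w"] + self.params["out_b"]


# token hashing is fixed vocabulary-free featurization: CRC32 of each
# lowercased word modulo the bucket count
def _hash_features(texts: Sequence[str], buckets: int) -> np.ndarray:
    out = np.zeros((len(texts), buckets))
    for i, text in enumerate(texts):
        if not text or not text.strip():
            raise ValueError(f"report {i} is empty")
        for token in text.lower().split():
            token = token.strip(".,;:()'\"!?")
            if token:
                out[i, zlib.crc32(token.encode("utf-8")) % buckets] += 1.0
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return out / norms


class TextEncoder(_Module):
    """Hash bag-of-words featurizer followed by a linear map to width d."""

    def __init__(self, spec: EncoderSpec) -> None:
        super().__init__()
        if spec.kind != "small_text":
            raise ValueError("TextEncoder requires kind='small_text'")
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        self._add("out_w", _glorot(rng, spec.vocab_buckets, spec.d))
        self._add("out_b", np.zeros(spec.d))

    def forward(self, texts: Sequence[str]) -> Tensor:
        feats = _hash_features(texts, self.spec.vocab_buckets)
        return Tensor(feats) @ self.params["out_w"] + self.params["out_b"]


class AdapterEncoder(_Module):
    """Wraps an external feature extractor (no trainable parameters)."""

    def __init__(self, spec: EncoderSpec) -> None:
        super().__init__()
        self.spec = spec

    def forward(self, batch) -> Tensor:
        feats = np.asarray(self.spec.adapter(batch), dtype=np.float64)
        if feats.ndim != 2 or feats.shape[1] != self.spec.d:
            raise ValueError("adapter must return N x d features")
        return Tensor(feats)


def build_encoder(spec: EncoderSpec) -> _Module:
    if spec.kind == "small_conv":
        return ImageEncoder(spec)
    if spec.kind == "small_text":
        return TextEncoder(spec)
    return AdapterEncoder(spec)


class SharedHead(_Module):
    """One projection + classifier serving both modalities.

    The projection is a bias-free linear map d -> h; the classifier is
    affine h -> 5. A single parameter set exists — there are no
    per-modality copies.
    """

    N_CLASSES = 5

    def __init__(self, d: int, h: int = 16, init_seed: int = 0) -> None:
        super().__init__()
        self.d, self.h = d, h
        rng = np.random.default_rng(init_seed)
        self._add("proj_w", _glorot(rng, d, h))
        self._add("clf_w", _glorot(rng, h, self.N_CLASSES))
        self._add("clf_b", np.zeros(self.N_CLASSES))

    def project(self, emb: Tensor) -> Tensor:
        """Map encoder output to the shared alignment space."""
        return emb @ self.params["proj_w"]

    def classify_projected(self, projected: Tensor) -> Tensor:
        """Logits from an already-projected (alignment-space) embedding."""
        return projected @ self.params["clf_w"] + self.params["clf_b"]

    def logits(self, emb: Tensor) -> Tensor:
        return self.classify_projected(self.project(emb))


def _coerce_encoder(encoder, expected_kind: str):
    if isinstance(encoder, EncoderSpec):
        return build_encoder(encoder)
    return encoder


def encode_images(
    images: np.ndarray,
    encoder: Union[ImageEncoder, EncoderSpec],
    mode: str = "eval",
    labels: Optional[Sequence[LesionClass]] = None,
) -> EmbeddingBatch:
    """Encode a uniform image batch to an N x d embedding matrix.

    Both modes are deterministic for fixed parameters; ``mode`` exists so
    stochastic encoders (e.g. adapters with dropout) can honor it.
    """
    enc = _coerce_encoder(encoder, "small_conv")
    out = enc.forward(np.asarray(images))
    return EmbeddingBatch(
        matrix=out.data, modality="image", labels=list(labels or [])
    )


def encode_texts(
    reports: Sequence[str],
    encoder: Union[TextEncoder, EncoderSpec],
    mode: str = "eval",
    labels: Optional[Sequence[LesionClass]] = None,
) -> EmbeddingBatch:
    """Encode report texts to an N x d embedding matrix."""
    enc = _coerce_encoder(encoder, "small_text")
    out = enc.forward(list(reports))
    return EmbeddingBatch(
        matrix=out.data, modality="text", labels=list(labels or [])
    )


def classify(emb: EmbeddingBatch, head: SharedHead) -> np.ndarray:
    """N x 5 logits from the shared head, identical for either modality."""
    if emb.d != head.d:
        raise ValueError(f"embedding width {emb.d} != head input width {head.d}")
    return head.logits(Tensor(emb.matrix)).data
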