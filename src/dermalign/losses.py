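"""The composite co-learning objective.

Training aligns the image and text branches with five terms: a shared-head
cross-entropy per modality, an elementwise L1 penalty between paired
embeddings, a cosine penalty (1 - cos per pair), and a contrastive
self-supervised term, selectable between NT-Xent (full 2N formulation,
intra- and cross-modality negatives) and InfoNCE (symmetric, cross-modal
negatives only). L1 and cosine match the representations samplewise; the
contrastive term is what pushes non-paired samples apart.

Every public function accepts plain NumPy arrays (returning a float) or
autodiff Tensors (returning a Tensor in the training graph); the math is
written once on the Tensor ops.

Conventions fixed here: similarities are cosine for both contrastive
losses; L1 and cosine reduce by mean (keeping weights comparable across
embedding widths); labels may be integers 0..4 or LesionClass members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .autodiff import Tensor, as_tensor, cat
from .core_types import LesionClass

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "cross_entropy",
    "l1_alignment",
    "cosine_alignment",
    "nt_xent",
    "info_nce",
    "composite_loss",
]

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass(frozen=True)
class LossWeights:
    """Weights and temperature of the composite objective.

    All weights default to 1 except the SSL weight, which is 0.5 with
    temperature 0.5 for NT-Xent and 0.25 with temperature 0.07 for
    InfoNCE (use the presets).
    """

    w_ce_image: float = 1.0
    w_ce_text: float = 1.0
    w_l1: float = 1.0
    w_cos: float = 1.0
    w_ssl: float = 0.5
    ssl_kind: str = "nt_xent"
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.ssl_kind not in ("nt_xent", "info_nce"):
            raise ValueError(f"unknown ssl_kind {self.ssl_kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @classmethod
    def nt_xent_default(cls) -> "LossWeights":
        return cls(w_ssl=0.5, ssl_kind="nt_xent", tau=0.5)

    @classmethod
    def info_nce_default(cls) -> "LossWeights":
        return cls(w_ssl=0.25, ssl_kind="info_nce", tau=0.07)

    @classmethod
    def unimodal(cls) -> "LossWeights":
        """Image-only training: every text/alignment weight is zero."""
        return cls(w_ce_text=0.0, w_l1=0.0, w_cos=0.0, w_ssl=0.0)

    @classmethod
    def preset(cls, name: str) -> "LossWeights":
        presets = {
            "nt_xent_default": cls.nt_xent_default,
            "info_nce_default": cls.info_nce_default,
            "unimodal": cls.unimodal,
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}")
        return presets[name]()


@dataclass
class LossBreakdown:
    """Per-component values of one composite-loss evaluation.

    ``total`` equals the weighted sum of the components to floating
    tolerance. ``graph_total`` carries the differentiable node when the
    loss was evaluated on Tensors (None otherwise).
    """

    total: float
    ce_image: float
    ce_text: float
    l1: float
    cosine: float
    ssl: float
    graph_total: Optional[Tensor] = field(default=None, repr=False, compare=False)


def _labels_to_index(labels: Sequence) -> np.ndarray:
    idx = np.array(
        [l.index if isinstance(l, LesionClass) else int(l) for l in labels]
    )
    if idx.size and (idx.min() < 0 or idx.max() > 4):
        raise ValueError("labels must be in 0..4")
    return idx


def _maybe_float(x: Tensor, graph: bool):
    return x if graph else float(x.data)


def cross_entropy(logits: ArrayOrTensor, labels: Sequence) -> Union[float, Tensor]:
    """Mean negative log-softmax probability of the true class."""
    graph = isinstance(logits, Tensor)
    z = as_tensor(logits)
    if z.ndim != 2:
        raise ValueError("logits must be N x C")
    idx = _labels_to_index(labels)
    if len(idx) != z.shape[0]:
        raise ValueError("labels length must match logits rows")
    m = z.max_detached(axis=1, keepdims=True)
    shifted = z - m
    lse = shifted.exp().sum(axis=1).log()  # log-sum-exp, shift cancels
    true_logit = shifted[np.arange(z.shape[0]), idx]
    loss = (lse - true_logit).mean()
    return _maybe_float(loss, graph)


def _check_paired(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(
            f"paired embeddings must be equal N x d, got {a.shape} vs {b.shape}"
        )


def l1_alignment(
    emb_image: ArrayOrTensor, emb_text: ArrayOrTensor
) -> Union[float, Tensor]:
    """Mean absolute difference over all N x d entries of paired rows."""
    graph = isinstance(emb_image, Tensor) or isinstance(emb_text, Tensor)
    a, b = as_tensor(emb_image), as_tensor(emb_text)
    _check_paired(a, b)
    return _maybe_float((a - b).abs().mean(), graph)


def _row_normalize(x: Tensor, what: str) -> Tensor:
    norms = (x * x).sum(axis=1, keepdims=True).sqrt()
    if np.any(norms.data == 0.0):
        raise ValueError(f"zero-norm row in {what}")
    return x / norms


def cosine_alignment(
    emb_image: ArrayOrTensor, emb_text: ArrayOrTensor
) -> Union[float, Tensor]:
    """Mean over pairs of (1 - cosine similarity); range [0, 2]."""
    graph = isinstance(emb_image, Tensor) or isinstance(emb_text, Tensor)
    a, b = as_tensor(emb_image), as_tensor(emb_text)
    _check_paired(a, b)
    an = _row_normalize(a, "emb_image")
    bn = _row_normalize(b, "emb_text")
    cos = (an * bn).sum(axis=1)
    return _maybe_float((1.0 - cos).mean(), graph)


def nt_xent(
    emb_image: ArrayOrTensor, emb_text: ArrayOrTensor, tau: float = 0.5
) -> Union[float, Tensor]:
    """Normalized temperature-scaled cross entropy over 2N views.

    Both matrices are stacked into 2N rows; (image_i, text_i) are the
    positive pairs. Each of the 2N anchors contrasts its positive against
    every other row — intra- and cross-modality alike — under cosine
    similarity scaled by ``tau``. With N = 1 the sole candidate is the
    positive and the loss is exactly 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    graph = isinstance(emb_image, Tensor) or isinstance(emb_text, Tensor)
    a, b = as_tensor(emb_image), as_tensor(emb_text)
    _check_paired(a, b)
    n = a.shape[0]
    z = cat([_row_normalize(a, "emb_image"), _row_normalize(b, "emb_text")])
    sims = (z @ z.T) / tau  # (2N, 2N)
    two_n = 2 * n
    off_diag = 1.0 - np.eye(two_n)
    # detached per-anchor max over candidates, for a stable log-sum-exp
    m = np.where(off_diag > 0, sims.data, -np.inf).max(axis=1, keepdims=True)
    expv = (sims - m).exp() * off_diag
    denom = expv.sum(axis=1).log() + Tensor(m[:, 0])
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    num = sims[np.arange(two_n), pos]
    return _maybe_float((denom - num).mean(), graph)


def info_nce(
    emb_image: ArrayOrTensor, emb_text: ArrayOrTensor, tau: float = 0.07
) -> Union[float, Tensor]:
    """Symmetric cross-modal InfoNCE.

    Image-to-text: each image row scores against all N text rows (its own
    as positive, the other N-1 as negatives); text-to-image symmetric; the
    result is the mean of the two directional means. N = 1 gives 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    graph = isinstance(emb_image, Tensor) or isinstance(emb_text, Tensor)
    a, b = as_tensor(emb_image), as_tensor(emb_text)
    _check_paired(a, b)
    n = a.shape[0]
    an = _row_normalize(a, "emb_image")
    bn = _row_normalize(b, "emb_text")
    sims = (an @ bn.T) / tau  # (N, N); rows: images, cols: texts
    diag = (np.arange(n), np.arange(n))

    def directional(s: Tensor) -> Tensor:
        m = s.max_detached(axis=1, keepdims=True)
        lse = (s - m).exp().sum(axis=1).log() + Tensor(m[:, 0])
        return (lse - s[diag]).mean()

    loss = (directional(sims) + directional(sims.T)) / 2.0
    return _maybe_float(loss, graph)


def composite_loss(
    logits_image: ArrayOrTensor,
    logits_text: Optional[ArrayOrTensor],
    labels: Sequence,
    emb_image: Optional[ArrayOrTensor],
    emb_text: Optional[ArrayOrTensor],
    weights: LossWeights,
) -> LossBreakdown:
    """Weighted sum of the five terms with a per-component breakdown.

    Text-side arguments may be None when every text/alignment weight is
    zero (unimodal training); the corresponding components report 0.
    """
    graph = isinstance(logits_image, Tensor)
    zero = Tensor(0.0)

    ce_img = as_tensor(cross_entropy(logits_image, labels))
    text_needed = (
        weights.w_ce_text != 0.0
        or weights.w_l1 != 0.0
        or weights.w_cos != 0.0
        or weights.w_ssl != 0.0
    )
    if text_needed:
        if logits_text is None or emb_image is None or emb_text is None:
            raise ValueError(
                "text logits and paired embeddings required unless all "
                "text/alignment weights are zero"
            )
        ce_txt = as_tensor(cross_entropy(logits_text, labels))
        l1 = as_tensor(l1_alignment(emb_image, emb_text))
        cos = as_tensor(cosine_alignment(emb_image, emb_text))
        if weights.ssl_kind == "nt_xent":
            ssl = as_tensor(nt_xent(emb_image, emb_text, weights.tau))
        else:
            ssl = as_tensor(info_nce(emb_image, emb_text, weights.tau))
    else:
        ce_txt = l1 = cos = ssl = zero

    total = (
        weights.w_ce_image * ce_img
        + weights.w_ce_text * ce_txt
        + weights.w_l1 * l1
        + weights.w_cos * cos
        + weights.w_ssl * ssl
    )
    return LossBreakdown(
        total=float(total.data),
        ce_image=float(ce_img.data),
        ce_text=float(ce_txt.data),
        l1=float(l1.data),
        cosine=float(cos.data),
        ssl=float(ssl.data),
        graph_total=total if graph else None,
    )
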