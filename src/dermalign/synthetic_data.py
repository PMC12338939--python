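"""Synthetic paired (image, metadata) cohorts.

Every other module is testable without real dermatology data because this
generator emulates the interface of a curated cohort: five classes, each
rendered as a parametric visual motif on a skin-tone background, with
metadata (raw class string, optional subclass) from which the report
generator produces genuinely class-informative text.

Motifs are crude analogues of lesion morphology:

* NEV — filled ellipse (nevus-like compact pigmentation)
* MEL — ragged star polygon (irregular border)
* BCC — ring / annulus (rolled border, pale center)
* ACK — stippled patch (keratotic speckling)
* BEK — scaly checker patch (verrucous surface)

each with a class base color. ``motif_separation`` interpolates the five
base colors between a common average (0, maximally confusable) and the
full palette (1, maximally distinct); ``noise_sd`` adds Gaussian pixel
noise as a fraction of the 8-bit dynamic range. A nearest-prototype color
rule (`rule_based_classify`) certifies that class signal exists: with zero
noise and full separation it recovers every label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image

from .core_types import (
    DatasetManifest,
    LesionClass,
    LesionRecord,
    SubclassMap,
    aggregate_manifest,
    write_manifest_csv,
)
from .report_synthesis import (
    DescriptorVocabulary,
    ReportPair,
    TemplateSynthesizer,
    make_report_pair,
)

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "split_cohort",
    "rule_based_classify",
    "write_cohort",
]

# full-separation palette (RGB), chosen distinct under the color rule
_BASE_COLORS = {
    LesionClass.BEK: np.array([165.0, 125.0, 70.0]),   # tan, hyperkeratotic
    LesionClass.NEV: np.array([120.0, 75.0, 45.0]),    # medium brown
    LesionClass.ACK: np.array([205.0, 95.0, 90.0]),    # erythematous pink-red
    LesionClass.BCC: np.array([235.0, 130.0, 120.0]),  # pearly pink
    LesionClass.MEL: np.array([50.0, 35.0, 35.0]),     # dark brown-black
}
_BACKGROUND = np.array([222.0, 184.0, 158.0])  # skin tone


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a moderately difficult task: visible class overlap from
    partial color separation plus light pixel noise, so a small image
    classifier is challenged while the paired reports stay perfectly
    class-informative.
    """

    n_per_class: int = 40
    image_size: int = 64
    noise_sd: float = 0.15
    subclass_rate: float = 0.3
    motif_separation: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0.0 <= self.subclass_rate <= 1.0:
            raise ValueError("subclass_rate must be in [0, 1]")
        if not 0.0 <= self.motif_separation <= 1.0:
            raise ValueError("motif_separation must be in [0, 1]")


@dataclass
class SynthCohort:
    """Generated records plus their report pairs and ground truth."""

    records: list[LesionRecord]
    reports: dict[str, ReportPair]
    truth: dict[str, LesionClass]
    config: SynthConfig = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.records)


def class_palette(separation: float) -> dict[LesionClass, np.ndarray]:
    """Base colors pulled toward their common mean by 1 - separation."""
    mean = np.mean(list(_BASE_COLORS.values()), axis=0)
    return {
        c: mean + separation * (col - mean) for c, col in _BASE_COLORS.items()
    }


def _motif_mask(
    cls: LesionClass, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean lesion mask for one sample, with jittered geometry."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = size / 2 + rng.uniform(-size / 10, size / 10)
    cx = size / 2 + rng.uniform(-size / 10, size / 10)
    r0 = size * rng.uniform(0.22, 0.30)
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)

    if cls is LesionClass.NEV:
        a = r0 * rng.uniform(0.8, 1.2)
        b = r0 * rng.uniform(0.8, 1.2)
        theta = rng.uniform(0, np.pi)
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if cls is LesionClass.MEL:
        k = 12
        radii = r0 * (1.0 + rng.uniform(-0.4, 0.4, size=k))
        ang = np.arctan2(dy, dx)  # [-pi, pi]
        idx = ((ang + np.pi) / (2 * np.pi) * k).astype(int) % k
        frac = (ang + np.pi) / (2 * np.pi) * k - idx
        r_theta = radii[idx] * (1 - frac) + radii[(idx + 1) % k] * frac
        return dist <= r_theta
    if cls is LesionClass.BCC:
        outer = r0 * rng.uniform(1.0, 1.2)
        inner = outer * rng.uniform(0.45, 0.6)
        return (dist <= outer) & (dist >= inner)
    if cls is LesionClass.ACK:
        disk = dist <= r0 * 1.15
        stipple = rng.random((size, size)) < 0.5
        return disk & stipple
    # BEK: scaly checker inside a disk
    disk = dist <= r0 * 1.15
    cell = max(2, size // 16)
    checker = ((yy // cell).astype(int) + (xx // cell).astype(int)) % 2 == 0
    return disk & checker


def render_image(
    cls: LesionClass, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """One H x W x 3 uint8 sample of the class motif."""
    size = cfg.image_size
    palette = class_palette(cfg.motif_separation)
    img = np.empty((size, size, 3))
    img[:] = _BACKGROUND + rng.normal(0.0, 5.0, size=3)
    mask = _motif_mask(cls, size, rng)
    color = palette[cls] + rng.normal(0.0, 8.0, size=3)
    img[mask] = color
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd * 255.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _subclasses_by_class() -> dict[LesionClass, list[str]]:
    inv: dict[LesionClass, list[str]] = {c: [] for c in LesionClass}
    for name, cls in SubclassMap.default().entries.items():
        inv[cls].append(name)
    return {c: sorted(v) for c, v in inv.items()}


def generate_cohort(
    cfg: SynthConfig, vocab: Optional[DescriptorVocabulary] = None
) -> SynthCohort:
    """Render ``n_per_class`` samples per class with paired reports.

    Deterministic given ``cfg.seed``: images, metadata and reports are all
    drawn from one seeded generator. Records start in the training
    partition; use `split_cohort` to partition.

    Reports use the class-conditioned synthesizer, so descriptor fields —
    not just the class name — are informative about the image class, as
    they would be in reports written from diagnostic metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = vocab or DescriptorVocabulary.default()
    backend = TemplateSynthesizer.class_conditioned()
    sub_pool = _subclasses_by_class()
    records: list[LesionRecord] = []
    reports: dict[str, ReportPair] = {}
    truth: dict[str, LesionClass] = {}
    for cls in LesionClass:
        for i in range(cfg.n_per_class):
            rid = f"syn-{cls.code.lower()}-{i:04d}"
            image = render_image(cls, cfg, rng)
            subclass = None
            if sub_pool[cls] and rng.random() < cfg.subclass_rate:
                subclass = sub_pool[cls][int(rng.integers(len(sub_pool[cls])))]
            modality = "dermoscopic" if rng.random() < 0.7 else "clinical"
            report_seed = int(rng.integers(2**31))
            records.append(
                LesionRecord(
                    record_id=rid,
                    image=image,
                    source="synthetic",
                    modality=modality,
                    raw_class=cls.display_name,
                    raw_subclass=subclass,
                    label=cls,
                    partition="training",
                )
            )
            reports[rid] = make_report_pair(
                cls, subclass, vocab, report_seed, backend
            )
            truth[rid] = cls
    return SynthCohort(records=records, reports=reports, truth=truth, config=cfg)


def split_cohort(
    cohort: SynthCohort,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetManifest:
    """Stratified (by class) split into training/validation/testing.

    Partitions are disjoint and exhaustive; per class, floor(n * f) records
    go to training and validation and the remainder to testing.
    """
    if any(f < 0 or f > 1 for f in fractions) or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be in [0, 1] and sum to 1")
    rng = np.random.default_rng(seed)
    f_tr, f_va, _ = fractions
    out: list[LesionRecord] = []
    by_class: dict[LesionClass, list[LesionRecord]] = {c: [] for c in LesionClass}
    for r in cohort.records:
        by_class[r.label].append(r)
    for cls in LesionClass:
        group = list(by_class[cls])
        order = rng.permutation(len(group))
        n = len(group)
        n_tr = int(np.floor(f_tr * n + 1e-9))
        n_va = int(np.floor(f_va * n + 1e-9))
        for rank, j in enumerate(order):
            if rank < n_tr:
                part = "training"
            elif rank < n_tr + n_va:
                part = "validation"
            else:
                part = "testing"
            out.append(group[j].with_partition(part))
    return aggregate_manifest(out)


def rule_based_classify(
    images: Sequence[np.ndarray],
    cfg: SynthConfig,
    mask_threshold: float = 25.0,
) -> list[LesionClass]:
    """Hand-written pixel-statistic classifier (the class-signal oracle).

    Per image: estimate the background color from the four corner patches,
    mask pixels whose color sits further from that estimate than both
    ``mask_threshold`` and the 99th percentile of the corner pixels' own
    distances (an empirical noise floor), and assign the class whose
    palette color (at the cohort's separation) is nearest to the masked
    mean color. Not a learned model — it certifies that the rendered class
    signal exists and that pixel noise degrades it.
    """
    palette = class_palette(cfg.motif_separation)
    classes = list(LesionClass)
    cmat = np.stack([palette[c] for c in classes])
    k = max(4, cfg.image_size // 8)
    out = []
    for img in images:
        x = np.asarray(img, dtype=float)
        corners = np.concatenate(
            [
                x[:k, :k].reshape(-1, 3),
                x[:k, -k:].reshape(-1, 3),
                x[-k:, :k].reshape(-1, 3),
                x[-k:, -k:].reshape(-1, 3),
            ]
        )
        bg = np.median(corners, axis=0)
        corner_dist = np.linalg.norm(corners - bg, axis=1)
        threshold = max(mask_threshold, float(np.percentile(corner_dist, 99)))
        dist_bg = np.linalg.norm(x - bg, axis=2)
        mask = dist_bg > threshold
        v = x[mask].mean(axis=0) if mask.any() else x.reshape(-1, 3).mean(axis=0)
        out.append(classes[int(np.argmin(np.linalg.norm(cmat - v, axis=1)))])
    return out


def write_cohort(
    cohort: SynthCohort,
    out_dir: Union[str, Path],
    manifest: Optional[DatasetManifest] = None,
) -> Path:
    """Materialize a cohort as images/ + manifest.csv + reports.jsonl.

    The on-disk layout is interface-identical to a real cohort: PNG files
    referenced by relative path from the manifest's directory.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    records = manifest.records if manifest is not None else cohort.records
    on_disk = []
    for r in records:
        rel = f"images/{r.record_id}.png"
        if isinstance(r.image, np.ndarray):
            Image.fromarray(r.image).save(out_dir / rel)
        on_disk.append(
            LesionRecord(
                record_id=r.record_id,
                image=rel,
                source=r.source,
                modality=r.modality,
                raw_class=r.raw_class,
                raw_subclass=r.raw_subclass,
                label=r.label,
                partition=r.partition,
            )
        )
    write_manifest_csv(aggregate_manifest(on_disk), out_dir / "manifest.csv")
    with (out_dir / "reports.jsonl").open("w", encoding="utf-8") as fh:
        for r in on_disk:
            pair = cohort.reports[r.record_id]
            fh.write(
                json.dumps(
                    {
                        "record_id": r.record_id,
                        "structured": pair.structured,
                        "synthesized": pair.synthesized,
                        "descriptor_choices": pair.descriptor_choices,
                        "seed": pair.seed,
                    }
                )
                + "\n"
            )
    return out_dir
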