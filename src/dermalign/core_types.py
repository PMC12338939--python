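"""Domain vocabulary for the skin-lesion co-learning pipeline.

The five diagnostic classes, the per-record metadata model, label
normalization (raw metadata strings -> canonical class, optionally via a
subclass mapping), and manifest accounting over (partition, source, class).
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np

__all__ = [
    "LesionClass",
    "LesionRecord",
    "DatasetManifest",
    "SubclassMap",
    "UnmappableLabel",
    "DuplicateRecordId",
    "ManifestFormatError",
    "PARTITIONS",
    "MODALITIES",
    "normalize_label",
    "aggregate_manifest",
    "read_manifest_csv",
    "write_manifest_csv",
]

PARTITIONS = ("training", "validation", "testing")
MODALITIES = ("dermoscopic", "clinical")


class UnmappableLabel(ValueError):
    """Raised when neither raw_class nor raw_subclass resolves to a class."""


class DuplicateRecordId(ValueError):
    """Raised when two records in a manifest share a record_id."""


class ManifestFormatError(ValueError):
    """Raised for malformed manifest CSV content."""


class LesionClass(enum.Enum):
    """The five diagnostic classes, each with a malignancy grade.

    BEK and NEV are benign, ACK is pre-malignant, BCC and MEL are malignant.
    """

    BEK = ("benign keratosis", "benign")
    NEV = ("benign nevus", "benign")
    ACK = ("actinic keratosis", "pre-malignant")
    BCC = ("basal-cell cancer", "malignant")
    MEL = ("melanoma", "malignant")

    def __init__(self, display_name: str, malignancy: str) -> None:
        self.display_name = display_name
        self.malignancy = malignancy

    @property
    def code(self) -> str:
        return self.name

    @property
    def index(self) -> int:
        """Stable integer index 0..4 in declaration order (BEK..MEL)."""
        return list(LesionClass).index(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LesionClass.{self.name}"


def _norm(text: str) -> str:
    return " ".join(text.strip().lower().split())


@dataclass(frozen=True)
class SubclassMap:
    """User-extensible mapping from normalized subclass strings to classes.

    Ships with the two authoritative entries (melanocytic nevus -> NEV,
    bowen's disease -> ACK) plus common synonyms; metadata vocabularies of
    real sources vary, so the table is open for extension.
    """

    entries: Mapping[str, LesionClass] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "SubclassMap":
        e = {
            "melanocytic nevus": LesionClass.NEV,
            "bowen's disease": LesionClass.ACK,
            "bowens disease": LesionClass.ACK,
            "nevus": LesionClass.NEV,
            "naevus": LesionClass.NEV,
            "dysplastic nevus": LesionClass.NEV,
            "seborrheic keratosis": LesionClass.BEK,
            "solar lentigo": LesionClass.BEK,
            "lichenoid keratosis": LesionClass.BEK,
            "lentigo maligna": LesionClass.MEL,
            "nodular melanoma": LesionClass.MEL,
            "superficial spreading melanoma": LesionClass.MEL,
            "nodular basal cell carcinoma": LesionClass.BCC,
            "superficial basal cell carcinoma": LesionClass.BCC,
            "actinic cheilitis": LesionClass.ACK,
        }
        return cls(entries=e)

    def extended(self, extra: Mapping[str, LesionClass]) -> "SubclassMap":
        merged = dict(self.entries)
        merged.update({_norm(k): v for k, v in extra.items()})
        return SubclassMap(entries=merged)

    def lookup(self, subclass: str) -> Optional[LesionClass]:
        return self.entries.get(_norm(subclass))


# direct aliases for raw_class strings, beyond codes and display names
_CLASS_ALIASES = {
    "melanoma": LesionClass.MEL,
    "basal cell carcinoma": LesionClass.BCC,
    "basal cell cancer": LesionClass.BCC,
    "basal-cell carcinoma": LesionClass.BCC,
    "actinic keratosis": LesionClass.ACK,
    "benign keratosis": LesionClass.BEK,
    "benign nevus": LesionClass.NEV,
}


def normalize_label(
    raw_class: str,
    raw_subclass: Optional[str] = None,
    map: Optional[SubclassMap] = None,
) -> LesionClass:
    """Resolve raw metadata strings to one of the five classes.

    Resolution order: exact normalized match on class codes, display names
    and aliases first; the subclass mapping is consulted only when
    ``raw_class`` does not resolve directly. Matching is case- and
    whitespace-insensitive and deterministic.

    Raises
    ------
    UnmappableLabel
        If neither ``raw_class`` nor ``raw_subclass`` resolves.
    """
    if not raw_class or not raw_class.strip():
        raise UnmappableLabel("raw_class must be non-empty")
    submap = map if map is not None else SubclassMap.default()
    key = _norm(raw_class)
    for cls in LesionClass:
        if key == cls.code.lower() or key == cls.display_name:
            return cls
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    hit = submap.lookup(raw_class)
    if hit is not None:
        return hit
    if raw_subclass is not None and raw_subclass.strip():
        hit = submap.lookup(raw_subclass)
        if hit is not None:
            return hit
    raise UnmappableLabel(
        f"cannot map raw_class={raw_class!r}, raw_subclass={raw_subclass!r}"
    )


@dataclass
class LesionRecord:
    """One lesion image plus its metadata.

    ``image`` is either an H x W x 3 uint8 array or a path to a PNG/JPEG;
    paths are interpreted relative to the manifest's directory when read
    from CSV.
    """

    record_id: str
    image: Union[np.ndarray, str, Path]
    source: str
    modality: str
    raw_class: str
    label: LesionClass
    partition: str
    raw_subclass: Optional[str] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.partition not in PARTITIONS:
            raise ValueError(f"unknown partition {self.partition!r}")
        if isinstance(self.image, np.ndarray):
            if self.image.ndim != 3 or self.image.shape[2] != 3:
                raise ValueError("image array must be H x W x 3")
            if self.image.shape[0] < 8 or self.image.shape[1] < 8:
                raise ValueError("image must be at least 8 x 8")

    def with_partition(self, partition: str) -> "LesionRecord":
        return replace(self, partition=partition)


@dataclass
class DatasetManifest:
    """A record collection with exact (partition, source, class) tallies."""

    records: list[LesionRecord]
    counts: dict[tuple[str, str, LesionClass], int]

    def partition_records(self, partition: str) -> list[LesionRecord]:
        return [r for r in self.records if r.partition == partition]

    def partition_total(self, partition: str) -> int:
        return sum(
            n for (p, _, _), n in self.counts.items() if p == partition
        )

    def class_counts(self, partition: str) -> dict[LesionClass, int]:
        out: dict[LesionClass, int] = {c: 0 for c in LesionClass}
        for (p, _, cls), n in self.counts.items():
            if p == partition:
                out[cls] += n
        return out

    def sources(self) -> list[str]:
        return sorted({r.source for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


def aggregate_manifest(records: Iterable[LesionRecord]) -> DatasetManifest:
    """Tally records into a manifest; totals are additive over keys.

    Raises
    ------
    DuplicateRecordId
        If two records share a record_id.
    """
    records = list(records)
    seen = Counter(r.record_id for r in records)
    dups = [rid for rid, n in seen.items() if n > 1]
    if dups:
        raise DuplicateRecordId(f"duplicate record ids: {dups[:5]}")
    counts: Counter = Counter(
        (r.partition, r.source, r.label) for r in records
    )
    return DatasetManifest(records=records, counts=dict(counts))


_CSV_COLUMNS = [
    "record_id",
    "image_path",
    "source",
    "modality",
    "raw_class",
    "raw_subclass",
    "partition",
]


def write_manifest_csv(manifest: DatasetManifest, path: Union[str, Path]) -> None:
    """Write the manifest as UTF-8 CSV with the canonical header.

    Array-backed images are not serialized; their records must carry a
    path-backed ``image`` (as produced by the cohort writer).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in manifest.records:
            if isinstance(r.image, np.ndarray):
                raise ManifestFormatError(
                    f"record {r.record_id}: in-memory image has no path"
                )
            writer.writerow(
                [
                    r.record_id,
                    str(r.image),
                    r.source,
                    r.modality,
                    r.raw_class,
                    r.raw_subclass or "",
                    r.partition,
                ]
            )


def read_manifest_csv(
    path: Union[str, Path],
    subclass_map: Optional[SubclassMap] = None,
) -> DatasetManifest:
    """Read a manifest CSV; labels are re-derived from the raw strings.

    Image paths stay relative strings; resolve them against the manifest's
    directory when loading pixels.
    """
    path = Path(path)
    records: list[LesionRecord] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CSV_COLUMNS if c not in header]
        if missing:
            raise ManifestFormatError(f"missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            partition = row["partition"].strip()
            if partition not in PARTITIONS:
                raise ManifestFormatError(
                    f"row {i}: unknown partition {partition!r}"
                )
            modality = row["modality"].strip()
            if modality not in MODALITIES:
                raise ManifestFormatError(
                    f"row {i}: unknown modality {modality!r}"
                )
            raw_subclass = row["raw_subclass"].strip() or None
            label = normalize_label(
                row["raw_class"], raw_subclass, subclass_map
            )
            records.append(
                LesionRecord(
                    record_id=row["record_id"],
                    image=row["image_path"],
                    source=row["source"],
                    modality=modality,
                    raw_class=row["raw_class"],
                    raw_subclass=raw_subclass,
                    label=label,
                    partition=partition,
                )
            )
    return aggregate_manifest(records)
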