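"""Composition of the reference multi-source skin-lesion study.

The per-source, per-class record counts of the curated five-class cohort
(training/validation from five sources; testing additionally from six
external sources), as published with the study. Only the counts are
shipped — acquiring the underlying images is outside this package's
scope — but they drive manifest-accounting checks and the inverse-
frequency class weights of the balanced sampler.
"""

from __future__ import annotations

from .core_types import (
    DatasetManifest,
    LesionClass,
    LesionRecord,
    aggregate_manifest,
)

__all__ = ["STUDY_COMPOSITION", "SOURCE_MODALITY", "study_manifest"]

_CLASS_ORDER = (
    LesionClass.BEK,
    LesionClass.NEV,
    LesionClass.ACK,
    LesionClass.BCC,
    LesionClass.MEL,
)

# (partition, source) -> counts in class order BEK, NEV, ACK, BCC, MEL
STUDY_COMPOSITION: dict[str, dict[str, tuple[int, int, int, int, int]]] = {
    "training": {
        "BCN20000": (796, 2944, 515, 1966, 1999),
        "Derm12345": (430, 1683, 16, 291, 263),
        "DDI": (22, 22, 0, 7, 5),
        "Derm7pt": (46, 18, 0, 26, 160),
        "DermNet": (171, 39, 38, 133, 62),
    },
    "validation": {
        "BCN20000": (170, 630, 110, 421, 428),
        "Derm12345": (110, 455, 13, 47, 55),
        # the published Derm7pt MEL cell (60) disagrees with both its row
        # total (110) and the MEL column total (562); 69 reconciles all
        # printed marginals and is used here
        "Derm7pt": (21, 8, 0, 12, 69),
        "DermNet": (25, 7, 6, 19, 10),
    },
    "testing": {
        "BCN20000": (172, 632, 112, 422, 430),
        "Derm12345": (135, 534, 8, 85, 82),
        "Derm7pt": (13, 5, 0, 7, 45),
        "DermNet": (49, 11, 11, 38, 18),
        "HAM10000": (1338, 7737, 378, 622, 1305),
        "SKINL2": (33, 97, 0, 40, 28),
        "Fitzpatrick17k": (30, 39, 5, 36, 115),
        "Buenos Aires": (88, 602, 63, 340, 253),
        "SD198": (60, 32, 62, 13, 38),
        "PAD UFES 20": (52, 68, 13, 64, 26),
    },
}

SOURCE_MODALITY = {
    "BCN20000": "dermoscopic",
    "Derm12345": "dermoscopic",
    "DDI": "clinical",
    "Derm7pt": "clinical",
    "DermNet": "clinical",
    "HAM10000": "dermoscopic",
    "SKINL2": "dermoscopic",
    "Fitzpatrick17k": "clinical",
    "Buenos Aires": "dermoscopic",
    "SD198": "clinical",
    "PAD UFES 20": "clinical",
}


def study_manifest() -> DatasetManifest:
    """The study composition expanded into stub records and aggregated.

    Records carry placeholder image paths (the real images are not
    distributed); the manifest's counts therefore reproduce the published
    per-source tallies exactly and the partition totals are recomputed by
    aggregation, not hard-coded.
    """
    records: list[LesionRecord] = []
    for partition, sources in STUDY_COMPOSITION.items():
        for source, counts in sources.items():
            for cls, n in zip(_CLASS_ORDER, counts):
                slug = source.lower().replace(" ", "-")
                for i in range(n):
                    rid = f"{partition[:2]}-{slug}-{cls.code.lower()}-{i:05d}"
                    records.append(
                        LesionRecord(
                            record_id=rid,
                            image=f"images/{rid}.png",
                            source=source,
                            modality=SOURCE_MODALITY[source],
                            raw_class=cls.display_name,
                            label=cls,
                            partition=partition,
                        )
                    )
    return aggregate_manifest(records)
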