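"""Report generation from lesion metadata.

Two report renditions per record: a *structured* report filled from a fixed
template (malignancy grade + class display name + optional subclass), and a
*synthesized* report that extends the structured sentence with descriptor
clauses drawn from a closed controlled vocabulary. Constraining every
descriptor to a closed option set is the anti-hallucination defense that
makes a deterministic synthesizer a faithful stand-in for an LLM backend;
the backend interface below is the plug-in point for a generative model.

Report *turnover* — randomly substituting one rendition for the other while
training — is the text-side augmentation.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .core_types import LesionClass

__all__ = [
    "ReportPair",
    "DescriptorVocabulary",
    "EmptyVocabularyField",
    "ReportBackend",
    "TemplateSynthesizer",
    "make_structured_report",
    "make_synthesized_report",
    "augment_report",
]


class EmptyVocabularyField(ValueError):
    """Raised when a vocabulary field offers fewer than two options."""


@dataclass(frozen=True)
class DescriptorVocabulary:
    """Ordered closed option sets, one per descriptor field.

    Field order is significant: synthesized reports emit one clause per
    field in vocabulary order, which keeps output byte-stable.
    """

    fields: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for name, options in self.fields:
            if len(options) < 2:
                raise EmptyVocabularyField(
                    f"field {name!r} needs >= 2 options, got {len(options)}"
                )

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.fields)

    def options(self, name: str) -> tuple[str, ...]:
        for fname, opts in self.fields:
            if fname == name:
                return opts
        raise KeyError(name)

    @classmethod
    def from_mapping(
        cls, mapping: dict[str, Sequence[str]]
    ) -> "DescriptorVocabulary":
        return cls(
            fields=tuple(
                (name, tuple(str(o) for o in opts))
                for name, opts in mapping.items()
            )
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DescriptorVocabulary":
        with Path(path).open("r", encoding="utf-8") as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise EmptyVocabularyField("vocabulary file must map fields to lists")
        return cls.from_mapping(mapping)

    @classmethod
    def default(cls) -> "DescriptorVocabulary":
        """The packaged version-1 vocabulary (four dermoscopy fields)."""
        ref = resources.files("dermalign.data") / "descriptor_vocabulary.yaml"
        mapping = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class ReportPair:
    """The two text renditions of one record's metadata."""

    structured: str
    synthesized: str
    descriptor_choices: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.structured or not self.synthesized:
            raise ValueError("both report texts must be non-empty")


def make_structured_report(
    label: LesionClass, subclass: Optional[str] = None
) -> str:
    """Fill the fixed template from the class metadata.

    'The image includes a {malignancy} skin lesion, specifically a
    {display name}', with ' (specifically a {subclass})' appended only when
    a subclass is present. The malignancy slot renders the full three-way
    grade, so pre-malignant classes read 'pre-malignant'.
    """
    text = (
        f"The image includes a {label.malignancy} skin lesion, "
        f"specifically a {label.display_name}"
    )
    if subclass is not None and subclass.strip():
        text += f" (specifically a {subclass.strip()})"
    return text


# clause templates per known descriptor field; unknown fields fall back to
# a generic phrasing built from the field name
_CLAUSE_TEMPLATES = {
    "skin_structure": "The skin structure is {}.",
    "image_color": "The image color is mostly {}.",
    "dermoscopic_structures": "Dermoscopic structures include {}.",
    "symmetry": "The lesion is {}.",
}


def _clause(field_name: str, option: str) -> str:
    template = _CLAUSE_TEMPLATES.get(
        field_name, "The " + field_name.replace("_", " ") + " is {}."
    )
    return template.format(option)


class ReportBackend(abc.ABC):
    """Text-generation backend interface for synthesized reports.

    The default implementation is the deterministic template synthesizer;
    a generative model can be plugged in by implementing ``synthesize``.
    Implementations must only emit descriptor strings from the vocabulary.
    """

    @abc.abstractmethod
    def synthesize(
        self,
        label: LesionClass,
        subclass: Optional[str],
        vocab: DescriptorVocabulary,
        seed: int,
    ) -> tuple[str, dict[str, str]]:
        """Return (report text, descriptor choices)."""


class TemplateSynthesizer(ReportBackend):
    """Deterministic synthesizer: seeded choice per field.

    Without a profile every option is drawn uniformly. With a
    class-conditioned profile — mapping each class to its typical options
    per field — a preferred option is drawn with probability
    ``preference`` (uniform within the preferred subset) and any option
    uniformly otherwise. The profile emulates a report writer who knows
    the diagnosis: descriptor fields then carry class signal, the way
    morphology wording in real reports does, while every choice still
    stays inside the closed vocabulary.
    """

    def __init__(
        self,
        profile: Optional[dict[LesionClass, dict[str, tuple[str, ...]]]] = None,
        preference: float = 0.8,
    ) -> None:
        if not 0.0 <= preference <= 1.0:
            raise ValueError("preference must be in [0, 1]")
        self.profile = profile
        self.preference = preference

    @classmethod
    def class_conditioned(cls, preference: float = 0.8) -> "TemplateSynthesizer":
        """Synthesizer whose descriptors reflect the lesion class."""
        return cls(profile=CLASS_DESCRIPTOR_PROFILE, preference=preference)

    def _pick(
        self,
        label: LesionClass,
        field_name: str,
        options: tuple[str, ...],
        rng: np.random.Generator,
    ) -> str:
        preferred = None
        if self.profile is not None:
            preferred = [
                o for o in self.profile.get(label, {}).get(field_name, ())
                if o in options
            ]
        if preferred and rng.random() < self.preference:
            return preferred[int(rng.integers(len(preferred)))]
        return options[int(rng.integers(len(options)))]

    def synthesize(
        self,
        label: LesionClass,
        subclass: Optional[str],
        vocab: DescriptorVocabulary,
        seed: int,
    ) -> tuple[str, dict[str, str]]:
        rng = np.random.default_rng(seed)
        choices: dict[str, str] = {}
        clauses: list[str] = []
        for name, options in vocab.fields:
            pick = self._pick(label, name, options, rng)
            choices[name] = pick
            clauses.append(_clause(name, pick))
        text = make_structured_report(label, subclass) + ". " + " ".join(clauses)
        return text, choices


# typical descriptor options per class for the default vocabulary, loosely
# following lesion morphology (keratotic scale for BEK/ACK, pigment
# network for nevi, arborizing vessels for BCC, asymmetry and dark
# colors for melanoma)
CLASS_DESCRIPTOR_PROFILE: dict[LesionClass, dict[str, tuple[str, ...]]] = {
    LesionClass.BEK: {
        "skin_structure": ("scaly", "raised"),
        "image_color": ("light brown",),
        "dermoscopic_structures": ("structureless areas",),
        "symmetry": ("symmetric",),
    },
    LesionClass.NEV: {
        "skin_structure": ("smooth", "flat"),
        "image_color": ("light brown", "dark brown"),
        "dermoscopic_structures": ("pigment network", "globules"),
        "symmetry": ("symmetric",),
    },
    LesionClass.ACK: {
        "skin_structure": ("scaly", "flat"),
        "image_color": ("pink", "red"),
        "dermoscopic_structures": ("dots", "structureless areas"),
        "symmetry": ("asymmetric",),
    },
    LesionClass.BCC: {
        "skin_structure": ("ulcerated", "raised"),
        "image_color": ("pink",),
        "dermoscopic_structures": ("arborizing vessels",),
        "symmetry": ("asymmetric",),
    },
    LesionClass.MEL: {
        "skin_structure": ("raised", "ulcerated"),
        "image_color": ("black", "blue-gray"),
        "dermoscopic_structures": ("streaks", "dots"),
        "symmetry": ("asymmetric",),
    },
}


_DEFAULT_BACKEND = TemplateSynthesizer()


def make_synthesized_report(
    label: LesionClass,
    subclass: Optional[str],
    vocab: DescriptorVocabulary,
    seed: int,
    backend: Optional[ReportBackend] = None,
) -> tuple[str, dict[str, str]]:
    """Generate the descriptor-rich report; deterministic given ``seed``.

    The output contains the full structured sentence followed by one clause
    per vocabulary field, each clause using only an option from that
    field's closed set.
    """
    be = backend if backend is not None else _DEFAULT_BACKEND
    return be.synthesize(label, subclass, vocab, seed)


def make_report_pair(
    label: LesionClass,
    subclass: Optional[str],
    vocab: DescriptorVocabulary,
    seed: int,
    backend: Optional[ReportBackend] = None,
) -> ReportPair:
    """Convenience: build both renditions for one record."""
    structured = make_structured_report(label, subclass)
    synthesized, choices = make_synthesized_report(
        label, subclass, vocab, seed, backend
    )
    return ReportPair(
        structured=structured,
        synthesized=synthesized,
        descriptor_choices=choices,
        seed=seed,
    )


def augment_report(
    pair: ReportPair,
    rng: np.random.Generator,
    turnover_probability: float = 0.5,
) -> str:
    """Report turnover: draw the synthesized rendition with the given
    probability, otherwise the structured one."""
    if not 0.0 <= turnover_probability <= 1.0:
        raise ValueError("turnover_probability must be in [0, 1]")
    if rng.random() < turnover_probability:
        return pair.synthesized
    return pair.structured
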