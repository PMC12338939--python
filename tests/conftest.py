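import numpy as np
import pytest

from dermalign import (
    DescriptorVocabulary,
    LesionClass,
    LesionRecord,
    SynthConfig,
    generate_cohort,
    split_cohort,
)


@pytest.fixture(scope="session")
def vocab():
    return DescriptorVocabulary.default()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but complete cohort: 8 per class, 32px, default difficulty."""
    cfg = SynthConfig(n_per_class=8, image_size=32, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_manifest(small_cohort):
    return split_cohort(small_cohort, (0.5, 0.25, 0.25), seed=123)


def make_record(rid="r0", cls=LesionClass.MEL, partition="training",
                source="src", modality="dermoscopic", subclass=None,
                image="images/r0.png"):
    return LesionRecord(
        record_id=rid,
        image=image,
        source=source,
        modality=modality,
        raw_class=cls.display_name,
        raw_subclass=subclass,
        label=cls,
        partition=partition,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
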