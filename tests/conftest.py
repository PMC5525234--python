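import pytest

from fntkit.mapping import align_to_reference
from fntkit.reference_frame import load_reference
from fntkit.subfamily import SUBFAMILIES
from fntkit.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def frame():
    return load_reference()


@pytest.fixture(scope="session")
def mapped_ref(frame):
    """The reference sequence mapped onto itself (identity map)."""
    return align_to_reference(("ref", frame.reference_sequence), frame)


@pytest.fixture(scope="session")
def small_cohort(frame):
    """A seeded 8-subfamily cohort (12 sequences each) with ground truth."""
    config = GeneratorConfig(counts={s: 12 for s in SUBFAMILIES}, seed=42)
    records, truth = generate_cohort(config, frame)
    return config, records, truth


@pytest.fixture(scope="session")
def small_cohort_mapped(frame, small_cohort):
    _, records, truth = small_cohort
    mapped = [align_to_reference(r, frame) for r in records]
    labels = dict(zip(truth.id, truth.subfamily))
    return mapped, labels, truth
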