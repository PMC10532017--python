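import pytest
from hypothesis import settings

from lesionprep.phantom import PhantomSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    # small cohort, short padding -> quick to render, still covers all sizes
    return PhantomSpec(
        n_patients=6,
        seed=11,
        stack_pad_range=(2, 5),
        other_series_slices=(2, 3),
    )


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory, phantom_spec):
    """On-disk phantom cohort shared by ingest/preprocess/pipeline tests."""
    root = tmp_path_factory.mktemp("phantom")
    cohort = generate_cohort(phantom_spec, root)
    return cohort


@pytest.fixture(scope="session")
def memory_cohort():
    """In-memory phantom cohort (no images) for geometry/detector tests."""
    return generate_cohort(PhantomSpec(n_patients=20, seed=5))
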