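import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_dataset():
    """A small fully labelled synthetic dataset shared across test modules."""
    import retrofossil as rf

    specs = (
        rf.CopySpec(age_years=0.0, expression=50),
        rf.CopySpec(age_years=0.0, truncation_5p=300, expression=20),
        rf.CopySpec(
            age_years=0.0,
            planted_stops=(20, 120),
            planted_frameshifts=((60, "del"),),
            expression=15,
        ),
        rf.CopySpec(age_years=20e6, orf_constrained=True, truncation_5p=0, expression=80),
        rf.CopySpec(age_years=20e6, expression=10),
    )
    return rf.generate_dataset(rf.GeneratorConfig(seed=7, copies=specs))


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    import retrofossil as rf

    return rf.annotate_genome(small_dataset.parent, contigs=dict(small_dataset.genome))


def call_for_copy(calls, copy):
    """The annotation call overlapping a planted copy's genomic interval."""
    for c in calls:
        if (
            c.subject_id == copy.subject_id
            and c.s_start < copy.end
            and copy.start < c.s_end
        ):
            return c
    raise AssertionError(f"no call overlaps planted copy {copy.copy_id}")


def parent_call(calls, dataset):
    contig, start, end, _ = dataset.parent_locus
    for c in calls:
        if c.subject_id == contig and c.s_start < end and start < c.s_end:
            return c
    raise AssertionError("no call overlaps the parental locus")
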