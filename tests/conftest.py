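import numpy as np
import pytest

from ty5cards import (
    FeatureAnnotation,
    FeatureClass,
    Genome,
    GenomeIndex,
    Interval,
    TimingProfile,
    annotate_features,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """20 kb single-chromosome random genome used across unit tests."""
    return generate_genome(1, [20_000], 0.40, seed=42)


@pytest.fixture(scope="session")
def small_index(small_genome) -> GenomeIndex:
    return GenomeIndex(small_genome)


@pytest.fixture(scope="session")
def small_annotation(small_genome) -> FeatureAnnotation:
    return annotate_features(
        small_genome,
        {FeatureClass.ACS_CONFIRMED_LIKELY: 5, FeatureClass.TSS: 8},
        spacing_min=1500,
        seed=7,
    )


@pytest.fixture(scope="session")
def flat_timing(small_genome) -> TimingProfile:
    """Constant T_rep = 20 min everywhere (no timing structure)."""
    return TimingProfile({n: np.full(len(s), 20.0) for n, s in small_genome.chromosomes})


@pytest.fixture()
def tiny_genome() -> Genome:
    """Hand-specifiable genome for coordinate-level assertions."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return Genome.from_dict({"chrA": seq})
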