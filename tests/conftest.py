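import numpy as np
import pytest

from genomesurvey import synthetic as syn


@pytest.fixture(scope="session")
def unique_genome_reads():
    """100 kb low-repeat genome with error-free 20x reads (L=100)."""
    spec = syn.SyntheticGenomeSpec(genome_length=100_000, seed=0)
    genome, truth = syn.generate_genome(spec)
    reads = syn.simulate_reads(
        genome, syn.ReadSimSpec(coverage=20, read_length=100, seed=100)
    )
    return genome, truth, reads


@pytest.fixture(scope="session")
def two_copy_repeat_genome_reads():
    """100 kb genome that is 30% exact two-copy repeat, error-free 20x reads."""
    spec = syn.SyntheticGenomeSpec(
        genome_length=100_000,
        repeat_families=(syn.RepeatFamilySpec("REP", 15_000, 2, 0.0),),
        seed=2,
    )
    genome, truth = syn.generate_genome(spec)
    reads = syn.simulate_reads(
        genome, syn.ReadSimSpec(coverage=20, read_length=100, seed=9)
    )
    return genome, truth, reads


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
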