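import pytest

from t2c.digestion import ReferenceGenome, digest, double_digest, get_enzyme
from t2c.simulate import simulate_genome


@pytest.fixture(scope="session")
def hindiii():
    return get_enzyme("HindIII")


@pytest.fixture(scope="session")
def nlaiii():
    return get_enzyme("NlaIII")


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated genome with its implant log (deterministic)."""
    return simulate_genome(length=120_000, target_frag_len=3_000, seed=5)


@pytest.fixture(scope="session")
def small_maps(sim_small, hindiii, nlaiii):
    """(genome, fragmap, subfragmap) for the small simulated genome."""
    genome = sim_small.genome
    chrom = next(iter(genome.sequences))
    fragmap = digest(genome, hindiii, [(chrom, 0, genome.lengths[chrom])])
    subfragmap = double_digest(fragmap, nlaiii, genome)
    return genome, fragmap, subfragmap
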