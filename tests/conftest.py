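import numpy as np
import pytest

from stai.adaptiveness import default_weight_set
from stai.core import CodingGene, Genome, TrnaPool
from stai.simulate import SimulationConfig, default_trna_pool, simulate_genome


@pytest.fixture(scope="session")
def eukarya_pool():
    return default_trna_pool("eukarya")


@pytest.fixture(scope="session")
def bacteria_pool():
    return default_trna_pool("bacteria")


@pytest.fixture(scope="session")
def default_weights():
    return default_weight_set("eukarya")


@pytest.fixture(scope="session")
def small_sim():
    """A small expression-coupled synthetic genome shared across tests."""
    return simulate_genome(SimulationConfig(n_genes=150, min_len=60,
                                            max_len=120, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_genome():
    genes = [
        CodingGene(id="g1", codons=["ATG", "GCT", "GCT", "AAA"]),
        CodingGene(id="g2", codons=["ATG", "GCC", "TTT", "AAA", "CGT"]),
        CodingGene(id="g3", codons=["GCT", "GGT", "CAA"]),
    ]
    return Genome(organism_id="tiny", domain="eukarya", genes=genes)


def random_gene(rng, length, gene_id="g"):
    """A random stop-free gene for oracle comparisons."""
    from stai.genetic_code import SENSE_CODONS
    codons = [SENSE_CODONS[i]
              for i in rng.integers(0, len(SENSE_CODONS), size=length)]
    return CodingGene(id=gene_id, codons=codons)


def random_pool(rng):
    """A random tRNA pool over a random subset of anticodons."""
    import itertools
    from stai.genetic_code import revcomp
    counts = {}
    for b1, b2 in itertools.product("ACGT", repeat=2):
        tail = revcomp(b1 + b2)
        for x in "ACGT":
            if rng.random() < 0.6:
                counts[x + tail] = int(rng.integers(0, 12))
    if not any(counts.values()):
        counts["AGC"] = 1
    return TrnaPool(counts=counts,
                    special_ile_count=int(rng.integers(0, 4)))
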