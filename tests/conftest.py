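import numpy as np
import pytest

from mtsoma.genome import Feature, MtGenomeAnnotation
from mtsoma.selection import EffectTable
from mtsoma.simulate import SimConfig, simulate_genome

BASES = "ACGT"


def make_single_gene_annotation(cds: str, flank: str = "", strand: str = "+",
                                pad: str = "ACGTAC") -> MtGenomeAnnotation:
    """Genome holding one plus- or minus-strand gene, optionally preceded by
    a D-loop made of the flank sequence."""
    from mtsoma.genome import reverse_complement
    segment = cds if strand == "+" else reverse_complement(cds)
    seq = flank + segment + pad
    features = []
    if flank:
        features.append(Feature("D-loop", "D-loop", 1, len(flank)))
    features.append(Feature("GENE1", "protein", len(flank) + 1,
                            len(flank) + len(segment), strand=strand))
    return MtGenomeAnnotation(sequence=seq, features=features)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    stops = {"TAA", "TAG", "AGA", "AGG"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(master_seed=7)


@pytest.fixture(scope="session")
def sim_genome(sim_cfg):
    return simulate_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_ann(sim_genome):
    return sim_genome[0]


@pytest.fixture(scope="session")
def sim_haplotypes(sim_genome):
    return sim_genome[1]


@pytest.fixture(scope="session")
def effect_table(sim_ann):
    return EffectTable(sim_ann)
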