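import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from orthoprofile import (
    GeneRecord,
    Genome,
    GenomeRegistry,
    ScoringScheme,
    build_profile,
)
from orthoprofile.synthetic_data import demo_dataset


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def demo():
    """The bundled 12-leaf / 40-family recipe (no losses, no duplications)."""
    return demo_dataset(seed=20)


@pytest.fixture(scope="session")
def demo_registry(demo):
    return demo.registry()


@pytest.fixture(scope="session")
def demo_profile(demo_registry, scheme):
    return build_profile(demo_registry, scheme=scheme)


def make_gene(gene_id, protein, cds="", replicon="chr", ordinal=0):
    return GeneRecord(
        gene_id=gene_id,
        protein=protein,
        cds=cds or backtranslate_simple(protein),
        replicon_id=replicon,
        ordinal=ordinal,
    )


_SIMPLE_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def backtranslate_simple(protein):
    """Deterministic TTA-free back-translation for fixtures."""
    return "".join(_SIMPLE_CODON[a] for a in protein) + "TAA"


def make_genome(genome_id, proteins, taxon_group="g"):
    """Genome from {gene_id: protein}; order = insertion order."""
    genes = [
        make_gene(gid, prot, ordinal=i)
        for i, (gid, prot) in enumerate(proteins.items())
    ]
    return Genome(genome_id=genome_id, genes=genes, taxon_group=taxon_group)


def make_registry(reference_id, genomes):
    return GenomeRegistry(
        reference_id=reference_id, genomes={g.genome_id: g for g in genomes}
    )
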