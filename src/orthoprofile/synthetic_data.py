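"""Synthetic genome evolution with a known truth table.

Stands in for a registry of downloaded proteomes: gene families are born at
the root of a species tree and evolve down it by site substitution, gene
loss and gene duplication, then each leaf's gene set is back-translated to
CDSs with a tunable TTA rate for leucine codons.  Every event is recorded,
so reciprocal-best-hit profiling, presence vectors, Dollo loss edges,
paralogue families and TTA counts can all be checked against simulation
bookkeeping rather than against other inferences.

Model choices (deliberately simple, so expectations are closed-form):

* substitution: each site mutates on a branch of length b with probability
  1 - exp(-intensity * b), to a uniformly chosen one of the other 19
  residues.  Parent-child identity over one branch is then 1 - p, and over
  a two-branch path (1-p)^2 + p^2/19 + ... by the obvious chain.
* loss / duplication: per family, per branch, probability 1-(1-rate)^b.
  Duplicated copies are inserted adjacent to their parent gene, so synteny
  structure is controlled.
* no indels: homologous proteins stay full-length (alignment overlap tests
  use full-length homologs).
* CDSs: uniform synonymous codon choice, except leucine which is encoded
  TTA with probability ``tta_rate``; every CDS ends with TAA and internal
  stops are never generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GeneRecord, Genome, GenomeRegistry, SpeciesTree

__all__ = [
    "SimulationParams",
    "TruthTables",
    "SyntheticDataset",
    "simulate",
    "truth_presence_vector",
    "mutate_sequence",
    "substitution_probability",
    "demo_params",
    "demo_dataset",
    "DEMO_TREE",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

Edge = frozenset  # edge named by the leaf set under its child node


def _codon_tables() -> dict[str, list[str]]:
    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    rev: dict[str, list[str]] = {}
    for codon, aa in sorted(fwd.items()):
        rev.setdefault(aa, []).append(codon)
    return rev


_REV_CODONS = _codon_tables()
_LEU_NON_TTA = [c for c in _REV_CODONS["L"] if c != "TTA"]


@dataclass
class SimulationParams:
    """Knobs of the generator; the seed is mandatory."""

    tree: SpeciesTree
    seed: int
    n_families: int = 40
    protein_length_mean: int = 180
    protein_length_sd: int = 40
    p_loss: float = 0.0
    p_dup: float = 0.0
    intensity: float = 0.5
    tta_rate: float = 0.1
    taxon_groups: Mapping[str, str] = field(default_factory=dict)
    # per-family substitution-rate multipliers (family id -> factor), e.g.
    # {"F003": 3.0} evolves family F003 at 3x the background rate
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_loss", "p_dup", "tta_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass
class TruthTables:
    """Ground truth recorded while simulating."""

    # canonical pair keys: tuple(sorted(("genomeA|geneA", "genomeB|geneB")))
    ortholog_pairs: set[tuple[str, str]] = field(default_factory=set)
    loss_events: dict[str, set[Edge]] = field(default_factory=dict)
    duplication_events: list[tuple[str, Edge, str]] = field(default_factory=list)
    tta_genes: dict[str, set[str]] = field(default_factory=dict)
    # realized identity fraction between primary copies, keyed
    # (family, leafA, leafB) with leafA < leafB
    realized_identity: dict[tuple[str, str, str], float] = field(default_factory=dict)
    family_presence: dict[str, dict[str, bool]] = field(default_factory=dict)

    def mean_identity(self) -> float:
        return float(np.mean(list(self.realized_identity.values())))


@dataclass
class SyntheticDataset:
    params: SimulationParams
    genomes: dict[str, Genome]
    truth: TruthTables

    def registry(self, reference_id: str | None = None) -> GenomeRegistry:
        ref = reference_id or self.params.tree.leaf_labels[0]
        order: list[str] = []
        for g in self.genomes.values():
            if g.taxon_group not in order:
                order.append(g.taxon_group)
        return GenomeRegistry(
            reference_id=ref, genomes=dict(self.genomes), group_order=order
        )

    def write(self, outdir: str | Path) -> Path:
        """Emit genome input files, a registry JSON and the truth JSON."""
        from .genome_io import write_genome

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        entries = []
        for gid, genome in self.genomes.items():
            write_genome(
                genome,
                outdir / f"{gid}.faa",
                outdir / f"{gid}.fna",
                outdir / f"{gid}.tsv",
            )
            entries.append(
                {
                    "genome_id": gid,
                    "taxon_group": genome.taxon_group,
                    "protein_fasta": f"{gid}.faa",
                    "cds_fasta": f"{gid}.fna",
                    "annotation": f"{gid}.tsv",
                }
            )
        reg = {
            "reference_id": self.params.tree.leaf_labels[0],
            "genomes": entries,
        }
        (outdir / "registry.json").write_text(json.dumps(reg, indent=1))
        (outdir / "tree.nwk").write_text(self.params.tree.as_newick() + "\n")
        truth = {
            "ortholog_pairs": sorted(map(list, self.truth.ortholog_pairs)),
            "loss_events": {
                f: sorted(map(sorted, edges))
                for f, edges in self.truth.loss_events.items()
            },
            "duplication_events": [
                [f, sorted(e), c] for f, e, c in self.truth.duplication_events
            ],
            "tta_genes": {g: sorted(s) for g, s in self.truth.tta_genes.items()},
            "family_presence": self.truth.family_presence,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        return outdir


def substitution_probability(intensity: float, branch_length: float) -> float:
    """Per-site substitution probability over one branch."""
    return 1.0 - float(np.exp(-intensity * branch_length))


def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Mutate each site with probability p, uniformly to another residue."""
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    idx = np.where(hit)[0]
    for i in idx:
        current = chr(arr[i])
        choices = [a for a in AMINO_ACIDS if a != current]
        arr[i] = ord(choices[rng.integers(len(choices))])
    return arr.tobytes().decode("ascii")


def _event(prob_per_unit: float, b: float, rng: np.random.Generator) -> bool:
    if prob_per_unit <= 0:
        return False
    return bool(rng.random() < 1.0 - (1.0 - prob_per_unit) ** b)


def _back_translate(protein: str, tta_rate: float, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        if aa == "L":
            if rng.random() < tta_rate:
                codons.append("TTA")
            else:
                codons.append(_LEU_NON_TTA[rng.integers(len(_LEU_NON_TTA))])
        else:
            opts = _REV_CODONS[aa]
            codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


@dataclass
class _Copy:
    family: str
    copy_id: str  # family for the primary copy, family+"dN" for duplicates
    seq: str
    primary: bool


def simulate(params: SimulationParams) -> SyntheticDataset:
    """Run the generator; reproducible from the seed alone."""
    tree = params.tree
    rng = np.random.default_rng(params.seed)
    fam_ids = [f"F{i:03d}" for i in range(params.n_families)]

    lengths = np.clip(
        rng.normal(params.protein_length_mean, params.protein_length_sd,
                   params.n_families).round().astype(int),
        50, None,
    )
    root_content = []
    for fid, ln in zip(fam_ids, lengths):
        body = "".join(
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=int(ln) - 1)
        )
        root_content.append(_Copy(fid, fid, "M" + body, True))

    truth = TruthTables()
    for fid in fam_ids:
        truth.loss_events[fid] = set()

    dup_counter = {fid: 0 for fid in fam_ids}
    leaf_content: dict[str, list[_Copy]] = {}

    def descend(node, content: list[_Copy]) -> None:
        if node.is_leaf():
            leaf_content[node.taxon.label] = content
            return
        for child in node.child_nodes():
            b = child.edge.length if child.edge.length is not None else 0.0
            edge = Edge(tree.leafset(child))
            out: list[_Copy] = []
            for copy in content:
                if _event(params.p_loss, b, rng):
                    if copy.primary:
                        truth.loss_events[copy.family].add(edge)
                    continue
                mult = params.rate_multipliers.get(copy.family, 1.0)
                p = substitution_probability(params.intensity * mult, b)
                mutated = _Copy(
                    copy.family, copy.copy_id, mutate_sequence(copy.seq, p, rng),
                    copy.primary,
                )
                out.append(mutated)
                if _event(params.p_dup, b, rng):
                    dup_counter[copy.family] += 1
                    dup_id = f"{copy.family}d{dup_counter[copy.family]}"
                    # duplicate diverges from the post-branch state and sits
                    # adjacent to its parent gene
                    out.append(_Copy(copy.family, dup_id, mutated.seq, False))
                    truth.duplication_events.append((copy.family, edge, dup_id))
            descend(child, out)

    descend(tree.root, root_content)

    genomes: dict[str, Genome] = {}
    for leaf in tree.leaf_labels:
        content = leaf_content[leaf]
        genes = []
        tta_here: set[str] = set()
        for ordinal, copy in enumerate(content):
            gene_id = f"{leaf}_{copy.copy_id}"
            cds = _back_translate(copy.seq, params.tta_rate, rng)
            if any(
                cds[3 * i : 3 * i + 3] == "TTA" for i in range(len(cds) // 3)
            ):
                tta_here.add(gene_id)
            genes.append(
                GeneRecord(
                    gene_id=gene_id, protein=copy.seq, cds=cds,
                    replicon_id="chr", ordinal=ordinal, strand="+",
                )
            )
        genomes[leaf] = Genome(
            genome_id=leaf,
            genes=genes,
            taxon_group=params.taxon_groups.get(leaf, "default"),
        )
        truth.tta_genes[leaf] = tta_here

    # presence, ortholog pairs and realized identity from the leaf contents
    for fid in fam_ids:
        truth.family_presence[fid] = {
            leaf: any(c.family == fid for c in leaf_content[leaf])
            for leaf in tree.leaf_labels
        }
    leaves = tree.leaf_labels
    for ia, a in enumerate(leaves):
        prim_a = {c.family: c for c in leaf_content[a] if c.primary}
        for b in leaves[ia + 1 :]:
            prim_b = {c.family: c for c in leaf_content[b] if c.primary}
            for fid in set(prim_a) & set(prim_b):
                ga, gb = f"{a}|{a}_{fid}", f"{b}|{b}_{fid}"
                truth.ortholog_pairs.add(tuple(sorted((ga, gb))))
                sa, sb = prim_a[fid].seq, prim_b[fid].seq
                ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
                key = (fid, *sorted((a, b)))
                truth.realized_identity[key] = ident

    return SyntheticDataset(params=params, genomes=genomes, truth=truth)


def truth_presence_vector(dataset: SyntheticDataset, family_id: str) -> pd.Series:
    """Presence of a family per leaf, from simulation bookkeeping alone."""
    if family_id not in dataset.truth.family_presence:
        raise KeyError(f"unknown family {family_id!r}")
    pres = dataset.truth.family_presence[family_id]
    return pd.Series({k: int(v) for k, v in pres.items()}, dtype=int)


# The bundled demo recipe: 12 leaves in 4 taxon groups (echoing the grouped
# colour blocks of a reference-anchored profile display), moderate divergence
# (pairwise identities roughly 70-90%), 40 families.
DEMO_TREE = (
    "((((s1:0.08,s2:0.08):0.06,s3:0.14):0.16,((a1:0.08,a2:0.08):0.06,"
    "a3:0.14):0.16):0.10,(((c1:0.08,c2:0.08):0.06,c3:0.14):0.16,"
    "((b1:0.08,b2:0.08):0.06,b3:0.14):0.16):0.10);"
)

DEMO_GROUPS = {
    "s1": "streptomycetes", "s2": "streptomycetes", "s3": "streptomycetes",
    "a1": "other-actinomycetales", "a2": "other-actinomycetales",
    "a3": "other-actinomycetales",
    "c1": "corynebacterineae", "c2": "corynebacterineae",
    "c3": "corynebacterineae",
    "b1": "bifidobacteriales", "b2": "bifidobacteriales",
    "b3": "bifidobacteriales",
}


def demo_params(seed: int, **overrides) -> SimulationParams:
    """The default 12-leaf, 40-family recipe; overrides replace fields."""
    base = dict(
        tree=SpeciesTree.from_newick(DEMO_TREE),
        seed=seed,
        n_families=40,
        protein_length_mean=180,
        protein_length_sd=40,
        p_loss=0.0,
        p_dup=0.0,
        intensity=0.5,
        tta_rate=0.1,
        taxon_groups=DEMO_GROUPS,
    )
    base.update(overrides)
    return SimulationParams(**base)


def demo_dataset(seed: int = 20, **overrides) -> SyntheticDataset:
    return simulate(demo_params(seed, **overrides))
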