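"""Genome input/output and the shared data model.

A *genome* here is an ordered list of protein-coding genes on one or more
replicons, each gene carrying its amino-acid sequence, its CDS in coding
orientation, and its ordinal position in the gene order.  Genomes are read
from a protein FASTA, a CDS FASTA and a headered TSV annotation table
(gene_id, replicon_id, start, end, strand; 1-based inclusive coordinates).
A *registry* bundles the genomes of a study together with a designated
reference genome and an ordered list of taxon-group labels used for display
grouping.  Species phylogenies are rooted Newick trees whose leaf labels are
genome ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "Genome",
    "GenomeRegistry",
    "SpeciesTree",
    "GenomeFormatError",
    "read_genome",
    "write_genome",
    "validate_translation",
    "read_tree",
    "read_registry",
]

_NUCLEOTIDES = set("ACGTUNacgtun")


class GenomeFormatError(ValueError):
    """Raised when input files are inconsistent or malformed."""


@dataclass
class GeneRecord:
    """One protein-coding gene.

    ``cds`` is always stored in coding orientation (for minus-strand genes the
    CDS FASTA is authoritative and assumed already reverse-complemented; the
    annotation strand is metadata only).  ``ordinal`` is the 0-based position
    of the gene in the gene order of its replicon.
    """

    gene_id: str
    protein: str
    cds: str
    replicon_id: str = "chromosome"
    ordinal: int = 0
    strand: str = "+"
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.protein:
            raise GenomeFormatError(f"gene {self.gene_id!r}: empty protein")
        if self.cds:
            bad = set(self.cds) - _NUCLEOTIDES
            if bad:
                raise GenomeFormatError(
                    f"gene {self.gene_id!r}: non-nucleotide character(s) "
                    f"{sorted(bad)} in CDS"
                )
            if len(self.cds) % 3 != 0:
                self.partial = True

    @property
    def codon_count(self) -> int:
        return len(self.cds) // 3


@dataclass
class Genome:
    """An ordered collection of genes with a taxon-group label."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    taxon_group: str = ""

    def __post_init__(self) -> None:
        self._index: dict[str, GeneRecord] = {}
        self._by_position: dict[tuple[str, int], GeneRecord] = {}
        for g in self.genes:
            if g.gene_id in self._index:
                raise GenomeFormatError(
                    f"genome {self.genome_id!r}: duplicate gene id {g.gene_id!r}"
                )
            self._index[g.gene_id] = g
            self._by_position[(g.replicon_id, g.ordinal)] = g
        for rep in self.replicons():
            ords = sorted(g.ordinal for g in self.genes if g.replicon_id == rep)
            if ords != list(range(len(ords))):
                raise GenomeFormatError(
                    f"genome {self.genome_id!r}: ordinals on replicon {rep!r} "
                    "are not consecutive from 0"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not in genome {self.genome_id!r}"
            ) from None

    def at(self, replicon_id: str, ordinal: int) -> GeneRecord | None:
        return self._by_position.get((replicon_id, ordinal))

    def replicons(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.replicon_id, None)
        return list(seen)

    def replicon_size(self, replicon_id: str) -> int:
        return sum(1 for g in self.genes if g.replicon_id == replicon_id)


@dataclass
class GenomeRegistry:
    """The genomes of one study, with a designated reference."""

    reference_id: str
    genomes: dict[str, Genome]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.reference_id not in self.genomes:
            raise GenomeFormatError(
                f"reference genome {self.reference_id!r} not in registry"
            )
        if not self.group_order:
            seen: dict[str, None] = {}
            for g in self.genomes.values():
                seen.setdefault(g.taxon_group, None)
            self.group_order = list(seen)

    @property
    def reference(self) -> Genome:
        return self.genomes[self.reference_id]

    def target_ids(self) -> list[str]:
        """Non-reference genome ids, ordered by taxon group then id."""
        rank = {g: i for i, g in enumerate(self.group_order)}
        ids = [i for i in self.genomes if i != self.reference_id]
        return sorted(
            ids,
            key=lambda i: (rank.get(self.genomes[i].taxon_group, len(rank)), i),
        )


class SpeciesTree:
    """A rooted species phylogeny; leaf labels are genome ids.

    Thin wrapper over a :class:`dendropy.Tree` adding the traversal caches the
    parsimony routines need (postorder node list, per-node leaf sets).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise GenomeFormatError(f"duplicate leaf label(s): {dupes}")
        self.leaf_labels = labels
        self._postorder = list(tree.postorder_node_iter())
        self._leafset: dict[int, frozenset[str]] = {}
        for node in self._postorder:
            if node.is_leaf():
                self._leafset[id(node)] = frozenset([node.taxon.label])
            else:
                self._leafset[id(node)] = frozenset().union(
                    *(self._leafset[id(c)] for c in node.child_nodes())
                )

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        s = newick.strip()
        if "[&U]" in s.upper().replace(" ", ""):
            raise GenomeFormatError(
                "tree is explicitly unrooted ([&U]); rooting is a user "
                "decision and is not guessed"
            )
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise GenomeFormatError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    def __len__(self) -> int:
        return len(self.leaf_labels)

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def postorder(self) -> list[dendropy.Node]:
        return self._postorder

    def leafset(self, node: dendropy.Node) -> frozenset[str]:
        """Labels of the leaves under ``node``."""
        return self._leafset[id(node)]

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        want = frozenset(labels)
        missing = want - frozenset(self.leaf_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        best = self.root
        # deepest node whose leafset still covers all wanted labels
        changed = True
        while changed:
            changed = False
            for child in best.child_nodes():
                if want <= self._leafset[id(child)]:
                    best = child
                    changed = True
                    break
        return best

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def _read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise GenomeFormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise GenomeFormatError(f"{path}: no FASTA records")
    return out


def read_genome(
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    annotation: str | Path,
    genome_id: str | None = None,
    taxon_group: str = "",
) -> Genome:
    """Assemble a :class:`Genome` from its three input files.

    Gene order (ordinals) comes from the annotation table: rows are sorted by
    replicon then by start coordinate.  Ids must match exactly across the
    three files; any discrepancy is reported by id.
    """
    proteins = _read_fasta(protein_fasta)
    cdss = _read_fasta(cds_fasta)

    import pandas as pd

    ann = pd.read_csv(annotation, sep="\t", dtype={"gene_id": str, "replicon_id": str})
    required = {"gene_id", "replicon_id", "start", "end", "strand"}
    if not required <= set(ann.columns):
        raise GenomeFormatError(
            f"{annotation}: annotation must have columns {sorted(required)}"
        )

    ids_p, ids_c, ids_a = set(proteins), set(cdss), set(ann["gene_id"])
    for a, b, what in [
        (ids_p, ids_c, "protein FASTA ids absent from CDS FASTA"),
        (ids_c, ids_p, "CDS FASTA ids absent from protein FASTA"),
        (ids_a, ids_p, "annotation ids absent from protein FASTA"),
        (ids_p, ids_a, "protein FASTA ids absent from annotation"),
    ]:
        missing = sorted(a - b)
        if missing:
            raise GenomeFormatError(f"{what}: {missing}")

    ann = ann.sort_values(["replicon_id", "start"], kind="stable")
    genes: list[GeneRecord] = []
    counters: dict[str, int] = {}
    for row in ann.itertuples(index=False):
        rep = row.replicon_id
        ordinal = counters.get(rep, 0)
        counters[rep] = ordinal + 1
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                protein=proteins[row.gene_id],
                cds=cdss[row.gene_id],
                replicon_id=rep,
                ordinal=ordinal,
                strand=str(row.strand),
            )
        )
    gid = genome_id or Path(protein_fasta).stem
    return Genome(genome_id=gid, genes=genes, taxon_group=taxon_group)


def write_genome(genome: Genome, protein_fasta: str | Path, cds_fasta: str | Path,
                 annotation: str | Path) -> None:
    """Emit the three input files for ``genome`` (inverse of read_genome).

    Synthetic coordinates are derived from the gene order: gene i on a
    replicon occupies [i*3000+1, i*3000+len(cds)] so that re-reading sorts
    back to the same ordinals.
    """
    with open(protein_fasta, "w") as fp, open(cds_fasta, "w") as fc, \
            open(annotation, "w") as fa:
        fa.write("gene_id\treplicon_id\tstart\tend\tstrand\n")
        for g in genome.genes:
            fp.write(f">{g.gene_id}\n{g.protein}\n")
            fc.write(f">{g.gene_id}\n{g.cds}\n")
            start = g.ordinal * 3000 + 1
            end = start + max(len(g.cds), 3) - 1
            fa.write(f"{g.gene_id}\t{g.replicon_id}\t{start}\t{end}\t{g.strand}\n")


def validate_translation(rec: GeneRecord, table: int = 11) -> tuple[bool, str]:
    """Check that the CDS translates to the stored protein.

    Uses the bacterial genetic code (table 11) by default.  The terminal stop
    codon is excluded from the comparison.  Returns ``(ok, report)`` where the
    report names the first mismatching codon/residue, or an internal stop.
    """
    if len(rec.cds) < 3:
        raise ValueError(f"gene {rec.gene_id!r}: CDS shorter than one codon")
    n_codons = len(rec.cds) // 3
    aa = str(Seq(rec.cds[: n_codons * 3]).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    stop_at = aa.find("*")
    if stop_at != -1:
        return False, (
            f"gene {rec.gene_id!r}: internal stop codon at codon {stop_at + 1}"
        )
    if aa == rec.protein:
        return True, "ok"
    # report the first differing residue (1-based)
    limit = min(len(aa), len(rec.protein))
    for i in range(limit):
        if aa[i] != rec.protein[i]:
            return False, (
                f"gene {rec.gene_id!r}: residue {i + 1} translates to "
                f"{aa[i]!r} but protein has {rec.protein[i]!r}"
            )
    return False, (
        f"gene {rec.gene_id!r}: translated length {len(aa)} != protein "
        f"length {len(rec.protein)}"
    )


def read_tree(newick: str | Path) -> SpeciesTree:
    """Read a rooted Newick species tree from a file path or literal string."""
    p = Path(str(newick))
    if p.exists():
        text = p.read_text()
    else:
        text = str(newick)
        if not text.strip().endswith(";"):
            raise GenomeFormatError(f"no such file and not a Newick string: {newick}")
    return SpeciesTree.from_newick(text)


def read_registry(path: str | Path) -> GenomeRegistry:
    """Load a registry JSON and all the genomes it references.

    Schema::

        {"reference_id": "...",
         "group_order": ["...", ...],            # optional
         "genomes": [{"genome_id": "...", "taxon_group": "...",
                      "protein_fasta": "...", "cds_fasta": "...",
                      "annotation": "..."}, ...]}

    Relative paths are resolved against the registry file's directory.
    """
    path = Path(path)
    spec: Mapping = json.loads(path.read_text())
    base = path.parent
    genomes: dict[str, Genome] = {}
    for entry in spec["genomes"]:
        g = read_genome(
            base / entry["protein_fasta"],
            base / entry["cds_fasta"],
            base / entry["annotation"],
            genome_id=entry["genome_id"],
            taxon_group=entry.get("taxon_group", ""),
        )
        genomes[g.genome_id] = g
    return GenomeRegistry(
        reference_id=spec["reference_id"],
        genomes=genomes,
        group_order=list(spec.get("group_order", [])),
    )
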