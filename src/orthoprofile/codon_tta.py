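"""TTA codon analysis.

UUA is the only leucine codon made solely of A and U, which makes the TTA
codon rare in GC-rich genomes and gives it a regulatory role in
*Streptomyces*: its translation depends on a single tRNA (the *bldA*
product), so TTA-containing genes form a developmentally controlled regulon.
This module finds in-frame TTA codons, counts TTA-bearing genes per genome,
tabulates how often orthologues of a reference gene carry a TTA, and tests
whether first TTAs cluster toward the 5' end of genes (an exact binomial
test of first-third enrichment against a uniform null).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binom

from .genome_io import Genome, GenomeRegistry
from .orthology import ABSENT, ORTHOLOGUE, SUB_THRESHOLD, ProfileMatrix

__all__ = [
    "TtaReport",
    "ConservedTtaRow",
    "scan_tta",
    "tta_report",
    "count_tta_genes",
    "annotate_profile_tta",
    "conserved_tta_table",
    "positional_bias_test",
]


@dataclass
class TtaReport:
    """In-frame TTA codons of one CDS (1-based codon positions)."""

    gene_id: str
    tta_codon_indices: list[int]
    codon_count: int  # includes the stop codon

    @property
    def has_tta(self) -> bool:
        return bool(self.tta_codon_indices)

    @property
    def first_tta_relative(self) -> float | None:
        """Relative position of the first TTA in [0, 1), or None."""
        if not self.tta_codon_indices:
            return None
        return (self.tta_codon_indices[0] - 1) / self.codon_count


@dataclass
class ConservedTtaRow:
    """Per reference gene: how many orthologues carry a TTA codon."""

    ref_gene_id: str
    ref_has_tta: bool
    n_orthologues: int
    n_with_tta: int
    included: bool

    @property
    def fraction_text(self) -> str:
        return f"{self.n_with_tta}/{self.n_orthologues}"


def scan_tta(cds: str, gene_id: str = "") -> TtaReport:
    """Find in-frame TTA codons; frame 0 only, case-insensitive.

    A "TTA" substring spanning a codon boundary never counts; codons with
    ambiguity characters never match.  Raises ``ValueError`` for a CDS
    shorter than one codon.
    """
    if len(cds) < 3:
        raise ValueError("scan_tta: CDS shorter than one codon")
    s = cds.upper()
    n_codons = len(s) // 3
    hits = [
        i + 1 for i in range(n_codons) if s[3 * i : 3 * i + 3] == "TTA"
    ]
    return TtaReport(gene_id=gene_id, tta_codon_indices=hits, codon_count=n_codons)


def tta_report(gene) -> TtaReport:
    """``scan_tta`` for a GeneRecord."""
    return scan_tta(gene.cds, gene.gene_id)


def count_tta_genes(
    genome: Genome, replicon_filter: Sequence[str] | None = None
) -> int:
    """Number of genes with at least one in-frame TTA codon.

    ``replicon_filter`` restricts the count to the listed replicons (e.g.
    the chromosome only, excluding plasmids).
    """
    reps = set(replicon_filter) if replicon_filter is not None else None
    n = 0
    for gene in genome:
        if reps is not None and gene.replicon_id not in reps:
            continue
        if len(gene.cds) >= 3 and scan_tta(gene.cds).has_tta:
            n += 1
    return n


def annotate_profile_tta(matrix: ProfileMatrix, registry: GenomeRegistry) -> None:
    """Fill ``tta_in_target`` on every non-absent call of the matrix."""
    for call in matrix.calls.values():
        if call.status == ABSENT:
            call.tta_in_target = False
            continue
        gene = registry.genomes[call.genome_id].get(call.target_gene_id)
        call.tta_in_target = len(gene.cds) >= 3 and scan_tta(gene.cds).has_tta
    matrix.tta_annotated = True


def conserved_tta_table(
    matrix: ProfileMatrix,
    registry: GenomeRegistry,
    min_other: int = 5,
    count_sub_threshold: bool = False,
) -> list[ConservedTtaRow]:
    """Conserved-TTA tabulation: one row per reference gene with orthologues.

    The fraction counts TTA-bearing orthologues among the genomes where an
    orthologue exists (denominators therefore vary between genes).  A gene is
    ``included`` when at least ``min_other`` orthologues outside the
    reference carry a TTA, the level adopted as likely to indicate adaptive
    value.  Sub-threshold hits are excluded from the denominator by default.
    """
    if not matrix.tta_annotated:
        raise RuntimeError(
            "tta_in_target flags are not populated; run annotate_profile_tta "
            "on this matrix first"
        )
    accepted = {ORTHOLOGUE} | ({SUB_THRESHOLD} if count_sub_threshold else set())
    ref = registry.reference
    rows = []
    for gene_id in matrix.gene_ids:
        cells = [c for c in matrix.row(gene_id) if c.status in accepted]
        if not cells:
            continue
        n_tta = sum(1 for c in cells if c.tta_in_target)
        ref_gene = ref.get(gene_id)
        rows.append(
            ConservedTtaRow(
                ref_gene_id=gene_id,
                ref_has_tta=len(ref_gene.cds) >= 3 and scan_tta(ref_gene.cds).has_tta,
                n_orthologues=len(cells),
                n_with_tta=n_tta,
                included=n_tta >= min_other,
            )
        )
    return rows


def positional_bias_test(
    genome: Genome, replicon_filter: Sequence[str] | None = None
) -> tuple[int, int, float]:
    """Test 5' positional bias of first TTA codons.

    Returns ``(n_tta_genes, k_first_third, p_value)`` where ``k`` counts
    genes whose first TTA lies in the first third of codons
    (``first_tta_relative < 1/3``) and the p-value is the one-sided exact
    binomial tail P(X >= k | n, 1/3).  Under the uniform null a first TTA is
    equally likely anywhere along the gene.
    """
    reps = set(replicon_filter) if replicon_filter is not None else None
    n = k = 0
    for gene in genome:
        if reps is not None and gene.replicon_id not in reps:
            continue
        if len(gene.cds) < 3:
            continue
        rep = scan_tta(gene.cds)
        if rep.has_tta:
            n += 1
            if rep.first_tta_relative < 1.0 / 3.0:
                k += 1
    if n == 0:
        raise ValueError("positional_bias_test: no TTA-containing genes")
    p_value = float(binom.sf(k - 1, n, 1.0 / 3.0))
    return n, k, p_value


def conserved_tta_tsv(rows: list[ConservedTtaRow], path) -> None:
    """Write the conserved-TTA table as TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tref_has_tta\tn_orthologues\tn_with_tta\tfraction\tincluded\n")
        for r in rows:
            fh.write(
                f"{r.ref_gene_id}\t{int(r.ref_has_tta)}\t{r.n_orthologues}\t"
                f"{r.n_with_tta}\t{r.fraction_text}\t{int(r.included)}\n"
            )
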