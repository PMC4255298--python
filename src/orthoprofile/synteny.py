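"""Local synteny: conservation of the gene neighborhood around an orthologue.

When a reciprocal best hit is weak, conservation of the surrounding gene
order is the classic rescue evidence that the pair really is orthologous
(and, conversely, a shuffled neighborhood weakens the case).  The score here
is deliberately simple: of the up-to-2w genes flanking the reference gene,
how many have their own orthologue within w positions of the partner gene in
the target genome (either side, strand-agnostic)?  Replicons are treated as
linear arrays; circularity is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Genome, GenomeRegistry
from .orthology import ABSENT, ORTHOLOGUE, SUB_THRESHOLD, ProfileMatrix

__all__ = ["SyntenyResult", "neighborhood", "synteny_score"]


@dataclass
class SyntenyResult:
    """Shared-neighbor count for one (reference gene, target genome) pair."""

    ref_gene_id: str
    genome_id: str
    window: int
    shared_neighbors: int
    s_min: int = 2

    @property
    def has_local_synteny(self) -> bool:
        return self.shared_neighbors >= self.s_min


def neighborhood(genome: Genome, gene_id: str, w: int) -> list[str]:
    """Up to ``w`` gene ids on each side of a gene, same replicon, in order.

    Truncated at replicon ends; the focal gene itself is excluded.
    """
    gene = genome.get(gene_id)
    out = []
    for off in range(-w, w + 1):
        if off == 0:
            continue
        nb = genome.at(gene.replicon_id, gene.ordinal + off)
        if nb is not None:
            out.append(nb.gene_id)
    return out


def synteny_score(
    matrix: ProfileMatrix,
    registry: GenomeRegistry,
    ref_gene_id: str,
    genome_id: str,
    w: int = 5,
    s_min: int = 2,
    count_sub_threshold: bool = True,
) -> SyntenyResult:
    """Count conserved flanking genes around an orthologue pair.

    Requires a non-absent call for (ref_gene, genome): synteny is undefined
    without a partner gene.  Neighbors whose own call is sub-threshold count
    by default (neighborhood conservation is exactly the evidence used to
    rescue weak hits); pass ``count_sub_threshold=False`` to restrict to
    full orthologue calls.  Reference neighbors without a row in the profile
    matrix are skipped.
    """
    call = matrix.call(ref_gene_id, genome_id)
    if call.status == ABSENT:
        raise ValueError(
            f"synteny undefined: no reciprocal hit for {ref_gene_id!r} in "
            f"{genome_id!r}"
        )
    target = registry.genomes[genome_id]
    partner = target.get(call.target_gene_id)
    accepted = {ORTHOLOGUE} | ({SUB_THRESHOLD} if count_sub_threshold else set())
    profiled = set(matrix.gene_ids)

    shared = 0
    for nb_id in neighborhood(registry.reference, ref_gene_id, w):
        if nb_id not in profiled:
            continue
        nb_call = matrix.call(nb_id, genome_id)
        if nb_call.status not in accepted:
            continue
        nb_partner = target.get(nb_call.target_gene_id)
        if nb_partner.replicon_id != partner.replicon_id:
            continue
        if 0 < abs(nb_partner.ordinal - partner.ordinal) <= w:
            shared += 1
    return SyntenyResult(
        ref_gene_id=ref_gene_id,
        genome_id=genome_id,
        window=w,
        shared_neighbors=shared,
        s_min=s_min,
    )


def synteny_table_tsv(results: list[SyntenyResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_gene\tgenome\twindow\tshared_neighbors\tlocal_synteny\n")
        for r in results:
            fh.write(
                f"{r.ref_gene_id}\t{r.genome_id}\t{r.window}\t"
                f"{r.shared_neighbors}\t{'yes' if r.has_local_synteny else 'no'}\n"
            )
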