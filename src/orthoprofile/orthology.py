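"""Reciprocal-best-hit orthology calls and the phylogenetic profile matrix.

For each reference gene and each target genome the pipeline records one of
three states, mirroring the coloured/grey/white boxes of a reciprocal-best-
hit presence matrix:

* ``orthologue``   - a reciprocal best hit that meets the orthology criteria
                     (identity and overlap thresholds);
* ``sub_threshold`` - a reciprocal best hit that falls below those criteria
                     (the "grey box": real signal, weak support);
* ``absent``       - no reciprocal best hit at all.

The default criteria are identity >= 40% and overlap >= 60% of the shorter
protein.  The identity cutoff follows the usage of ">40% identity" as an
orthology-acceptance level in the source analyses; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentResult, KmerPrefilter, ScoringScheme, best_hit
from .genome_io import Genome, GenomeRegistry

__all__ = [
    "OrthologyThresholds",
    "OrthologyCall",
    "ProfileMatrix",
    "reciprocal_best_hits",
    "build_profile",
    "presence_vector",
]

ORTHOLOGUE = "orthologue"
SUB_THRESHOLD = "sub_threshold"
ABSENT = "absent"


@dataclass(frozen=True)
class OrthologyThresholds:
    """Minimal criteria for accepting a reciprocal hit as an orthologue."""

    min_identity_pct: float = 40.0
    min_overlap_fraction_of_shorter: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not (0 < self.min_overlap_fraction_of_shorter <= 1):
            raise ValueError("min_overlap_fraction_of_shorter must be in (0, 1]")

    def satisfied(self, aln: AlignmentResult) -> bool:
        shorter = min(aln.query_length, aln.target_length)
        return (
            aln.identity_pct >= self.min_identity_pct
            and aln.overlap >= self.min_overlap_fraction_of_shorter * shorter
        )


@dataclass
class OrthologyCall:
    """The orthology state of one (reference gene, target genome) cell."""

    ref_gene_id: str
    genome_id: str
    status: str
    target_gene_id: str = ""
    alignment: AlignmentResult | None = None
    tta_in_target: bool | None = None  # filled by the TTA annotation step

    def __post_init__(self) -> None:
        if self.status not in (ORTHOLOGUE, SUB_THRESHOLD, ABSENT):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == ABSENT) != (self.target_gene_id == ""):
            raise ValueError("target_gene_id empty iff status is absent")


@dataclass
class ProfileMatrix:
    """Complete grid of orthology calls: reference genes x target genomes."""

    reference_id: str
    gene_ids: list[str]
    genome_ids: list[str]
    calls: dict[tuple[str, str], OrthologyCall] = field(default_factory=dict)
    tta_annotated: bool = False

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            for t in self.genome_ids:
                if (g, t) not in self.calls:
                    raise ValueError(f"incomplete matrix: missing cell ({g}, {t})")

    def call(self, gene_id: str, genome_id: str) -> OrthologyCall:
        try:
            return self.calls[(gene_id, genome_id)]
        except KeyError:
            raise KeyError(
                f"no call for gene {gene_id!r} in genome {genome_id!r}"
            ) from None

    def row(self, gene_id: str) -> list[OrthologyCall]:
        if gene_id not in set(self.gene_ids):
            raise KeyError(f"gene {gene_id!r} not in profile")
        return [self.calls[(gene_id, t)] for t in self.genome_ids]

    def to_frame(self) -> pd.DataFrame:
        """Compact display frame: 'O:identity', 'S:identity' or '-' per cell."""
        data = {}
        for t in self.genome_ids:
            col = []
            for g in self.gene_ids:
                c = self.calls[(g, t)]
                if c.status == ABSENT:
                    col.append("-")
                else:
                    tag = "O" if c.status == ORTHOLOGUE else "S"
                    col.append(f"{tag}:{c.alignment.identity_pct:.1f}")
            data[t] = col
        return pd.DataFrame(data, index=self.gene_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def _back_best(target_gene_id: str, target: Genome, ref: Genome,
               scheme: ScoringScheme, prefilter: KmerPrefilter | None,
               cache: dict[str, str | None]) -> str | None:
    """Best hit of a target gene back into the reference (memoised)."""
    if target_gene_id not in cache:
        hit = best_hit(target.get(target_gene_id), ref, scheme, prefilter)
        cache[target_gene_id] = hit[0] if hit else None
    return cache[target_gene_id]


def reciprocal_best_hits(
    ref: Genome,
    target: Genome,
    scheme: ScoringScheme | None = None,
    thresholds: OrthologyThresholds | None = None,
    prefilter: KmerPrefilter | None = KmerPrefilter(),
    gene_subset: Sequence[str] | None = None,
) -> list[OrthologyCall]:
    """One orthology call per reference gene against ``target``.

    A reciprocal pair exists when the forward best hit's own best hit back
    into the reference is the original gene; it is then classified
    orthologue/sub_threshold by the thresholds, otherwise the call is absent.
    """
    if len(ref) == 0 or len(target) == 0:
        raise ValueError("reciprocal_best_hits: empty proteome")
    if ref.genome_id == target.genome_id:
        raise ValueError("reciprocal_best_hits: ref and target are the same genome")
    scheme = scheme or ScoringScheme()
    thresholds = thresholds or OrthologyThresholds()
    back_cache: dict[str, str | None] = {}
    genes = (
        [ref.get(g) for g in gene_subset] if gene_subset is not None else ref.genes
    )
    calls = []
    for gene in genes:
        fwd = best_hit(gene, target, scheme, prefilter)
        status, tid, aln = ABSENT, "", None
        if fwd is not None:
            cand_id, cand_aln = fwd
            back = _back_best(cand_id, target, ref, scheme, prefilter, back_cache)
            if back == gene.gene_id:
                tid, aln = cand_id, cand_aln
                status = ORTHOLOGUE if thresholds.satisfied(cand_aln) else SUB_THRESHOLD
        calls.append(
            OrthologyCall(
                ref_gene_id=gene.gene_id,
                genome_id=target.genome_id,
                status=status,
                target_gene_id=tid,
                alignment=aln,
            )
        )
    return calls


def build_profile(
    registry: GenomeRegistry,
    gene_subset: Sequence[str] | None = None,
    scheme: ScoringScheme | None = None,
    thresholds: OrthologyThresholds | None = None,
    prefilter: KmerPrefilter | None = KmerPrefilter(),
) -> ProfileMatrix:
    """Reference genes x all non-reference genomes, every cell filled.

    Column order follows the registry's taxon-group order.  Deterministic
    given identical inputs.
    """
    ref = registry.reference
    if gene_subset is not None:
        for g in gene_subset:
            if g not in ref:
                raise KeyError(f"unknown reference gene id {g!r}")
    gene_ids = list(gene_subset) if gene_subset is not None else [
        g.gene_id for g in ref.genes
    ]
    calls: dict[tuple[str, str], OrthologyCall] = {}
    genome_ids = registry.target_ids()
    for gid in genome_ids:
        for call in reciprocal_best_hits(
            ref, registry.genomes[gid], scheme, thresholds, prefilter, gene_ids
        ):
            calls[(call.ref_gene_id, call.genome_id)] = call
    return ProfileMatrix(
        reference_id=registry.reference_id,
        gene_ids=gene_ids,
        genome_ids=genome_ids,
        calls=calls,
    )


def presence_vector(
    matrix: ProfileMatrix,
    gene_id: str,
    count_sub_threshold: bool = False,
    include_reference: bool = False,
) -> pd.Series:
    """Binary presence over genomes for one reference gene.

    1 where the call is ``orthologue`` (and optionally ``sub_threshold``),
    else 0.  With ``include_reference`` the reference genome is prepended
    with value 1, which is the form the tree-based reconstructions expect.
    """
    row = matrix.row(gene_id)
    accepted = {ORTHOLOGUE} | ({SUB_THRESHOLD} if count_sub_threshold else set())
    values = {c.genome_id: int(c.status in accepted) for c in row}
    if include_reference:
        values = {matrix.reference_id: 1, **values}
    return pd.Series(values, dtype=int)
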