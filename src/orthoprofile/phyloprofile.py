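"""Evolutionary interpretation of presence/absence patterns and divergence.

Four groups of tools:

* **Gain/loss reconstruction.** Under Dollo parsimony a gene family is
  gained exactly once (on the edge above the most recent common ancestor of
  the genomes that have it) and may then be lost any number of times; the
  reconstruction finds the minimal set of loss edges.  This formalizes
  "present in the ancestor, lost independently in several lines".  Fitch
  small parsimony (unrestricted binary changes) is provided as the
  alternative model for comparison.

* **Congruence.** Jaccard and simple-matching agreement between two
  presence vectors, used to ask whether two genes travel together across
  genomes.

* **Divergence profiling.** Pairwise identity of a protein across genomes,
  normalised by the identity of a concatenated universal-protein control
  (AtpD, DnaA, DnaG, DnaK, GyrB, RecA, RpoB in the canonical usage) for the
  same genome pair; ratios well below 1 flag proteins diverging faster than
  the housekeeping background.

* **Paralogue families.** One-way probe searches (reciprocity NOT required,
  so whole families are collected, not single orthologues) and
  neighbor-joining trees of the family from p-distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import AlignmentResult, ScoringScheme, local_align
from .genome_io import GeneRecord, GenomeRegistry, SpeciesTree
from .orthology import ABSENT, ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GainLossReconstruction",
    "DivergenceProfile",
    "ParalogFamily",
    "dollo_gain_loss",
    "fitch_changes",
    "congruence",
    "concat_control_identity",
    "divergence_profile",
    "paralog_family",
    "nj_tree",
    "family_distance_matrix",
    "family_nj_tree",
]

Edge = frozenset  # an edge is identified by the leaf set under its child node


@dataclass
class GainLossReconstruction:
    """Single-gain-plus-losses explanation of a presence vector.

    Edges are identified by the set of leaf labels below them; the gain edge
    is the edge above the MRCA of the present leaves (the root's stem edge
    when every leaf is present).  ``internal_states`` maps each node (by its
    leaf set) to 'present' or 'absent'.
    """

    gene_id: str
    gain_edge: Edge
    loss_edges: set[Edge]
    internal_states: dict[Edge, str] = field(default_factory=dict)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def _present_leaves(vector: Mapping[str, int], tree: SpeciesTree) -> set[str]:
    ids = set(vector.keys() if hasattr(vector, "keys") else vector.index)
    extra = ids - set(tree.leaf_labels)
    if extra:
        raise ValueError(f"presence-vector ids not in tree: {sorted(extra)}")
    return {k for k in ids if vector[k]}


def dollo_gain_loss(
    tree: SpeciesTree, vector: Mapping[str, int], gene_id: str = ""
) -> GainLossReconstruction:
    """Dollo parsimony: one gain at the MRCA of present leaves, minimal losses.

    Losses are the edges subtending the maximal all-absent subtrees inside
    the gain clade.  Raises ``ValueError`` on an all-absent vector.
    """
    present = _present_leaves(vector, tree)
    if not present:
        raise ValueError(
            f"gene {gene_id or '?'}: all-absent vector has no Dollo "
            "reconstruction (nothing was ever gained)"
        )
    mrca = tree.mrca(present)
    gain_edge = Edge(tree.leafset(mrca))

    loss_edges: set[Edge] = set()
    states: dict[Edge, str] = {}

    def walk(node) -> None:
        ls = tree.leafset(node)
        if ls & present:
            states[Edge(ls)] = "present"
            for child in node.child_nodes():
                cls = tree.leafset(child)
                if cls & present:
                    walk(child)
                else:
                    loss_edges.add(Edge(cls))
                    for n in child.preorder_iter():
                        states[Edge(tree.leafset(n))] = "absent"
        # unreachable for absent nodes: handled by the parent branch above

    walk(mrca)
    # everything outside the gain clade is absent
    for node in tree.postorder():
        e = Edge(tree.leafset(node))
        if e not in states:
            states[e] = "absent"
    return GainLossReconstruction(
        gene_id=gene_id,
        gain_edge=gain_edge,
        loss_edges=loss_edges,
        internal_states=states,
    )


def fitch_changes(tree: SpeciesTree, vector: Mapping[str, int]) -> int:
    """Minimum number of unrestricted binary state changes (Fitch parsimony)."""
    present = _present_leaves(vector, tree)
    missing = set(tree.leaf_labels) - (
        set(vector.keys() if hasattr(vector, "keys") else vector.index)
    )
    if missing:
        raise ValueError(f"presence vector missing leaves: {sorted(missing)}")
    if not present:
        raise ValueError("all-absent vector: state is trivially absent everywhere")
    INF = float("inf")
    # Sankoff DP with unit change cost: exact minimum on any tree shape,
    # including basal polytomies.
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            s = 1 if node.taxon.label in present else 0
            cost[id(node)] = (0.0 if s == 0 else INF, 0.0 if s == 1 else INF)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[id(child)]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[id(node)] = (c0, c1)
    return int(min(cost[id(tree.root)]))


def congruence(
    u: Mapping[str, int], v: Mapping[str, int]
) -> tuple[float, float]:
    """(Jaccard, simple-matching) agreement of two presence vectors.

    Both vectors must cover the same genome universe.  Jaccard of two empty
    vectors is defined as 1 by convention (they agree perfectly).
    """
    su = pd.Series(u).astype(int)
    sv = pd.Series(v).astype(int)
    if set(su.index) != set(sv.index):
        raise ValueError("congruence: presence vectors cover different genomes")
    sv = sv.reindex(su.index)
    both = int(((su == 1) & (sv == 1)).sum())
    either = int(((su == 1) | (sv == 1)).sum())
    jaccard = both / either if either else 1.0
    matching = float((su == sv).mean())
    return jaccard, matching


def _protein_in(
    registry: GenomeRegistry,
    matrix: ProfileMatrix,
    genome_id: str,
    ref_gene_id: str,
) -> str:
    """Protein sequence of a reference gene's representative in a genome."""
    if genome_id == registry.reference_id:
        return registry.reference.get(ref_gene_id).protein
    call = matrix.call(ref_gene_id, genome_id)
    if call.status == ABSENT:
        raise ValueError(
            f"no orthologue of {ref_gene_id!r} in genome {genome_id!r}"
        )
    return registry.genomes[genome_id].get(call.target_gene_id).protein


def concat_control_identity(
    registry: GenomeRegistry,
    matrix: ProfileMatrix,
    genome_a: str,
    genome_b: str,
    control_genes: Sequence[str],
    scheme: ScoringScheme | None = None,
) -> float:
    """Identity of the concatenated universal-protein control for one pair.

    The control proteins are concatenated in the fixed order given (the
    order is normative: permuting it changes the alignment and hence the
    value) and the two concatenations are locally aligned.  Raises
    ``ValueError`` naming the first control gene lacking an orthologue.
    """
    parts_a, parts_b = [], []
    for g in control_genes:
        parts_a.append(_protein_in(registry, matrix, genome_a, g))
        parts_b.append(_protein_in(registry, matrix, genome_b, g))
    aln = local_align("".join(parts_a), "".join(parts_b), scheme)
    if aln is None:
        raise ValueError(
            f"control concatenations of {genome_a!r}/{genome_b!r} do not align"
        )
    return aln.identity_pct


@dataclass
class DivergenceProfile:
    """Pairwise identity of one protein vs the universal-protein control."""

    protein_name: str
    identity: pd.DataFrame
    control_identity: pd.DataFrame
    ratio: pd.DataFrame

    def mean_ratio(self) -> float:
        vals = self.ratio.values
        mask = ~np.eye(len(self.ratio), dtype=bool)
        return float(np.nanmean(vals[mask]))


def divergence_profile(
    protein: str,
    genome_ids: Sequence[str],
    matrix: ProfileMatrix,
    registry: GenomeRegistry,
    control_genes: Sequence[str],
    scheme: ScoringScheme | None = None,
) -> DivergenceProfile:
    """Grid of pairwise identities for one protein, normalised by the control.

    ``ratio < 1`` flags faster-than-housekeeping divergence.  The protein
    must have an orthologue call in every listed genome.
    """
    seqs = {g: _protein_in(registry, matrix, g, protein) for g in genome_ids}
    n = len(genome_ids)
    ident = pd.DataFrame(np.full((n, n), 100.0), index=genome_ids, columns=genome_ids)
    ctrl = pd.DataFrame(np.full((n, n), 100.0), index=genome_ids, columns=genome_ids)
    for i, a in enumerate(genome_ids):
        for b in genome_ids[i + 1 :]:
            aln = local_align(seqs[a], seqs[b], scheme)
            if aln is None:
                raise ValueError(
                    f"orthologues of {protein!r} in {a!r}/{b!r} do not align"
                )
            ident.loc[a, b] = ident.loc[b, a] = aln.identity_pct
            c = concat_control_identity(registry, matrix, a, b, control_genes, scheme)
            ctrl.loc[a, b] = ctrl.loc[b, a] = c
    ratio = ident / ctrl.where(ctrl > 0)
    return DivergenceProfile(
        protein_name=protein, identity=ident, control_identity=ctrl, ratio=ratio
    )


@dataclass
class ParalogFamily:
    """All genes matching a probe in a one-way search (paralogues included)."""

    probe_gene_id: str
    members: list[tuple[str, str, AlignmentResult]]  # (genome_id, gene_id, aln)

    def __len__(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[str]:
        return [f"{g}|{i}" for g, i, _ in self.members]

    def counts_by_genome(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, _, _ in self.members:
            out[g] = out.get(g, 0) + 1
        return out


def paralog_family(
    probe: GeneRecord,
    registry: GenomeRegistry,
    scheme: ScoringScheme | None = None,
    min_identity_pct: float = 30.0,
    min_coverage_of_probe: float = 0.6,
) -> ParalogFamily:
    """One-way probe search: every gene meeting the family thresholds.

    Unlike reciprocal-best-hit calls this keeps *all* qualifying genes per
    genome, which is how abundant paralogue families are collected.  The
    probe's own genome is searched too (the probe matches itself at 100%).
    An empty family is a legal result.
    """
    members = []
    for genome_id in sorted(registry.genomes):
        genome = registry.genomes[genome_id]
        for gene in genome:
            aln = local_align(probe.protein, gene.protein, scheme)
            if aln is None:
                continue
            if (
                aln.identity_pct >= min_identity_pct
                and aln.coverage_query >= min_coverage_of_probe
            ):
                members.append((genome_id, gene.gene_id, aln))
    return ParalogFamily(probe_gene_id=probe.gene_id, members=members)


def nj_tree(labels: Sequence[str], distances: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted :class:`dendropy.Tree` with branch lengths; negative
    branch lengths are clamped to 0 (and logged).  Requires at least 3 taxa.
    Ties in the Q criterion are broken by the first (row-major) minimal pair,
    so the result is deterministic.
    """
    d = np.asarray(distances, dtype=float).copy()
    n = len(labels)
    if n < 3:
        raise ValueError("nj_tree: need at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("nj_tree: distance matrix must be symmetric n x n")
    if np.isnan(d).any():
        raise ValueError("nj_tree: undefined distance in matrix")

    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(lab)
        nodes.append(nd)
    active = list(range(n))

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.warning("nj_tree: negative branch length %.4g at %s clamped to 0",
                           x, what)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = np.array([sum(d[i, k] for k in active if k != i) for i in active])
        best = (None, None, math.inf)
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[ai] - r[aj]
                if q < best[2] - 1e-12:
                    best = (ai, aj, q)
        ai, aj, _ = best
        i, j = active[ai], active[aj]
        bi = 0.5 * d[i, j] + (r[ai] - r[aj]) / (2 * (m - 2))
        bj = d[i, j] - bi
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(bi, f"join({labels[i] if i < n else i})")
        nj_.edge.length = clamp(bj, f"join({labels[j] if j < n else j})")
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three nodes around one internal vertex
    i, j, k = active
    center = dendropy.Node()
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(v, "final-triple")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def family_distance_matrix(
    family: ParalogFamily,
    registry: GenomeRegistry,
    scheme: ScoringScheme | None = None,
    correction: str = "p",
) -> tuple[list[str], np.ndarray]:
    """All-vs-all p-distances (optionally Poisson-corrected) for a family.

    p = 1 - identity fraction of the local alignment of the two member
    proteins.  ``correction='poisson'`` applies -ln(1-p) for saturated
    families.  An unalignable pair is an error (the distance is undefined).
    """
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    labels = family.member_ids()
    seqs = [
        registry.genomes[g].get(i).protein for g, i, _ in family.members
    ]
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            aln = local_align(seqs[a], seqs[b], scheme)
            if aln is None or aln.overlap == 0:
                raise ValueError(
                    f"undefined distance: {labels[a]} vs {labels[b]} do not align"
                )
            p = 1.0 - aln.matches / aln.overlap
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for "
                        f"{labels[a]} vs {labels[b]}"
                    )
                p = -math.log(1.0 - p)
            d[a, b] = d[b, a] = p
    return labels, d


def family_nj_tree(
    family: ParalogFamily,
    registry: GenomeRegistry,
    scheme: ScoringScheme | None = None,
    correction: str = "p",
) -> dendropy.Tree:
    """Neighbor-joining tree of a paralogue family from pairwise distances."""
    if len(family) < 3:
        raise ValueError("family_nj_tree: need at least 3 family members")
    labels, d = family_distance_matrix(family, registry, scheme, correction)
    return nj_tree(labels, d)
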