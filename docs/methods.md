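# Methods

This note records the models, conventions and numerical choices behind
`orthoprofile`, in the order the pipeline applies them.

## Data model

A genome is an ordered list of protein-coding genes per replicon; each gene
carries its protein, its CDS in coding orientation, and a 0-based ordinal
in the gene order. The CDS FASTA is authoritative for minus-strand genes
(assumed already reverse-complemented); the annotation strand is metadata.
Annotation tables are headered TSV (`gene_id, replicon_id, start, end,
strand`) with 1-based inclusive coordinates, as in GFF; ordinals are
assigned by sorting on (replicon, start). Translation validation uses the
bacterial genetic code (NCBI table 11); alternative codes are out of scope.
Species trees are rooted Newick (a basal polytomy counts as rooted; an
explicit `[&U]` flag is rejected rather than silently re-rooted).

## Alignment

Optimal local alignment is computed by the Gotoh three-matrix recurrence
(H/E/F) with affine gaps; a gap of length k costs `open + k·extend`, the
NCBI convention for blastp's 11/1 defaults, and the default matrix is
BLOSUM62. The ambiguity residue X is forced to score 0 against everything
and never counts toward identity; at the protein level N is asparagine, a
real residue, and is treated as one. No E-values are computed: statistical
significance is deliberately replaced by the reciprocal-best-hit
requirement plus identity/overlap thresholds, which is what the downstream
logic consumes. `overlap` counts residue–residue columns only.

Determinism: the traceback starts at the first optimal cell in row-major
order and, within a cell, prefers diagonal, then vertical (gap in target),
then horizontal; a gap is closed rather than extended on ties. These
conventions are mirrored by an independently written brute-force oracle in
the test suite, and the two agree exactly on randomized short pairs.

The genome-scan `best_hit` may skip targets sharing no length-4 word with
the query. This is a documented heuristic; exact mode (`prefilter=None`) is
the reference behaviour and the suite asserts the two agree on simulated
genomes. Score ties are broken by higher identity, then lexicographically
smaller gene id, and the DP kernels are numba-compiled for speed.

## Orthology calls

For each reference gene: forward best hit into the target; if the target
gene's own best hit back into the reference is the original gene, a
reciprocal pair exists and is classified `orthologue` when identity ≥ 40 %
**and** overlap ≥ 0.6 × the shorter protein, else `sub_threshold`; with no
reciprocal pair the call is `absent`. The 40 % level follows the
">40 % identity" acceptance usage in comparative surveys of this clade;
both knobs are configurable, and threshold monotonicity (raising a
threshold can only shrink the orthologue set) is property-tested. RBH is
single-valued by construction: one call per reference gene per genome, with
paralogue expansion delegated to the one-way family search.

Presence vectors default to counting `orthologue` cells only. This
matters: on lossy simulations, two genes that have each lost their true
partner occasionally adopt each other as a weak reciprocal pair (~35 %
identity); the thresholds park exactly these artifacts in `sub_threshold`,
so treating grey boxes as presence would propagate them into the gain–loss
reconstruction. The flag `count_sub_threshold=True` remains available for
sensitivity analyses.

## TTA codon analysis

Only frame-0 codons are scanned; a `TTA` substring spanning a codon
boundary never counts, matching is case-insensitive, and codons containing
N never match. The conserved-TTA table counts TTA-bearing orthologues among
genomes *where an orthologue exists* (denominators vary per gene), and a
gene is reported when ≥ `min_other` (default 5) orthologues outside the
reference carry a TTA — an intentionally arbitrary level meant to suggest
adaptive value rather than prove it. Sub-threshold hits are excluded from
denominators by default (configurable).

Positional bias: the first TTA's relative position is
`(first_index − 1) / codon_count` with the stop codon in the denominator.
"Bias toward the start" is quantified as enrichment in the first third,
with a one-sided exact binomial tail against null proportion ⅓ — the
simplest test that needs no per-gene length modelling. With n = 10 genes
all early, p = (⅓)¹⁰ ≈ 1.7 × 10⁻⁵.

## Local synteny

`synteny_score` counts reference-neighborhood genes (window w each side,
default 5) whose own orthologue lies within w positions of the partner
gene, either side, strand-agnostic; `has_local_synteny` requires ≥ s_min
(default 2) such neighbors. Sub-threshold neighbor calls count by default,
because neighborhood conservation is precisely the evidence used to rescue
weak hits. Replicons are linear arrays — circularity is not modelled, so a
gene at position 0 and one at position n−1 are not neighbors (documented
limitation). Reference neighbors absent from the profile matrix are
skipped.

## Gain–loss reconstruction

Dollo: the gain is fixed on the edge above the MRCA of present leaves (the
root's stem when all are present); losses are the edges subtending maximal
all-absent subtrees within that clade. This is the standard Dollo
convention — no gain-cost optimization — and yields the unique minimal
loss set for that gain placement. The suite checks minimality exhaustively:
for random trees of ≤ 8 leaves, every presence vector's loss count equals
the minimum over all single-gain labelings, enumerated by brute force.
Fitch small parsimony is implemented as a Sankoff unit-cost DP, exact on
polytomies too.

A planted loss set is recovered edge-exactly whenever it is
"homoplasy-free" in the following checkable sense: every lost clade's
sibling retains a present leaf and the present-leaf MRCA is still the
root. Both conditions are computable from simulation truth alone, and
under them the planted set is the unique Dollo minimum, which is what the
end-to-end test asserts.

## Divergence profiling

The control is the concatenation, in a fixed caller-supplied order, of the
orthologues of a universal-protein list (canonically AtpD, DnaA, DnaG,
DnaK, GyrB, RecA, RpoB); the order is normative because permuting it
changes the local alignment. A protein's divergence ratio for a genome
pair is its identity divided by the control identity; ratios well below 1
flag faster-than-housekeeping divergence. On rate-homogeneous simulations
a control gene's own ratios stay near 1, and a family planted at 3× the
background rate drops below 1 — both are test conditions, not guarantees
about real proteomes.

## Paralogue families and NJ

`paralog_family` is a one-way scan: every gene in every registry genome
meeting identity ≥ 30 % and probe coverage ≥ 0.6 joins the family
(reciprocity deliberately not required; the probe's own genome included).
The 30 %/0.6 defaults are chosen to admit short, diverged family members
and are exposed in the API. Exact mode is the default here — the k-mer
prefilter is not applied, since family search must not miss borderline
members.

Family trees use Saitou–Nei neighbor joining on p-distances
(1 − identity fraction), with −ln(1 − p) Poisson correction available for
saturated families. Q-criterion ties break on the first row-major pair;
negative branch lengths are clamped to 0 and logged. On additive matrices
NJ is consistent, and the suite verifies exact topology and 1e-9 branch
lengths against distances generated from random trees, with an independent
library implementation as a topology cross-check.

## The synthetic generator

The generator is the package's ground-truth instrument, not a realistic
evolution model. Families are born at the root of a given tree (random
sequences, length ~ N(180, 40) clipped at 50, leading M); along each
branch of length b every copy is lost with probability 1 − (1 − p_loss)^b,
duplicated likewise (duplicates insert adjacent to their parent, giving
controlled synteny), and each site substitutes with probability
1 − e^(−intensity·b), uniformly to one of the other 19 residues. That
uniform chain has closed-form identities — 1 − p over one branch,
(1 − p)² + p²/19 over two — which the calibration tests verify at length
10⁴ within three Monte-Carlo standard errors. CDSs are back-translated at
the leaves with uniform synonymous choice except leucine, which is TTA
with probability `tta_rate`; every CDS ends TAA and internal stops never
occur.

What it does **not** emulate: indels (homologs stay full-length, so
overlap thresholds are never stressed), rate variation across sites,
horizontal transfer, composition bias (real actinobacterial proteomes are
GC-rich with skewed amino-acid usage), and codon-usage structure beyond
the single TTA knob. Passing tests therefore demonstrate algorithmic
correctness against planted truth, not robustness to every property of
real proteomes.

The bundled demo recipe uses a fixed 12-leaf tree in four taxon groups
with pairwise path lengths up to ~0.8 and intensity 0.5, giving realized
pairwise identities of roughly 55–95 % (mean ≈ 74 %) — comfortably inside
RBH's reliable range — with 40 families, no losses or duplications, and
tta_rate 0.1. Lossy variants (p_loss = 0.25) drive the gain–loss tests.
Problem sizes throughout the suite (12 genomes × 40 genes; 200 trees of
≤ 8 leaves; 100 additive matrices; 500 oracle pairs) are chosen so each
check runs in seconds while still exercising every code path; they are the
same sizes the acceptance script uses.

## Degenerate inputs and tie-breaks (summary)

* Empty sequence, empty genome, all-absent presence vector, < 3 NJ taxa,
  zero TTA genes: explicit errors, never silent defaults.
* Best-hit ties: score, then identity, then gene id.
* NJ Q ties: first row-major pair; negative branches clamped to 0.
* Jaccard of two empty vectors: 1 by convention (documented).
* Partial codons at the CDS end are ignored by the TTA scanner; CDSs with
  length not divisible by 3 are flagged `partial` at load time.
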