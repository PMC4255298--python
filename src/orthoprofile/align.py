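"""Affine-gap local protein alignment (a desk-scale stand-in for blastp).

Implements optimal Smith-Waterman local alignment with Gotoh affine gaps
against a substitution matrix (BLOSUM62 by default, gap open 11 / extend 1,
the blastp protein defaults).  A gap of length k costs open + k*extend.
Results report the raw score, the percentage identity and the overlap length
(residue-residue columns only), which are the quantities the downstream
orthology thresholds consume; no E-value statistics are computed because
significance here is decided by reciprocal-best-hit logic plus identity and
coverage cutoffs.

Traceback is deterministic: the start cell is the first optimal cell in
row-major order, and on ties within a cell the diagonal move is preferred,
then the vertical (gap in target), then the horizontal (gap in query); a gap
is closed rather than extended when both give the same score.

``best_hit`` scans a whole genome for the best-scoring partner of a query
protein, optionally skipping targets that share no k-mer word with the query
(a documented heuristic; exact mode is the reference behaviour and the two
must agree whenever the true best hit shares at least one word).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import GeneRecord, Genome

__all__ = ["ScoringScheme", "AlignmentResult", "local_align", "best_hit"]

_NEG = -(10**7)

# protein ambiguity characters: never an identity match, never in a k-mer
# word (N is a real residue - asparagine - at the protein level)
_AMBIGUOUS = set("Xx*")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``matrix_name`` is either a matrix bundled with Biopython ("BLOSUM62",
    "PAM250", ...) or a path to a matrix in NCBI text format.  The ambiguity
    residue X is forced to score 0 against everything.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")

    @property
    def matrix(self) -> tuple[str, np.ndarray]:
        return _load_matrix(self.matrix_name)

    def encode(self, seq: str) -> np.ndarray:
        alphabet, _ = self.matrix
        lut = _alphabet_lut(alphabet)
        arr = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        return arr.astype(np.int8)


@lru_cache(maxsize=8)
def _load_matrix(name: str) -> tuple[str, np.ndarray]:
    if Path(name).exists():
        m = substitution_matrices.read(name)
    else:
        m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    n = len(alphabet)
    arr = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            arr[i, j] = int(m[a, b])
    if "X" in alphabet:
        xi = alphabet.index("X")
        arr[xi, :] = 0
        arr[:, xi] = 0
    return alphabet, arr


@lru_cache(maxsize=8)
def _alphabet_lut(alphabet: str) -> np.ndarray:
    fallback = alphabet.index("X") if "X" in alphabet else 0
    lut = np.full(128, fallback, dtype=np.int16)
    for i, a in enumerate(alphabet):
        lut[ord(a)] = i
    return lut


@dataclass
class AlignmentResult:
    """One local alignment: score, identity, overlap and coverage.

    ``overlap`` counts aligned residue-residue columns only (gap columns are
    excluded), matching the "length of the overlap" readout of pairwise
    protein comparisons.  Spans are half-open 0-based intervals on each
    sequence.
    """

    score: int
    matches: int
    overlap: int
    query_length: int
    target_length: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    n_gap_columns: int = 0

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.overlap if self.overlap else 0.0

    @property
    def coverage_query(self) -> float:
        return self.overlap / self.query_length

    @property
    def coverage_target(self) -> float:
        return self.overlap / self.target_length

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"score={self.score} identity={self.identity_pct:.1f}% "
            f"overlap={self.overlap}"
        )


@njit(cache=False)
def _gotoh_matrices(q, t, sub, go, ge):
    """Full H/E/F dynamic-programming matrices for traceback."""
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in target (up)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - go - ge
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go - ge
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def _best_score(q, t, sub, go, ge):
    """Best local score only (rolling rows)."""
    m, n = len(q), len(t)
    h_prev = np.zeros(n + 1, dtype=np.int32)
    f_prev = np.full(n + 1, _NEG, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        h_cur = np.zeros(n + 1, dtype=np.int32)
        f_cur = np.full(n + 1, _NEG, dtype=np.int32)
        e = _NEG
        for j in range(1, n + 1):
            e_new = h_cur[j - 1] - go - ge
            if e - ge > e_new:
                e_new = e - ge
            e = e_new
            f = h_prev[j] - go - ge
            if f_prev[j] - ge > f:
                f = f_prev[j] - ge
            f_cur[j] = f
            h = h_prev[j - 1] + sub[qi, t[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        f_prev = f_cur
    return best


def _traceback(q, t, sub, go, ge, H, E, F):
    """Deterministic traceback from the first row-major optimal cell.

    Returns (matches, overlap, n_gap_columns, query_span, target_span).
    """
    best = int(H.max())
    bi, bj = np.unravel_index(int(np.argmax(H)), H.shape)  # first row-major max
    i, j = int(bi), int(bj)
    end_q, end_t = i, j
    matches = overlap = gaps = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]] if i > 0 and j > 0 else _NEG
            if i > 0 and j > 0 and H[i, j] == diag:
                overlap += 1
                if _ident(q[i - 1], t[j - 1]):
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # gap in target, consume query residue (up)
            gaps += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                state = "H"
            else:
                state = "F"
            i -= 1
        else:  # state == "E": gap in query, consume target residue (left)
            gaps += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                state = "H"
            else:
                state = "E"
            j -= 1
    return best, matches, overlap, gaps, (i, end_q), (j, end_t)


def _ident(a: int, b: int) -> bool:
    return a == b and a not in _ident.skip  # type: ignore[attr-defined]


def _configure_ident(alphabet: str) -> None:
    skip = {alphabet.index(c) for c in "X*" if c in alphabet}
    _ident.skip = skip  # type: ignore[attr-defined]


def local_align(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> AlignmentResult | None:
    """Optimal affine-gap local alignment; ``None`` when no positive score.

    Raises ``ValueError`` on an empty sequence.
    """
    if not query or not target:
        raise ValueError("local_align: empty sequence")
    scheme = scheme or ScoringScheme()
    alphabet, sub = scheme.matrix
    _configure_ident(alphabet)
    q = scheme.encode(query)
    t = scheme.encode(target)
    H, E, F = _gotoh_matrices(q, t, sub, scheme.gap_open, scheme.gap_extend)
    if H.max() <= 0:
        return None
    score, matches, overlap, gaps, qspan, tspan = _traceback(
        q, t, sub, scheme.gap_open, scheme.gap_extend, H, E, F
    )
    return AlignmentResult(
        score=score,
        matches=matches,
        overlap=overlap,
        query_length=len(query),
        target_length=len(target),
        query_span=qspan,
        target_span=tspan,
        n_gap_columns=gaps,
    )


@dataclass(frozen=True)
class KmerPrefilter:
    """Shared-word requirement: candidates must share one exact k-mer."""

    k: int = 4


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    s = seq.upper()
    return frozenset(
        s[i : i + k]
        for i in range(len(s) - k + 1)
        if not (_AMBIGUOUS & set(s[i : i + k]))
    )


def _genome_kmer_sets(genome: Genome, k: int) -> dict[str, frozenset[str]]:
    cache = getattr(genome, "_kmer_cache", None)
    if cache is None:
        cache = {}
        genome._kmer_cache = cache  # type: ignore[attr-defined]
    if k not in cache:
        cache[k] = {g.gene_id: _kmer_set(g.protein, k) for g in genome.genes}
    return cache[k]


def best_hit(
    query: GeneRecord | str,
    target: Genome,
    scheme: ScoringScheme | None = None,
    prefilter: KmerPrefilter | None = KmerPrefilter(),
) -> tuple[str, AlignmentResult] | None:
    """Highest-scoring partner of ``query`` in ``target``.

    Ties on score are broken by higher identity, then by lexicographically
    smallest gene id.  ``prefilter=None`` forces exact mode (every gene
    aligned).  Returns ``None`` when no gene aligns with positive score.
    """
    if len(target) == 0:
        raise ValueError(f"best_hit: genome {target.genome_id!r} is empty")
    scheme = scheme or ScoringScheme()
    qseq = query.protein if isinstance(query, GeneRecord) else query
    if not qseq:
        raise ValueError("best_hit: empty query sequence")
    alphabet, sub = scheme.matrix
    q = scheme.encode(qseq)

    candidates = target.genes
    if prefilter is not None:
        qk = _kmer_set(qseq, prefilter.k)
        if qk:  # a query with no informative word cannot be prefiltered
            sets = _genome_kmer_sets(target, prefilter.k)
            candidates = [g for g in candidates if qk & sets[g.gene_id]]
    if not candidates:
        return None

    scores = []
    for g in candidates:
        t = scheme.encode(g.protein)
        scores.append(
            int(_best_score(q, t, sub, scheme.gap_open, scheme.gap_extend))
        )
    best = max(scores)
    if best <= 0:
        return None
    tied = [g for g, s in zip(candidates, scores) if s == best]
    results = [(g.gene_id, local_align(qseq, g.protein, scheme)) for g in tied]
    results.sort(key=lambda it: (-it[1].identity_pct, it[0]))
    return results[0]


def results_to_tsv(rows, path: str | Path) -> None:
    """Serialize (query_id, target_id, AlignmentResult) triples to TSV."""
    with open(path, "w") as fh:
        fh.write(
            "query\ttarget\tscore\tidentity_pct\toverlap\t"
            "coverage_query\tcoverage_target\n"
        )
        for qid, tid, r in rows:
            fh.write(
                f"{qid}\t{tid}\t{r.score}\t{r.identity_pct:.1f}\t{r.overlap}\t"
                f"{r.coverage_query:.3f}\t{r.coverage_target:.3f}\n"
            )
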