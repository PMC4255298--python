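"""Independent brute-force oracles used by the test suite.

These are deliberately written with different machinery from the library
(top-down memoised recursion instead of iterative DP; exhaustive labelling
enumeration instead of tree logic; path distances on explicitly built trees
instead of agglomeration) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

NEG = float("-inf")


def sw_oracle(query: str, target: str, scheme):
    """Exhaustive affine-gap local alignment by memoised recursion.

    Same scoring conventions as the library aligner (gap of length k costs
    open + k*extend; traceback start = first row-major optimal cell; move
    preference diagonal > up > left; close a gap rather than extend on ties)
    but an entirely separate top-down implementation.

    Returns (score, matches, overlap) or None for no positive score.
    """
    alphabet, sub = scheme.matrix
    amb = {alphabet.index(c) for c in "X*" if c in alphabet}
    q = [int(x) for x in scheme.encode(query)]
    t = [int(x) for x in scheme.encode(target)]
    go, ge = scheme.gap_open, scheme.gap_extend
    m, n = len(q), len(t)

    @functools.lru_cache(maxsize=None)
    def E(i, j):  # gap in query ending at (i, j): consumes target
        if j == 0:
            return NEG
        return max(H(i, j - 1) - go - ge, E(i, j - 1) - ge)

    @functools.lru_cache(maxsize=None)
    def F(i, j):  # gap in target ending at (i, j): consumes query
        if i == 0:
            return NEG
        return max(H(i - 1, j) - go - ge, F(i - 1, j) - ge)

    @functools.lru_cache(maxsize=None)
    def H(i, j):
        if i == 0 or j == 0:
            return 0
        return max(
            0,
            H(i - 1, j - 1) + sub[q[i - 1], t[j - 1]],
            F(i, j),
            E(i, j),
        )

    best, bi, bj = 0, -1, -1
    for i in range(m + 1):
        for j in range(n + 1):
            if H(i, j) > best:
                best, bi, bj = H(i, j), i, j
    if best <= 0:
        return None

    matches = overlap = 0
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            if H(i, j) == 0:
                break
            if i > 0 and j > 0 and H(i, j) == H(i - 1, j - 1) + sub[q[i - 1], t[j - 1]]:
                overlap += 1
                if q[i - 1] == t[j - 1] and q[i - 1] not in amb:
                    matches += 1
                i, j = i - 1, j - 1
            elif H(i, j) == F(i, j):
                state = "F"
            else:
                state = "E"
        elif state == "F":
            state = "H" if F(i, j) == H(i - 1, j) - go - ge else "F"
            i -= 1
        else:
            state = "H" if E(i, j) == H(i, j - 1) - go - ge else "E"
            j -= 1
    return best, matches, overlap


# ---------------------------------------------------------------------------
# tree structures for the parsimony / NJ oracles


@dataclass
class ArrayTree:
    """Flat encoding of a rooted tree: nodes 0..N-1 in postorder-compatible
    numbering, ``parent[i]`` (-1 for the root), and leaf labels."""

    parent: list[int]
    leaf_index: dict[str, int]  # label -> node index

    @property
    def n_nodes(self) -> int:
        return len(self.parent)


def species_tree_to_arrays(tree) -> ArrayTree:
    """Flatten an orthoprofile SpeciesTree (or dendropy tree) to arrays."""
    nodes = list(tree.postorder())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent = [-1] * len(nodes)
    leaf_index = {}
    for nd in nodes:
        for child in nd.child_nodes():
            parent[idx[id(child)]] = idx[id(nd)]
        if nd.is_leaf():
            leaf_index[nd.taxon.label] = idx[id(nd)]
    return ArrayTree(parent=parent, leaf_index=leaf_index)


def dollo_min_losses_all_vectors(at: ArrayTree) -> dict[tuple[int, ...], int]:
    """Minimum Dollo loss count for EVERY presence vector of a tree.

    Enumerates all 2^n_nodes full 0/1 labelings.  A labeling is a valid
    Dollo history iff the total number of gains is exactly one, where a
    present root counts as the single gain (on its stem edge) and every
    parent-0 -> child-1 edge counts as a gain.  Its cost is the number of
    parent-1 -> child-0 edges.  Returns {leaf-state tuple: min losses},
    leaf states ordered by sorted leaf label.
    """
    n = at.n_nodes
    lab = np.arange(2**n, dtype=np.uint32)
    bits = ((lab[:, None] >> np.arange(n)) & 1).astype(np.int8)  # (L, n)
    root = at.parent.index(-1)
    gains = bits[:, root].astype(np.int32)
    losses = np.zeros(len(lab), dtype=np.int32)
    for child, par in enumerate(at.parent):
        if par == -1:
            continue
        gains += (bits[:, child] == 1) & (bits[:, par] == 0)
        losses += (bits[:, child] == 0) & (bits[:, par] == 1)
    valid = gains == 1

    leaf_cols = [at.leaf_index[k] for k in sorted(at.leaf_index)]
    out: dict[tuple[int, ...], int] = {}
    leaf_states = bits[:, leaf_cols]
    for i in np.where(valid)[0]:
        key = tuple(int(x) for x in leaf_states[i])
        c = int(losses[i])
        if key not in out or c < out[key]:
            out[key] = c
    return out


def fitch_min_changes(at: ArrayTree, presence: dict[str, int]) -> int:
    """Minimum unrestricted binary changes by exhaustive labelling."""
    n = at.n_nodes
    fixed = {at.leaf_index[k]: v for k, v in presence.items()}
    free = [i for i in range(n) if i not in fixed]
    best = n + 1
    for mask in range(2 ** len(free)):
        states = dict(fixed)
        for b, node in enumerate(free):
            states[node] = (mask >> b) & 1
        cost = sum(
            1
            for child, par in enumerate(at.parent)
            if par != -1 and states[child] != states[par]
        )
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# random additive trees for the NJ consistency check


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary topology with positive branch lengths.

    Built by sequential taxon insertion into random edges.  Returns
    (labels, distance_matrix, splits) where splits is the set of non-trivial
    bipartitions (each a frozenset of labels on one side).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (neighbor, length); leaves are 0..n_taxa-1
    next_id = n_taxa
    edges: dict[tuple[int, int], float] = {}

    def bl() -> float:
        return float(rng.uniform(0.1, 2.0))

    # start from a 3-star
    center = next_id
    next_id += 1
    for leaf in range(3):
        edges[(min(leaf, center), max(leaf, center))] = bl()
    for leaf in range(3, n_taxa):
        e = list(edges)[rng.integers(len(edges))]
        L = edges.pop(e)
        mid = next_id
        next_id += 1
        a, b = e
        cut = float(rng.uniform(0.2, 0.8)) * L
        edges[(min(a, mid), max(a, mid))] = cut
        edges[(min(b, mid), max(b, mid))] = L - cut
        edges[(min(leaf, mid), max(leaf, mid))] = bl()

    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), L in edges.items():
        adj.setdefault(a, []).append((b, L))
        adj.setdefault(b, []).append((a, L))

    def dists_from(src: int) -> dict[int, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, L in adj[u]:
                if v not in out:
                    out[v] = out[u] + L
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dists_from(i)
        for j in range(n_taxa):
            D[i, j] = di[j]

    # bipartition (and branch length) per edge; canonical key is the side
    # whose sorted label list is lexicographically smaller
    splits = set()
    blmap: dict[frozenset, float] = {}
    for (a, b), L in edges.items():
        seen = {a, b}
        stack = [a]
        side = set()
        while stack:
            u = stack.pop()
            if u < n_taxa:
                side.add(labels[u])
            for v, _ in adj[u]:
                if v not in seen and not (u == a and v == b):
                    seen.add(v)
                    stack.append(v)
        half = frozenset(side)
        other = frozenset(labels) - half
        key = min(half, other, key=sorted)
        blmap[key] = L
        if 1 < len(half) < n_taxa - 1:
            splits.add(key)
    return labels, D, splits, blmap


def tree_splits(tree, labels) -> set:
    """Non-trivial bipartitions of a dendropy tree, label-frozenset form."""
    all_labels = frozenset(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 1 < len(below) < len(all_labels) - 1:
            other = all_labels - below
            splits.add(min(below, other, key=sorted))
    return splits


def nj_branch_length_map(tree) -> dict[frozenset, float]:
    """Map each split/leaf of an unrooted dendropy tree to its branch length.

    Keyed by the smaller side of the bipartition (singletons for leaf
    edges), which is stable across representations of the same unrooted
    tree rooted anywhere along an edge.
    """
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(below, labels - below, key=sorted)
        out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
    return out
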