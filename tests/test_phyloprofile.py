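"""Gain/loss parsimony, congruence, divergence profiling, families and NJ."""

import numpy as np
import pytest

from orthoprofile import (
    build_profile,
    concat_control_identity,
    congruence,
    divergence_profile,
    dollo_gain_loss,
    family_nj_tree,
    fitch_changes,
    nj_tree,
    paralog_family,
    read_tree,
)
from orthoprofile.phyloprofile import ParalogFamily, family_distance_matrix
from orthoprofile.synthetic_data import (
    AMINO_ACIDS,
    SpeciesTree,
    demo_dataset,
    mutate_sequence,
)

from conftest import make_genome, make_registry
from oracles import (
    dollo_min_losses_all_vectors,
    fitch_min_changes,
    nj_branch_length_map,
    random_additive_tree,
    species_tree_to_arrays,
    tree_splits,
)


def random_rooted_newick(rng, n_leaves):
    """Random rooted binary topology by sequential attachment."""
    clades = [f"L{i}" for i in range(n_leaves)]
    rng.shuffle(clades)
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        b = clades.pop(j)
        a = clades.pop(i)
        clades.append(f"({a},{b})")
    return clades[0] + ";"


class TestDollo:
    def test_all_present_gains_at_root_stem(self):
        t = read_tree("((A,B),(C,D));")
        r = dollo_gain_loss(t, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert r.gain_edge == frozenset("ABCD")
        assert r.n_losses == 0

    def test_two_independent_losses(self):
        t = read_tree("((A,B),(C,D));")
        r = dollo_gain_loss(t, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert r.gain_edge == frozenset("ABCD")
        assert r.loss_edges == {frozenset("B"), frozenset("D")}

    def test_gain_at_mrca_of_present_clade(self):
        t = read_tree("((A,B),(C,D));")
        r = dollo_gain_loss(t, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert r.gain_edge == frozenset("AB")
        assert r.n_losses == 0

    def test_all_absent_rejected(self):
        t = read_tree("((A,B),(C,D));")
        with pytest.raises(ValueError):
            dollo_gain_loss(t, {"A": 0, "B": 0, "C": 0, "D": 0})

    def test_internal_states_match_reconstruction(self):
        t = read_tree("((A,B),(C,D));")
        r = dollo_gain_loss(t, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert r.internal_states[frozenset("A")] == "present"
        assert r.internal_states[frozenset("B")] == "absent"
        assert r.internal_states[frozenset("CD")] == "absent"

    def test_minimality_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            tree = read_tree(random_rooted_newick(rng, n))
            at = species_tree_to_arrays(tree)
            oracle = dollo_min_losses_all_vectors(at)
            leaves = sorted(tree.leaf_labels)
            for key, want in oracle.items():
                vec = dict(zip(leaves, key))
                if sum(key) == 0:
                    continue
                r = dollo_gain_loss(tree, vec)
                assert r.n_losses == want, (tree.as_newick(), vec)

    def test_fitch_never_better_than_one_plus_losses(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            tree = read_tree(random_rooted_newick(rng, n))
            leaves = sorted(tree.leaf_labels)
            vec = {k: int(rng.integers(0, 2)) for k in leaves}
            if sum(vec.values()) == 0:
                vec[leaves[0]] = 1
            r = dollo_gain_loss(tree, vec)
            assert fitch_changes(tree, vec) <= 1 + r.n_losses


class TestFitch:
    def test_all_present_needs_no_change(self):
        t = read_tree("((A,B),(C,D));")
        assert fitch_changes(t, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0

    def test_alternating_pattern_needs_two(self):
        t = read_tree("((A,B),(C,D));")
        assert fitch_changes(t, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_single_present_leaf_needs_one(self):
        for nwk in ["((A,B),(C,D));", "(A,(B,(C,D)));", "(A,B,C);"]:
            t = read_tree(nwk)
            vec = {k: 0 for k in t.leaf_labels}
            vec[t.leaf_labels[0]] = 1
            assert fitch_changes(t, vec) == 1

    def test_matches_exhaustive_labelling_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            tree = read_tree(random_rooted_newick(rng, n))
            at = species_tree_to_arrays(tree)
            for _ in range(6):
                vec = {k: int(rng.integers(0, 2)) for k in tree.leaf_labels}
                if sum(vec.values()) == 0:
                    continue
                assert fitch_changes(tree, vec) == fitch_min_changes(at, vec)


class TestCongruence:
    def test_identical_vectors_agree_fully(self):
        u = {"a": 1, "b": 0, "c": 1}
        assert congruence(u, u) == (1.0, 1.0)

    def test_disjoint_vectors(self):
        u = {"a": 1, "b": 0, "c": 0, "d": 0}
        v = {"a": 0, "b": 1, "c": 0, "d": 0}
        j, m = congruence(u, v)
        assert j == 0.0
        assert m == pytest.approx(0.5)  # the two shared zeros

    def test_jaccard_one_third(self):
        u = {"a": 1, "b": 1, "c": 0, "d": 0}
        v = {"a": 1, "b": 0, "c": 1, "d": 0}
        j, _ = congruence(u, v)
        assert j == pytest.approx(1 / 3)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            congruence({"a": 1}, {"b": 1})

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(45)
        keys = [f"g{i}" for i in range(8)]
        for _ in range(30):
            u = {k: int(rng.integers(0, 2)) for k in keys}
            v = {k: int(rng.integers(0, 2)) for k in keys}
            juv, muv = congruence(u, v)
            jvu, mvu = congruence(v, u)
            assert (juv, muv) == (jvu, mvu)
            assert 0 <= juv <= 1 and 0 <= muv <= 1

    def test_both_empty_is_one_by_convention(self):
        u = {"a": 0, "b": 0}
        assert congruence(u, u)[0] == 1.0


@pytest.fixture(scope="module")
def control_setup(scheme):
    """Small registry with 8 families; first 7 serve as the control set."""
    ds = demo_dataset(seed=55, n_families=8)
    reg = ds.registry()
    pm = build_profile(reg, scheme=scheme)
    ref = reg.reference_id
    controls = [f"{ref}_F{i:03d}" for i in range(7)]
    return ds, reg, pm, controls


class TestDivergenceProfiling:
    def test_identical_genomes_are_100_percent(self, scheme, demo_registry,
                                               demo_profile):
        import copy

        from orthoprofile.genome_io import GenomeRegistry
        from test_orthology import renamed_copy

        ref = demo_registry.reference
        copy_g = renamed_copy(ref, "twin")
        reg = GenomeRegistry(reference_id=ref.genome_id,
                             genomes={ref.genome_id: ref, "twin": copy_g})
        pm = build_profile(reg, gene_subset=[g.gene_id for g in ref.genes[:7]],
                           scheme=scheme)
        ident = concat_control_identity(
            reg, pm, ref.genome_id, "twin",
            [g.gene_id for g in ref.genes[:7]], scheme,
        )
        assert ident == 100.0

    def test_concat_identity_tracks_realized_divergence(self, control_setup, scheme):
        ds, reg, pm, controls = control_setup
        a = reg.reference_id
        b = reg.target_ids()[0]
        got = concat_control_identity(reg, pm, a, b, controls, scheme)
        fam_ids = [c.split("_", 1)[1] for c in controls]
        per_protein = [
            100 * ds.truth.realized_identity[(f, *sorted((a, b)))] for f in fam_ids
        ]
        assert got == pytest.approx(np.mean(per_protein), abs=2.0)

    def test_missing_control_orthologue_names_gene(self, control_setup, scheme):
        ds, reg, pm, controls = control_setup
        a, b = reg.reference_id, reg.target_ids()[0]
        with pytest.raises(KeyError, match="absent_gene"):
            concat_control_identity(reg, pm, a, b, ["absent_gene"], scheme)

    def test_control_gene_against_control_is_ratio_one(self, control_setup, scheme):
        ds, reg, pm, controls = control_setup
        genomes = [reg.reference_id] + reg.target_ids()[:2]
        prof = divergence_profile(controls[0], genomes, pm, reg, controls, scheme)
        off = ~np.eye(len(genomes), dtype=bool)
        assert np.all(np.abs(prof.ratio.values[off] - 1.0) < 0.25)

    def test_fast_family_has_ratio_below_one(self, scheme):
        ds = demo_dataset(seed=56, n_families=8,
                          rate_multipliers={"F007": 3.0})
        reg = ds.registry()
        pm = build_profile(reg, scheme=scheme)
        ref = reg.reference_id
        controls = [f"{ref}_F{i:03d}" for i in range(7)]
        fast = f"{ref}_F007"
        genomes = [ref] + reg.target_ids()[:3]
        prof = divergence_profile(fast, genomes, pm, reg, controls, scheme)
        assert prof.mean_ratio() < 1.0

    def test_identical_pair_gives_identity_and_ratio_one(self, control_setup, scheme):
        ds, reg, pm, controls = control_setup
        prof = divergence_profile(
            controls[1], [reg.reference_id, reg.target_ids()[0]],
            pm, reg, controls, scheme,
        )
        assert prof.identity.iloc[0, 0] == 100.0
        assert prof.ratio.iloc[0, 0] == pytest.approx(1.0)


class TestParalogFamily:
    def test_probe_matches_itself_at_100(self, scheme):
        probe_seq = "M" + "".join(
            AMINO_ACIDS[i] for i in np.random.default_rng(1).integers(0, 20, 79)
        )
        ref = make_genome("ref", {"probe": probe_seq})
        reg = make_registry("ref", [ref])
        fam = paralog_family(ref.get("probe"), reg, scheme)
        assert ("ref", "probe") in [(g, i) for g, i, _ in fam.members]
        self_aln = dict(
            ((g, i), a) for g, i, a in fam.members
        )[("ref", "probe")]
        assert self_aln.identity_pct == 100.0

    def test_unrelated_genome_contributes_no_members(self, scheme):
        rng = np.random.default_rng(2)
        mk = lambda n: "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
        ref = make_genome("ref", {"probe": mk(80)})
        other = make_genome("oth", {f"o{i}": mk(80) for i in range(5)})
        reg = make_registry("ref", [ref, other])
        fam = paralog_family(ref.get("probe"), reg, scheme)
        assert all(g == "ref" for g, _, _ in fam.members)

    def test_planted_family_members_all_recovered(self, scheme):
        rng = np.random.default_rng(3)
        probe_seq = "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 99))
        members = {
            f"m{i:02d}": mutate_sequence(probe_seq, 0.25, rng) for i in range(30)
        }
        decoys = {
            f"d{i:02d}": "M" + "".join(
                AMINO_ACIDS[j] for j in rng.integers(0, 20, 99)
            )
            for i in range(20)
        }
        ref = make_genome("ref", {"probe": probe_seq})
        host = make_genome("host", {**members, **decoys})
        reg = make_registry("ref", [ref, host])
        fam = paralog_family(ref.get("probe"), reg, scheme,
                             min_identity_pct=30.0, min_coverage_of_probe=0.6)
        got = {i for g, i, _ in fam.members if g == "host"}
        assert got == set(members)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj_tree(["A", "B", "C"], d)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_four_taxon_additive_split_recovered(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(list("ABCD"), d)
        splits = tree_splits(tree, list("ABCD"))
        assert splits == {frozenset("AB")}
        bl = nj_branch_length_map(tree)
        assert bl[frozenset("AB")] == pytest.approx(1.0)

    def test_consistency_on_random_additive_matrices(self):
        rng = np.random.default_rng(46)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            labels, D, want_splits, want_bl = random_additive_tree(rng, n)
            tree = nj_tree(labels, D)
            assert tree_splits(tree, labels) == want_splits
            got_bl = nj_branch_length_map(tree)
            for key, L in want_bl.items():
                assert got_bl[key] == pytest.approx(L, abs=1e-9)

    def test_matches_skbio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(47)
        labels, D, want_splits, _ = random_additive_tree(rng, 7)
        ours = tree_splits(nj_tree(labels, D), labels)
        sk = skbio_nj(DistanceMatrix((D + D.T) / 2, labels))
        sk_splits = set()
        for node in sk.traverse(include_self=False):
            if node.is_tip():
                continue
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(labels) - 1:
                other = frozenset(labels) - below
                sk_splits.add(min(below, other, key=sorted))
        assert ours == sk_splits == want_splits

    def test_identical_sequences_give_star_with_zero_lengths(self, scheme):
        seq = "MKVLWREQIDMKVLWREQID"
        genome = make_genome("g", {f"m{i}": seq for i in range(4)})
        reg = make_registry("g", [genome])
        fam = paralog_family(genome.get("m0"), reg, scheme)
        labels, d = family_distance_matrix(fam, reg, scheme)
        assert np.all(d == 0)
        tree = family_nj_tree(fam, reg, scheme)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length == 0

    def test_fewer_than_three_members_rejected(self, scheme):
        genome = make_genome("g", {"m0": "MKVLWREQID"})
        reg = make_registry("g", [genome])
        fam = paralog_family(genome.get("m0"), reg, scheme)
        with pytest.raises(ValueError):
            family_nj_tree(fam, reg, scheme)

    def test_undefined_distance_is_an_error(self, scheme):
        fam = ParalogFamily(
            probe_gene_id="p",
            members=[("g", "m0", None), ("g", "m1", None), ("g", "m2", None)],
        )
        genome = make_genome("g", {"m0": "AAAA", "m1": "GGGG", "m2": "MKVL"})
        reg = make_registry("g", [genome])
        with pytest.raises(ValueError, match="undefined distance"):
            family_distance_matrix(fam, reg, scheme)

    def test_poisson_correction_stretches_distances(self, scheme):
        rng = np.random.default_rng(48)
        seq = "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 59))
        genome = make_genome("g", {
            "m0": seq,
            "m1": mutate_sequence(seq, 0.2, rng),
            "m2": mutate_sequence(seq, 0.2, rng),
        })
        reg = make_registry("g", [genome])
        fam = paralog_family(genome.get("m0"), reg, scheme)
        _, dp = family_distance_matrix(fam, reg, scheme, correction="p")
        _, dpois = family_distance_matrix(fam, reg, scheme, correction="poisson")
        off = ~np.eye(3, dtype=bool)
        assert np.all(dpois[off] >= dp[off])
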