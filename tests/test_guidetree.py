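import dendropy
import numpy as np
import pytest

from guidealign.guidetree import (
    adaptive_guide_tree,
    binarize,
    distances_for_class,
    load_reference_tree,
    midpoint_root,
    nj_reference_tree,
    random_tree,
    robinson_foulds,
    upgma,
    validate_distance_matrix,
)
from guidealign.pairwise import percent_identity, global_align, local_align
from guidealign.seqio import MSA, Sequence
from guidealign.similarity import SimilarityClass, pid_matrix
from guidealign.tree import parse_newick

from oracles import brute_upgma, tree_heights, tree_topology


def topo(tree):
    return tree_topology(tree)


class TestDistancesForClass:
    def test_identical_sequences_zero(self, params):
        seqs = [Sequence(f"s{i}", "MKLVWGHE") for i in range(3)]
        for klass in SimilarityClass:
            d = distances_for_class(seqs, klass, params)
            assert np.allclose(d, 0.0)

    def test_high_uses_global_pid(self, params, make_sequences):
        seqs = make_sequences(2, 10, seed=5)
        d = distances_for_class(seqs, SimilarityClass.HIGH, params)
        pid = percent_identity(global_align(seqs[0], seqs[1], params))
        assert d[0, 1] == pytest.approx(1.0 - pid)

    def test_moderate_uses_local_pid(self, params, make_sequences):
        seqs = make_sequences(2, 10, seed=6)
        d = distances_for_class(seqs, SimilarityClass.MODERATE, params)
        pid = percent_identity(
            local_align(seqs[0], seqs[1], params.with_mode("local"))
        )
        assert d[0, 1] == pytest.approx(1.0 - pid)

    def test_low_averages_both_estimates(self, params, make_sequences):
        seqs = make_sequences(2, 12, seed=7)
        d = distances_for_class(seqs, SimilarityClass.LOW, params)
        pg = percent_identity(global_align(seqs[0], seqs[1], params))
        pl = percent_identity(
            local_align(seqs[0], seqs[1], params.with_mode("local"))
        )
        assert d[0, 1] == pytest.approx(1.0 - (pg + pl) / 2.0)

    def test_consensus_arithmetic(self):
        # PID_global 0.20 and PID_local 0.30 must give d = 0.75
        assert 1.0 - (0.20 + 0.30) / 2.0 == 0.75


class TestUpgma:
    def test_two_taxa_cherry(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = upgma(d, ["a", "b"])
        assert topo(tree) == frozenset(["a", "b"])
        assert tree.root.height == pytest.approx(0.2)

    def test_three_taxa_hand_case(self):
        d = np.array(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]
        )
        tree = upgma(d, ["a", "b", "c"])
        assert topo(tree) == frozenset([frozenset(["a", "b"]), "c"])
        heights = tree_heights(tree)
        assert heights[frozenset(["a", "b"])] == pytest.approx(0.1)
        assert heights[frozenset(["a", "b", "c"])] == pytest.approx(0.3)

    def test_equidistant_tie_break(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, ["a", "b", "c"])
        # lowest index pair (0, 1) merges first
        assert topo(tree) == frozenset([frozenset(["a", "b"]), "c"])

    def test_matches_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 8))
            d = np.zeros((n, n))
            iu = np.triu_indices(n, k=1)
            d[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
            d = d + d.T
            ids = [f"t{i}" for i in range(n)]
            tree = upgma(d, ids)
            expected_topo, expected_heights = brute_upgma(d.tolist(), ids)
            assert topo(tree) == expected_topo
            got_heights = tree_heights(tree)
            for members, h in expected_heights.items():
                assert got_heights[members] == pytest.approx(h)

    def test_heights_nondecreasing_to_root(self, rng):
        n = 6
        d = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        d[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
        d = d + d.T
        tree = upgma(d, [f"t{i}" for i in range(n)])
        for node in tree.postorder():
            for child in node.children:
                assert child.height <= node.height + 1e-12

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma(d, ["a", "b"])

    def test_negative_rejected(self):
        d = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError):
            upgma(d, ["a", "b"])


class TestAdaptiveGuideTree:
    def test_identical_family(self, params):
        seqs = [Sequence(f"s{i}", "MKLVWGHE") for i in range(4)]
        res = adaptive_guide_tree(seqs, params)
        assert res.klass is SimilarityClass.HIGH
        assert res.avg_pid == 1.0
        assert res.tree.is_binary()
        # zero distances everywhere: lowest-pair tie-break merges (s0,s1)
        # first, then (s2,s3), then the two cherries
        assert topo(res.tree) == frozenset(
            [frozenset(["s0", "s1"]), frozenset(["s2", "s3"])]
        )

    def test_oracle_family_pipeline(self, params, make_sequences):
        # full pipeline pinned by independent PID + brute-force UPGMA
        seqs = make_sequences(4, 14, seed=21)
        res = adaptive_guide_tree(seqs, params)
        pid_g = pid_matrix(seqs, params)
        if res.klass is SimilarityClass.HIGH:
            d = 1.0 - pid_g
        elif res.klass is SimilarityClass.MODERATE:
            d = 1.0 - pid_matrix(seqs, params.with_mode("local"))
        else:
            d = 1.0 - (
                pid_g + pid_matrix(seqs, params.with_mode("local"))
            ) / 2.0
        np.fill_diagonal(d, 0.0)
        expected_topo, _ = brute_upgma(d.tolist(), [s.id for s in seqs])
        assert topo(res.tree) == expected_topo

    def test_single_sequence_rejected(self, params):
        with pytest.raises(ValueError):
            adaptive_guide_tree([Sequence("a", "MK")], params)

    def test_permutation_equivariance(self, params, make_sequences):
        seqs = make_sequences(5, 16, seed=9)
        t1 = adaptive_guide_tree(seqs, params).tree
        perm = [3, 1, 4, 0, 2]
        t2 = adaptive_guide_tree([seqs[i] for i in perm], params).tree
        assert topo(t1) == topo(t2)


class TestRandomTree:
    def test_two_taxa(self):
        tree = random_tree(["a", "b"], seed=0)
        assert topo(tree) == frozenset(["a", "b"])

    def test_seed_reproducible(self):
        ids = [f"t{i}" for i in range(5)]
        t1 = random_tree(ids, seed=42)
        t2 = random_tree(ids, seed=42)
        assert t1.newick() == t2.newick()

    def test_seeds_vary(self):
        ids = [f"t{i}" for i in range(6)]
        newicks = {random_tree(ids, seed=s).newick() for s in range(10)}
        assert len(newicks) > 1

    def test_binary_with_right_leaves(self):
        ids = [f"t{i}" for i in range(7)]
        tree = random_tree(ids, seed=3)
        assert tree.is_binary()
        assert sorted(tree.leaf_names()) == ids

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            random_tree(["a"], seed=0)


class TestLoadReferenceTree:
    def test_matching_binary_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((a,b),(c,d));\n")
        tree = load_reference_tree(path, ["a", "b", "c", "d"])
        assert tree.is_binary()
        assert topo(tree) == topo(parse_newick("((a,b),(c,d));"))

    def test_multifurcation_left_nested(self):
        tree = load_reference_tree(
            parse_newick("((a,b,c),d);"), ["a", "b", "c", "d"]
        )
        assert tree.newick(lengths=False) == "(((a,b),c),d);"

    def test_missing_leaf_reported(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((a,b),c);\n")
        with pytest.raises(ValueError, match="d"):
            load_reference_tree(path, ["a", "b", "c", "d"])

    def test_extra_leaf_reported(self):
        with pytest.raises(ValueError, match="extra"):
            load_reference_tree(
                parse_newick("((a,b),(c,d));"), ["a", "b", "c"]
            )

    def test_unrooted_input_midpoint_rooted(self):
        # trifurcating root is read as unrooted and resolved by midpoint
        tree = load_reference_tree(
            parse_newick("(a:1,b:1,(c:1,d:5):1);"), ["a", "b", "c", "d"]
        )
        assert tree.is_binary()
        assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]
        # the longest path runs to d; the root must split d off
        sides = [set(l.name for l in c.leaves()) for c in tree.root.children]
        assert {"d"} in sides or {"c", "d"} in sides


class TestNjReferenceTree:
    def test_identical_rows(self):
        msa = MSA((("a", "MKLV"), ("b", "MKLV"), ("c", "MKLV"), ("d", "MKLV")))
        tree = nj_reference_tree(msa)
        assert tree.is_binary()
        assert sorted(tree.leaf_names()) == ["a", "b", "c", "d"]

    def test_two_rows_cherry(self):
        msa = MSA((("a", "MKLV"), ("b", "MKIV")))
        tree = nj_reference_tree(msa)
        assert topo(tree) == frozenset(["a", "b"])

    def test_recovers_clear_grouping(self):
        msa = MSA(
            (
                ("a", "MKLVWGHEAC"),
                ("b", "MKLVWGHEAD"),
                ("c", "PPIYFNNSTE"),
                ("d", "PPIYFNNSTQ"),
            )
        )
        tree = nj_reference_tree(msa)
        split = frozenset(
            [frozenset(["a", "b"]), frozenset(["c", "d"])]
        )
        assert split in tree.bipartitions()

    def test_additive_matrix_recovery(self):
        # distances additive on ((a,b),(c,d)): NJ must recover that split
        from guidealign.guidetree import _neighbor_joining

        d = np.array(
            [
                [0.0, 0.3, 1.1, 1.2],
                [0.3, 0.0, 1.2, 1.3],
                [1.1, 1.2, 0.0, 0.5],
                [1.2, 1.3, 0.5, 0.0],
            ]
        )
        tree = _neighbor_joining(d, ["a", "b", "c", "d"])
        split = frozenset([frozenset(["a", "b"]), frozenset(["c", "d"])])
        assert split in tree.bipartitions()

    def test_disjoint_gap_rows_rejected(self):
        msa = MSA((("a", "MK--"), ("b", "--LV"), ("c", "MKLV")))
        with pytest.raises(ValueError, match="p-distance"):
            nj_reference_tree(msa)


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = parse_newick("((a,b),(c,d));")
        assert robinson_foulds(t, parse_newick("((a,b),(c,d));")) == 0

    def test_distinct_quartets(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_mismatch_rejected(self):
        t1 = parse_newick("((a,b),c);")
        t2 = parse_newick("((a,b),d);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)

    def test_matches_dendropy(self):
        # cross-check against an independent published implementation
        taxa = [f"t{i}" for i in range(8)]
        for pair_seed in range(50):
            t1 = random_tree(taxa, seed=pair_seed)
            t2 = random_tree(taxa, seed=1000 + pair_seed)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.newick(), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=t2.newick(), schema="newick", taxon_namespace=ns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(
                d1, d2, is_bipartitions_updated=True
            )
            assert robinson_foulds(t1, t2) == expected


class TestValidateDistanceMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            validate_distance_matrix(np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            validate_distance_matrix(np.array([[0.1, 0.2], [0.2, 0.0]]))
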