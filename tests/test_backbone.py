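"""NJ inference, bootstrap, consensus, fossil placement, MPL dating."""

import numpy as np
import pytest

from phylograft.backbone import (
    bootstrap_support,
    date_tree,
    majority_consensus,
    matrix_distances,
    mpl_ultrametricize,
    nj_tree,
    place_fossils,
)
from phylograft.model import FossilCalibration
from phylograft.trees import Chronogram, TreeError

from conftest import random_binary_tree


def tree_distance_matrix(tree: Chronogram):
    """Path-length (additive) distances between tips of a tree."""
    tips = sorted(tree.tip_labels())
    depths = tree.depths()
    tipsets = tree.tipsets()
    n = len(tips)
    d = np.zeros((n, n))
    nodes = {t.label: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.mrca([tips[i], tips[j]])
            dist = depths[nodes[tips[i]]] + depths[nodes[tips[j]]] - 2 * depths[mrca]
            d[i, j] = d[j, i] = dist
    return tips, d


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        # d(A,B)=2, d(C,D)=2, cross distances 4 -> split AB|CD, internal 2
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        tree = nj_tree(labels, d)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        internal = [
            n.length
            for n in tree.nodes()
            if not n.is_leaf and n is not tree.root and n.length
        ]
        assert internal == [pytest.approx(2.0)]

    def test_identical_rows_zero_length_cherry(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj_tree(labels, d)
        # three-point formulas put A and B at distance 0 from the junction
        lengths = {t.label: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(0.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(["A", "B"], np.zeros((2, 2)))

    @pytest.mark.parametrize("n_tips", [4, 5, 6])
    def test_recovers_topology_from_additive_matrices(self, n_tips):
        """NJ is consistent on additive distances (random trees, n <= 6)."""
        rng = np.random.default_rng(n_tips)
        for _ in range(20):
            truth = random_binary_tree([f"t{i}" for i in range(n_tips)], rng)
            labels, d = tree_distance_matrix(truth)
            inferred = nj_tree(labels, d)
            assert inferred.bipartitions() == truth.bipartitions()


class TestMatrixDistances:
    def test_question_marks_are_missing(self):
        matrix = {"a": "ACGT????", "b": "ACGTAAAA", "c": "ACCTAAAA"}
        labels, d = matrix_distances(matrix, model="p")
        assert d[labels.index("a"), labels.index("b")] == 0.0

    def test_impute_mode_uses_three_point_bound(self):
        matrix = {
            "a": "AAAA????",
            "b": "????CCCC",
            "c": "AAAACCCC",
            "e": "AATACCGC",
        }
        with pytest.warns(UserWarning, match="imputed"):
            labels, d = matrix_distances(matrix, model="p", missing="impute")
        ia, ib, ic = labels.index("a"), labels.index("b"), labels.index("c")
        expected = max(d[ia, ic], d[ib, ic])  # the tightest third-taxon bound
        assert d[ia, ib] == pytest.approx(min(expected, max(d[ia, labels.index("e")], d[ib, labels.index("e")])))

    def test_error_mode_raises(self):
        matrix = {"a": "AAAA????", "b": "????CCCC", "c": "AAAACCCC"}
        from phylograft.distances import SaturationError

        with pytest.raises(SaturationError):
            matrix_distances(matrix)


class TestBootstrap:
    def test_clean_additive_signal_gets_high_support(self):
        rng = np.random.default_rng(42)
        # two clearly separated blocks of sequence
        block1 = "".join(rng.choice(list("ACGT"), size=300))
        blockify = lambda s, k: s[:k] + "".join(
            rng.choice(list("ACGT"), size=len(s) - k
        ))
        matrix = {
            "A": block1,
            "B": block1[:290] + "TTTTTTTTTT",
            "C": blockify(block1, 100),
            "D": blockify(block1, 100)[:290] + "GGGGGGGGGG",
        }
        # ensure C and D share their divergent block
        matrix["D"] = matrix["C"][:290] + "GGGGGGGGGG"
        tree = bootstrap_support(
            matrix, [("all", 1, 300)], replicates=100, seed=1
        )
        supports = [
            n.support
            for n in tree.nodes()
            if not n.is_leaf and n is not tree.root and n.support is not None
        ]
        assert supports and min(supports) >= 0.9

    def test_random_data_lowers_mean_support(self):
        rng = np.random.default_rng(0)
        rand = {
            lab: "".join(rng.choice(list("ACGT"), size=120)) for lab in "ABCDEF"
        }
        noisy = bootstrap_support(rand, [("all", 1, 120)], replicates=50, seed=2)
        clean_tree = random_binary_tree(list("ABCDEF"), np.random.default_rng(9))
        # simulate clean, clock-free signal by hamming-distance additive data:
        from phylograft.substmodels import SubstModelSpec, simulate_sequences

        seqs = simulate_sequences(
            clean_tree, SubstModelSpec("JC69", length=500), seed=3, rate=0.05
        )
        clean = bootstrap_support(seqs, [("all", 1, 500)], replicates=50, seed=2)

        def mean_support(t):
            vals = [
                n.support
                for n in t.nodes()
                if not n.is_leaf and n is not t.root and n.support is not None
            ]
            return np.mean(vals)

        assert mean_support(noisy) < mean_support(clean)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        matrix = {lab: "".join(rng.choice(list("ACGT"), size=80)) for lab in "ABCDE"}
        t1 = bootstrap_support(matrix, [("all", 1, 80)], replicates=20, seed=7)
        t2 = bootstrap_support(matrix, [("all", 1, 80)], replicates=20, seed=7)
        assert t1.newick() == t2.newick()


class TestConsensus:
    def test_identity_consensus(self):
        t = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cons = majority_consensus([t.copy(), t.copy(), t.copy()])
        assert cons.bipartitions() == t.bipartitions()
        supports = [
            n.support for n in cons.nodes() if n is not cons.root and not n.is_leaf
        ]
        assert all(s == pytest.approx(1.0) for s in supports)

    def test_two_thirds_split_retained_with_support(self):
        t1 = Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        t2 = Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        t3 = Chronogram.from_newick("(((A:1,C:1):1,B:2):1,D:3);")
        cons = majority_consensus([t1, t2, t3], threshold=0.5)
        ab = [n for n in cons.nodes() if {l.label for l in n.leaves()} == {"A", "B"}]
        assert len(ab) == 1
        assert ab[0].support == pytest.approx(2 / 3)

    def test_fifty_fifty_conflict_excluded_by_strict_rule(self):
        t1 = Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        t2 = Chronogram.from_newick("(((A:1,C:1):1,B:2):1,D:3);")
        cons = majority_consensus([t1, t2], threshold=0.5)
        clades = {frozenset(l.label for l in n.leaves()) for n in cons.nodes() if not n.is_leaf}
        assert frozenset({"A", "B"}) not in clades
        assert frozenset({"A", "C"}) not in clades

    def test_tip_set_mismatch_rejected(self):
        t1 = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        t2 = Chronogram.from_newick("((A:1,B:1):1,D:2);")
        with pytest.raises(TreeError):
            majority_consensus([t1, t2])


class TestPlaceFossils:
    TREE = "(((A:1,B:1):1,C:2):1,D:3);"

    def test_root_spanning_taxa(self):
        t = Chronogram.from_newick(self.TREE)
        t.compute_ages()
        placements = place_fossils(t, [FossilCalibration("f", ("A", "D"), 10.0)])
        assert placements[0].node is t.root

    def test_same_node_combination_rule(self):
        t = Chronogram.from_newick(self.TREE)
        t.compute_ages()
        placements = place_fossils(
            t,
            [
                FossilCalibration("f1", ("A", "B"), 10.0, 30.0),
                FossilCalibration("f2", ("A", "B"), 12.0, 25.0),
            ],
        )
        assert len(placements) == 1
        assert placements[0].min_age == 12.0
        assert placements[0].max_age == 25.0

    def test_ancestor_descendant_conflict(self):
        t = Chronogram.from_newick(self.TREE)
        t.compute_ages()
        with pytest.raises(TreeError):
            place_fossils(
                t,
                [
                    FossilCalibration("anc", ("A", "C"), 5.0, 15.0),
                    FossilCalibration("desc", ("A", "B"), 20.0),
                ],
            )

    def test_missing_taxon_skipped_with_warning(self):
        t = Chronogram.from_newick(self.TREE)
        t.compute_ages()
        with pytest.warns(UserWarning, match="skipped"):
            placements = place_fossils(t, [FossilCalibration("f", ("A", "Z"), 5.0)])
        assert placements == []

    def test_restrict_mode_maps_present_subset(self):
        t = Chronogram.from_newick(self.TREE)
        t.compute_ages()
        placements = place_fossils(
            t, [FossilCalibration("f", ("A", "B", "Z"), 5.0)], restrict=True
        )
        assert len(placements) == 1
        assert {l.label for l in placements[0].node.leaves()} == {"A", "B"}


class TestDateTree:
    def test_clocklike_scaling_to_root_minimum(self):
        phy = Chronogram.from_newick("((A:1,B:1):1,(C:2,D:2):0);")
        dated = date_tree(phy, [FossilCalibration("root", ("A", "C"), 10.0)])
        assert dated.root.age == pytest.approx(10.0)
        dated.validate_dated()

    def test_already_calibrated_tree_unchanged(self):
        phy = Chronogram.from_newick("((A:5,B:5):5,(C:10,D:10):0);")
        dated = date_tree(phy, [FossilCalibration("root", ("A", "C"), 10.0)])
        assert dated.root.age == pytest.approx(10.0)
        assert dated.mrca(["A", "B"]).age == pytest.approx(5.0)

    def test_unsatisfiable_max_age_raises(self):
        # satisfying the cherry minimum forces the root past its maximum
        phy = Chronogram.from_newick("((A:1,B:1):9,(C:10,D:10):0);")
        with pytest.raises(TreeError, match="max-age"):
            date_tree(
                phy,
                [
                    FossilCalibration("cherry", ("A", "B"), 8.0),
                    FossilCalibration("root", ("A", "C"), 10.0, 20.0),
                ],
            )

    def test_mpl_clamps_parent_at_least_child(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            phy = random_binary_tree([f"t{i}" for i in range(7)], rng)
            rel = mpl_ultrametricize(phy)
            rel.validate_dated()

    def test_all_minima_satisfied(self):
        phy = Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        dated = date_tree(
            phy,
            [
                FossilCalibration("c1", ("A", "B"), 5.0),
                FossilCalibration("c2", ("A", "D"), 12.0),
            ],
        )
        assert dated.mrca(["A", "B"]).age >= 5.0 - 1e-9
        assert dated.root.age >= 12.0 - 1e-9
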