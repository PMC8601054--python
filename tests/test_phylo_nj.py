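"""p-distances, neighbor joining, bootstrap, newick and clade cuts."""

import numpy as np
import pytest

from ringscan.io_formats import AlignedRecord
from ringscan.phylo_nj import (
    DistanceMatrix, bootstrap_support, clade_partition, nj_tree, parse_newick,
    pdistance_matrix,
)
from ringscan.synthetic_data import make_family_alignment

from conftest import random_additive_tree


def rec(name, seq):
    return AlignedRecord(name, seq)


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        d = pdistance_matrix([rec("a", "CACH"), rec("b", "CACH")])
        assert d.values[0, 1] == 0.0

    def test_one_mismatch_in_four_columns(self):
        d = pdistance_matrix([rec("a", "CACH"), rec("b", "CGCH")])
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gap_columns(self):
        d = pdistance_matrix([rec("a", "CA-H"), rec("b", "CGGH")])
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_x_columns_are_deleted_too(self):
        d = pdistance_matrix([rec("a", "CAXH"), rec("b", "CGGH")])
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="a and b"):
            pdistance_matrix([rec("a", "--AH"), rec("b", "GG--")])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pdistance_matrix([rec("a", "CA"), rec("b", "CAG")])


class TestNjTree:
    def test_three_taxa_closed_form(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # ((A:1,B:2):5,(C:3,D:4)) -> path-sum distances
        ids = ("A", "B", "C", "D")
        m = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, m))
        splits = {frozenset(s) for s in tree.bipartitions()}
        assert splits == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.root.walk() if n.name}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    @pytest.mark.parametrize("seed", range(30))
    def test_additive_matrices_up_to_eight_taxa_recovered(self, seed):
        local = np.random.default_rng(seed)
        n = int(local.integers(4, 9))
        matrix, true_splits = random_additive_tree(local, n)
        tree = nj_tree(matrix)
        assert {frozenset(s) for s in tree.bipartitions()} == true_splits

    def test_equal_distances_resolve_deterministically(self):
        ids = tuple("abcde")
        m = np.ones((5, 5)) - np.eye(5)
        first = nj_tree(DistanceMatrix(ids, m)).newick()
        second = nj_tree(DistanceMatrix(ids, m)).newick()
        assert first == second

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), m)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        local = np.random.default_rng(5)
        matrix, _ = random_additive_tree(local, 6)
        tree = nj_tree(matrix)
        for node in tree.bipartitions().values():
            node.support = 87
        back = parse_newick(tree.newick())
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)
        orig = tree.bipartitions()
        parsed = back.bipartitions()
        assert set(orig) == set(parsed)
        for split, node in orig.items():
            assert parsed[split].length == pytest.approx(node.length, abs=1e-9)
            assert parsed[split].support == node.support


class TestBootstrap:
    def test_zero_replicates_leaves_supports_unset(self):
        aligned = make_family_alignment(2, 3, 0.05, 0.5, seed=2)
        tree = bootstrap_support(aligned, 0, seed=1)
        assert all(n.support is None for n in tree.root.walk())

    def test_clean_family_split_supported_at_one_hundred(self):
        aligned = make_family_alignment(2, 4, 0.02, 0.6, seed=4, length=80)
        tree = bootstrap_support(aligned, 100, seed=11)
        family1 = frozenset(r.id for r in aligned if r.id.startswith("F1"))
        family2 = frozenset(r.id for r in aligned if r.id.startswith("F2"))
        splits = tree.bipartitions()
        support = {k: v.support for k, v in splits.items()}
        assert support.get(family1, support.get(family2)) == 100

    def test_same_seed_gives_identical_supports(self):
        aligned = make_family_alignment(2, 4, 0.05, 0.5, seed=8)
        t1 = bootstrap_support(aligned, 50, seed=33)
        t2 = bootstrap_support(aligned, 50, seed=33)
        assert t1.newick() == t2.newick()

    def test_supports_invariant_to_leaf_order(self):
        aligned = make_family_alignment(2, 4, 0.05, 0.5, seed=8)
        t1 = bootstrap_support(aligned, 50, seed=33)
        t2 = bootstrap_support(list(reversed(aligned)), 50, seed=33)
        s1 = {k: v.support for k, v in t1.bipartitions().items()}
        s2 = {k: v.support for k, v in t2.bipartitions().items()}
        assert s1 == s2


class TestCladePartition:
    def test_two_families_cut_into_their_families(self):
        aligned = make_family_alignment(2, 5, 0.05, 0.5, seed=14)
        tree = nj_tree(pdistance_matrix(aligned))
        partition = clade_partition(tree, k=2)
        clades = {
            frozenset(partition.clade_members(c))
            for c in set(partition.assignment.values())
        }
        assert clades == {
            frozenset(r.id for r in aligned if r.id.startswith("F1")),
            frozenset(r.id for r in aligned if r.id.startswith("F2")),
        }

    def test_k_equals_leaf_count_gives_singletons(self):
        ids = ("a", "b", "c")
        m = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(ids, m))
        partition = clade_partition(tree, k=3)
        assert partition.n_clades == 3
        assert all(len(partition.clade_members(c)) == 1 for c in (1, 2, 3))

    def test_three_families_get_distinct_majority_types(self):
        aligned = make_family_alignment(3, 6, 0.05, 0.5, seed=23)
        labels = {}
        for r in aligned:
            fam = r.id.split("_")[0]
            labels[r.id] = {"F1": "RING-H2", "F2": "RING-HCa",
                           "F3": "RING-v"}[fam]
        tree = nj_tree(pdistance_matrix(aligned))
        partition = clade_partition(tree, k=3, type_labels=labels)
        majorities = set(partition.majority_type.values())
        assert majorities == {"RING-H2", "RING-HCa", "RING-v"}

    def test_k_beyond_leaf_count_rejected(self):
        aligned = make_family_alignment(2, 2, 0.05, 0.5, seed=3)
        tree = nj_tree(pdistance_matrix(aligned))
        with pytest.raises(ValueError):
            clade_partition(tree, k=5)


def test_nj_agrees_with_dendropy_on_random_matrices():
    """Independent NJ implementation recovers the same unrooted topology."""
    import dendropy
    rng = np.random.default_rng(99)
    for _ in range(5):
        matrix, _ = random_additive_tree(rng, 7)
        ours = nj_tree(matrix)
        # dendropy wants a CSV distance table
        import io as _io
        buf = _io.StringIO()
        buf.write("," + ",".join(matrix.ids) + "\n")
        for i, taxon in enumerate(matrix.ids):
            buf.write(taxon + "," + ",".join(
                str(matrix.values[i, j]) for j in range(len(matrix.ids))
            ) + "\n")
        buf.seek(0)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            buf, delimiter=",")
        their_tree = pdm.nj_tree()
        their_splits = set()
        taxa = {t.label for t in their_tree.taxon_namespace}
        anchor = min(taxa)
        for edge in their_tree.preorder_edge_iter():
            if edge.head_node is None or edge.head_node.is_leaf():
                continue
            side = {l.taxon.label for l in edge.head_node.leaf_iter()}
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            their_splits.add(frozenset(taxa - side if anchor in side else side))
        assert {frozenset(s) for s in ours.bipartitions()} == their_splits
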