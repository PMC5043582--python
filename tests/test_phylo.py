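import itertools

import dendropy
import numpy as np
import pytest

from segscan import (
    Alignment,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    patristic_distances,
    robinson_foulds,
    sister_group,
)
from segscan.phylo import DistanceMatrix, RootingError, Tree, TreeNode, UndefinedDistanceError

from conftest import random_alignment
from oracles import enumerate_unrooted_trees, least_squares_fit, tree_bipartitions


class TestPDistance:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            ("ACGTACGTAC", "ACGTACGTAC", 0.0),
            ("ACGTACGTAC", "ACGTACGTTT", 0.2),
            ("AC-T", "ACGT", 0.0),  # gap column excluded by pairwise deletion
            ("ACNT", "AGGT", 1 / 3),
        ],
    )
    def test_pairwise(self, r1, r2, expected):
        aln = Alignment(("a", "b"), (r1, r2))
        assert p_distance_matrix(aln).value("a", "b") == pytest.approx(expected)

    def test_no_shared_columns_raises(self):
        aln = Alignment(("a", "b"), ("A--", "-CC"))
        with pytest.raises(UndefinedDistanceError, match="'a'"):
            p_distance_matrix(aln)


def _additive_distances(adj, labels, rng):
    """Random positive branch lengths on a topology -> additive matrix."""
    from oracles import path_edges

    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = sum(lengths[e] for e in path_edges(adj, labels[i], labels[j]))
        D[i, j] = D[j, i] = d
    return D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        t = nj_tree(D)
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    def test_four_taxon_additive_exact(self):
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(labels, d))
        assert t.bipartitions() == {frozenset({"C", "D"})}  # the AB|CD split
        assert np.allclose(patristic_distances(t).d, d, atol=1e-9)
        # oracle: of the three 4-taxon topologies, only AB|CD fits additively
        fits = []
        for adj in enumerate_unrooted_trees(list(labels)):
            fits.append((least_squares_fit(adj, list(labels), d), adj))
        fits.sort(key=lambda x: x[0])
        assert fits[0][0] == pytest.approx(0.0, abs=1e-12)
        assert tree_bipartitions(fits[0][1], list(labels)) == t.bipartitions()

    def test_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(("a", "b", "c", "d"), d)
        assert nj_tree(D).newick() == nj_tree(D).newick()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_recovers_generating_topology_from_additive_matrices(self, n_taxa, rng):
        labels = [f"t{k}" for k in range(n_taxa)]
        topologies = enumerate_unrooted_trees(labels)
        for _ in range(10):
            adj = topologies[int(rng.integers(len(topologies)))]
            D = _additive_distances(adj, labels, rng)
            t = nj_tree(DistanceMatrix(tuple(labels), D))
            assert t.bipartitions() == tree_bipartitions(adj, labels)
            assert np.allclose(patristic_distances(t).d, D, atol=1e-9)


def _split_alignment():
    """20 columns support the AB|CD split, none conflict."""
    a = "A" * 20 + "ACGTACGTAC"
    b = "A" * 20 + "ACGTACGTAC"
    c = "G" * 20 + "ACGTACGTAC"
    d = "G" * 20 + "ACGAACGAAC"
    return Alignment(("A", "B", "C", "D"), (a, b, c, d))


class TestBootstrap:
    def test_fully_supported_split(self):
        t = bootstrap_support(_split_alignment(), replicates=100, seed=7)
        supports = {n.support for n, _s in t.edge_sides() if not n.is_leaf}
        assert supports == {1.0}

    def test_single_replicate_supports_are_binary(self, rng):
        aln = random_alignment(rng, 5, 80)
        t = bootstrap_support(aln, replicates=1, seed=3)
        for node, _side in t.edge_sides():
            if node.support is not None:
                assert node.support in (0.0, 1.0)

    def test_same_seed_bit_identical(self, rng):
        aln = random_alignment(rng, 5, 60)
        assert (
            bootstrap_support(aln, 30, seed=5).newick()
            == bootstrap_support(aln, 30, seed=5).newick()
        )

    def test_row_order_invariance_of_supports(self, rng):
        aln = random_alignment(rng, 5, 120)
        shuffled = aln.subset(["s3", "s1", "s4", "s0", "s2"])
        s1 = bootstrap_support(aln, 50, seed=9).support_map()
        s2 = bootstrap_support(shuffled, 50, seed=9).support_map()
        assert set(s1) == set(s2)

    def test_duplicating_split_columns_does_not_decrease_support(self):
        base = _split_alignment()
        boosted = Alignment(
            base.ids, tuple(r[:20] + r for r in base.rows)
        )  # duplicate the split-defining columns
        split = frozenset({"C", "D"})
        for seed in (1, 2, 3):
            s_base = bootstrap_support(base, 50, seed).support_map()[split]
            s_boost = bootstrap_support(boosted, 50, seed).support_map()[split]
            assert s_boost >= s_base


def _tree_from_newick(nwk: str) -> Tree:
    dt = dendropy.Tree.get(data=nwk, schema="newick")

    def convert(nd) -> TreeNode:
        name = nd.taxon.label if nd.taxon else None
        out = TreeNode(name=name, length=float(nd.edge.length or 0.0))
        out.children = [convert(c) for c in nd.child_nodes()]
        return out

    return Tree(convert(dt.seed_node))


class TestRobinsonFoulds:
    def test_identity_and_four_taxon(self):
        t1 = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t1) == 0
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_set_mismatch(self):
        t1 = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = _tree_from_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)

    def test_random_six_taxon_pairs_match_dendropy(self, rng):
        labels = [f"t{k}" for k in range(6)]
        tns = dendropy.TaxonNamespace(labels)
        for _ in range(10):
            nwks = []
            for _t in range(2):
                adj = enumerate_unrooted_trees(labels)[
                    int(rng.integers(105))
                ]
                D = _additive_distances(adj, labels, rng)
                nwks.append(nj_tree(DistanceMatrix(tuple(labels), D)))
            mine = robinson_foulds(nwks[0], nwks[1])
            d1 = dendropy.Tree.get(data=nwks[0].newick(False), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=nwks[1].newick(False), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions(); d2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert mine == theirs

    def test_metric_spot_checks(self, rng):
        labels = [f"t{k}" for k in range(5)]
        trees = []
        for _ in range(3):
            adj = enumerate_unrooted_trees(labels)[int(rng.integers(15))]
            D = _additive_distances(adj, labels, rng)
            trees.append(nj_tree(DistanceMatrix(tuple(labels), D)))
        a, b, c = trees
        assert robinson_foulds(a, b) == robinson_foulds(b, a)
        assert robinson_foulds(a, c) <= robinson_foulds(a, b) + robinson_foulds(b, c)


class TestSisterGroup:
    def test_cherry_partner(self):
        t = _tree_from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,O:3);")
        assert sister_group(t, "A", ["O"]) == frozenset({"B"})
        assert sister_group(t, "C", ["O"]) == frozenset({"D"})

    def test_cherry_inside_larger_clade(self):
        t = _tree_from_newick("((((A:1,B:1):1,C:1):1,D:1):1,O:3);")
        assert sister_group(t, "C", ["O"]) == frozenset({"A", "B"})

    def test_focal_adjacent_to_root_gets_outgroup(self):
        t = _tree_from_newick("((A:1,B:1):1,(C:1,F:2):1);")
        assert sister_group(t, "F", ["C"]) == frozenset({"A", "B"})

    def test_incompatible_outgroup_raises(self):
        t = _tree_from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,O:3);")
        with pytest.raises(RootingError):
            sister_group(t, "A", ["O", "C"])  # {O, C} is not a clade

    def test_focal_in_outgroup_rejected(self):
        t = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            sister_group(t, "A", ["A", "B"])
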