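"""Observed/expected matrices, NJ correctness and the consensus network."""
import numpy as np
import pytest

from repskim.graph import HitTable, RepeatCluster
from repskim.network import (DistanceMatrix, PhyloTree, TreeNode,
                             consensus_network, neighbor_joining,
                             observed_expected_matrix, random_additive_tree,
                             to_distance, write_splits_nexus)


def _random_edge_hits(rng, n_nodes, n_edges):
    pairs = set()
    while len(pairs) < n_edges:
        a, b = rng.integers(0, n_nodes, size=2)
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    a = np.array([p[0] for p in pairs], dtype=np.int64)
    b = np.array([p[1] for p in pairs], dtype=np.int64)
    return HitTable(a, b, np.full(len(pairs), 80, dtype=np.int64),
                    np.ones(len(pairs)), np.zeros(len(pairs), dtype=np.uint8),
                    n_nodes)


class TestObservedExpected:
    def test_uniform_random_edges_near_unity(self, rng):
        n, E = 100, 600
        sample_idx = np.repeat([0, 1], 50).astype(np.int32)
        hits = _random_edge_hits(rng, n, E)
        cluster = RepeatCluster(1, np.arange(n), 1.0)
        mat = observed_expected_matrix(cluster, hits, sample_idx, ["AAAA", "BBBB"])
        assert mat.complete
        P = n * (n - 1) / 2
        for s, t in ((0, 0), (0, 1), (1, 1)):
            n_pairs_st = 50 * 49 / 2 if s == t else 2500
            p = n_pairs_st / P
            sd = np.sqrt(E * p * (1 - p)) / (E * p)
            assert abs(mat.obs_exp[s, t] - 1.0) < 3 * sd

    def test_no_cross_edges_incomplete(self):
        pairs = [(0, 1), (2, 3)]
        a = np.array([p[0] for p in pairs], dtype=np.int64)
        b = np.array([p[1] for p in pairs], dtype=np.int64)
        hits = HitTable(a, b, np.full(2, 80, dtype=np.int64), np.ones(2),
                        np.zeros(2, dtype=np.uint8), 4)
        cluster = RepeatCluster(1, np.arange(4), 1.0)
        mat = observed_expected_matrix(
            cluster, hits, np.array([0, 0, 1, 1], dtype=np.int32),
            ["AAAA", "BBBB"])
        assert mat.obs_exp[0, 1] == 0
        assert not mat.complete

    def test_absent_sample_incomplete(self):
        hits = HitTable(np.array([0]), np.array([1]),
                        np.array([80]), np.ones(1),
                        np.zeros(1, dtype=np.uint8), 2)
        cluster = RepeatCluster(1, np.arange(2), 1.0)
        mat = observed_expected_matrix(cluster, hits,
                                       np.zeros(2, dtype=np.int32),
                                       ["AAAA", "BBBB"])
        assert not mat.complete
        assert to_distance(mat) is None

    def test_to_distance_inverse(self):
        from repskim.network import ClusterSimilarityMatrix
        obs_exp = np.array([[1.0, 2.0], [2.0, 1.0]])
        mat = ClusterSimilarityMatrix(1, ["AAAA", "BBBB"], obs_exp, True)
        d = to_distance(mat)
        assert d.d[0, 1] == pytest.approx(0.5)
        assert d.d[0, 0] == 0.0

    def test_unit_matrix_distances_one(self):
        from repskim.network import ClusterSimilarityMatrix
        obs_exp = np.ones((3, 3))
        mat = ClusterSimilarityMatrix(1, list("ABC"), obs_exp, True)
        d = to_distance(mat)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(d.d[off], 1.0)


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        d = DistanceMatrix(list("ABC"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = neighbor_joining(d)
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"T{i}" for i in range(8)]
        _, dist = random_additive_tree(labels, rng)
        tree = neighbor_joining(dist)
        out = tree.distance_matrix()
        assert out.samples == sorted(labels)
        assert np.max(np.abs(out.d - dist.d)) < 1e-9

    def test_matches_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        labels = [f"T{i}" for i in range(7)]
        _, dist = random_additive_tree(labels, rng)
        ours = neighbor_joining(dist).distance_matrix()
        sym = (dist.d + dist.d.T) / 2  # skbio insists on exact symmetry
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(sym, ids=dist.samples))
        sk_d = sk_tree.tip_tip_distances(dist.samples)
        assert np.max(np.abs(ours.d - np.asarray(sk_d.data))) < 1e-8

    def test_tie_breaks_to_lexicographically_smallest_pair(self):
        d = DistanceMatrix(list("ABCD"), np.ones((4, 4)) - np.eye(4))
        tree = neighbor_joining(d)
        sides = {s for s, _ in tree.splits(nontrivial_only=True)}
        assert frozenset("CD") in sides  # complement of the (A,B) join

    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(list("AB"),
                                            np.array([[0, 1], [1, 0.0]])))


def _quartet(a, b, c, d):
    """Unrooted quartet with cherry (c, d)."""
    inner = TreeNode(children=[(TreeNode(name=c), 1.0),
                               (TreeNode(name=d), 1.0)])
    return PhyloTree(TreeNode(children=[(TreeNode(name=a), 1.0),
                                        (TreeNode(name=b), 1.0),
                                        (inner, 1.0)]))


class TestConsensusNetwork:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(3)
        tree, _ = random_additive_tree([f"T{i}" for i in range(6)], rng)
        net = consensus_network([tree] * 10)
        assert all(s.support == 1.0 for s in net.splits if s.support > 0)
        assert {s.side for s in net.nontrivial()} == {
            side for side, _ in tree.splits(nontrivial_only=True)}

    def test_conflicting_quartets_both_retained(self):
        trees = [_quartet("A", "B", "C", "D")] * 5 + \
                [_quartet("B", "D", "A", "C")] * 5
        net = consensus_network(trees, min_support=0.1)
        nt = {frozenset(s.side) for s in net.nontrivial()}
        assert frozenset("CD") in nt
        assert frozenset("AC") in nt or frozenset("BD") in nt
        assert all(s.support == pytest.approx(0.5) for s in net.nontrivial())

    def test_higher_threshold_drops_conflict(self):
        trees = [_quartet("A", "B", "C", "D")] * 5 + \
                [_quartet("B", "D", "A", "C")] * 5
        net = consensus_network(trees, min_support=0.6)
        assert net.nontrivial() == []
        # trivial splits always survive
        assert len(net.splits) == 4

    def test_mismatched_leaf_sets_raise(self):
        with pytest.raises(ValueError):
            consensus_network([_quartet("A", "B", "C", "D"),
                               _quartet("A", "B", "C", "E")])

    def test_nexus_writer_roundtrip_shape(self, tmp_path):
        trees = [_quartet("A", "B", "C", "D")] * 3
        net = consensus_network(trees)
        path = tmp_path / "splits.nex"
        write_splits_nexus(net, path)
        text = path.read_text()
        assert text.startswith("#nexus")
        assert "DIMENSIONS ntax=4" in text
        assert f"nsplits={len(net.splits)}" in text
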