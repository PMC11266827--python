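"""Repeat-cluster phylogenetics: observed/expected edge matrices,
inverse-similarity distances, neighbor joining and the consensus split
network.

For each repeat cluster shared across samples, the number of similarity
edges observed between each sample pair is compared with the expectation
under uniform random edge placement given the cluster's per-sample node
counts.  obs/exp > 1 marks sample pairs whose reads are more alike than
random mixing; its inverse is used as a phylogenetic distance.  Clusters
missing a sample, or with a zero observed cross-sample entry, are excluded
rather than patched.  Per-cluster NJ trees are finally condensed into a
consensus split network (all bipartitions above a support threshold).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import HitTable, RepeatCluster


@dataclass
class ClusterSimilarityMatrix:
    cluster_id: int
    samples: list[str]
    obs_exp: np.ndarray  # symmetric, includes diagonal
    complete: bool


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        self.d = d


def observed_expected_matrix(cluster: RepeatCluster, hits: HitTable,
                             sample_idx: np.ndarray, samples: list[str],
                             ) -> ClusterSimilarityMatrix:
    """Observed/expected edge counts between samples inside one cluster.

    expected(s,t) = E * n_s * n_t / P for s != t and E * C(n_s,2) / P on
    the diagonal, where E is the cluster's edge count, n_* its per-sample
    node counts and P the number of unordered node pairs.
    """
    members = cluster.members
    n_nodes = len(members)
    memberset = np.zeros(hits.n_reads, dtype=bool)
    memberset[members] = True
    sel = memberset[hits.a] & memberset[hits.b]
    E = int(sel.sum())
    if E == 0:
        raise ValueError(f"cluster {cluster.cluster_id} has no edges")

    S = len(samples)
    code_to_i = {s: i for i, s in enumerate(samples)}
    node_counts = np.zeros(S, dtype=np.int64)
    for m in members.tolist():
        node_counts[sample_idx[m]] += 1

    obs = np.zeros((S, S), dtype=np.int64)
    sa = sample_idx[hits.a[sel]]
    sb = sample_idx[hits.b[sel]]
    np.add.at(obs, (sa, sb), 1)
    obs = obs + obs.T - np.diag(np.diag(obs))  # symmetrize, diagonal once

    P = n_nodes * (n_nodes - 1) / 2
    expected = np.outer(node_counts, node_counts).astype(float)
    np.fill_diagonal(expected, node_counts * (node_counts - 1) / 2)
    expected = expected * E / P
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(expected > 0, obs / np.where(expected > 0, expected, 1),
                           0.0)

    off = ~np.eye(S, dtype=bool)
    complete = bool(np.all(node_counts > 0) and np.all(obs_exp[off] > 0))
    return ClusterSimilarityMatrix(cluster_id=cluster.cluster_id,
                                   samples=list(samples), obs_exp=obs_exp,
                                   complete=complete)


def to_distance(matrix: ClusterSimilarityMatrix) -> DistanceMatrix | None:
    """Inverse-similarity distance, or None when the cluster is excluded."""
    if not matrix.complete:
        return None
    S = len(matrix.samples)
    d = np.zeros((S, S))
    off = ~np.eye(S, dtype=bool)
    d[off] = 1.0 / matrix.obs_exp[off]
    d = (d + d.T) / 2  # enforce exact symmetry against float asymmetry
    return DistanceMatrix(samples=list(matrix.samples), d=d)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Minimal unrooted-tree node: leaves carry names, internals children."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree over samples (stored rooted at an internal node)."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def newick(self) -> str:
        return self.root.newick()

    def _adjacency(self):
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        counter = [0]

        def walk(node: TreeNode) -> int:
            nid = counter[0]
            counter[0] += 1
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[nid] = node.name
            for child, bl in node.children:
                cid = walk(child)
                adj[nid].append((cid, bl))
                adj[cid].append((nid, bl))
            return nid

        walk(self.root)
        return adj, names

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (sorted leaf order)."""
        adj, names = self._adjacency()
        leaves = sorted(names.items(), key=lambda kv: kv[1])
        order = [nid for nid, _ in leaves]
        labels = [nm for _, nm in leaves]
        D = np.zeros((len(order), len(order)))
        for i, src in enumerate(order):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, bl in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + bl
                        stack.append(v)
            for j, dst in enumerate(order):
                D[i, j] = dist[dst]
        np.fill_diagonal(D, 0.0)
        return DistanceMatrix(samples=labels, d=D)

    def splits(self, nontrivial_only: bool = False):
        """Bipartitions as (frozenset smaller-side, branch length).

        Each edge yields the split separating the subtree below it; the
        side not containing the alphabetically first leaf is reported.
        """
        all_leaves = frozenset(self.root.leaf_names())
        anchor = min(all_leaves)
        out: list[tuple[frozenset, float]] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, bl in node.children:
                sub = walk(child)
                side = sub if anchor not in sub else all_leaves - sub
                if 1 <= len(side) <= len(all_leaves) - 1:
                    if not (nontrivial_only and
                            min(len(side), len(all_leaves) - len(side)) < 2):
                        out.append((side, bl))
                below = below | sub
            return below

        walk(self.root)
        return out


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Classical agglomerative NJ with deterministic tie-breaking.

    Q-criterion joins; ties resolved toward the lexicographically smallest
    label pair; negative branch lengths clamped to zero with the deficit
    shifted to the sister branch.
    """
    labels = list(dist.samples)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dist.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in labels]
    # sort key per active node: smallest leaf label beneath it
    keys: list[str] = list(labels)
    active = list(range(n))

    def clamp(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((ia, ja) for ia, ja in cand if ia < ja),
            key=lambda t: tuple(sorted((keys[active[t[0]]], keys[active[t[1]]]))))
        ia, ja = best
        i, j = active[ia], active[ja]
        dij = D[i, j]
        vi = 0.5 * dij + (sums[ia] - sums[ja]) / (2 * (r - 2))
        vj = dij - vi
        vi, vj = clamp(vi, vj)
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        # distances to the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        D[-1, -1] = 0.0
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    root = TreeNode(children=[(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# consensus split network


@dataclass
class Split:
    side: frozenset
    support: float
    weight: float


@dataclass
class SplitSet:
    taxa: list[str]
    splits: list[Split]

    def find(self, side: frozenset) -> Split | None:
        all_taxa = frozenset(self.taxa)
        side = side if min(all_taxa) not in side else all_taxa - side
        for s in self.splits:
            if s.side == side:
                return s
        return None

    def nontrivial(self) -> list[Split]:
        nt = len(self.taxa)
        return [s for s in self.splits if 2 <= len(s.side) <= nt - 2]


def consensus_network(trees: list[PhyloTree], min_support: float = 0.1) -> SplitSet:
    """Consensus split network of a set of trees on one leaf set.

    Splits occurring in at least ``min_support`` of the trees are retained
    (trivial splits always); weight is the mean branch length over the
    trees containing the split.
    """
    if not trees:
        raise ValueError("need at least one tree")
    taxa = trees[0].leaf_names()
    taxa_set = frozenset(taxa)
    for t in trees[1:]:
        if frozenset(t.leaf_names()) != taxa_set:
            raise ValueError("trees have mismatched leaf sets")

    counts: dict[frozenset, int] = {}
    weights: dict[frozenset, float] = {}
    for t in trees:
        seen_here: dict[frozenset, float] = {}
        for side, bl in t.splits():
            # a split may appear once per tree; keep max length if repeated
            seen_here[side] = max(seen_here.get(side, 0.0), bl)
        for side, bl in seen_here.items():
            counts[side] = counts.get(side, 0) + 1
            weights[side] = weights.get(side, 0.0) + bl

    n_trees = len(trees)
    splits = []
    for side, cnt in counts.items():
        support = cnt / n_trees
        trivial = min(len(side), len(taxa) - len(side)) == 1
        if trivial or support >= min_support - 1e-12:
            splits.append(Split(side=side, support=support,
                                weight=weights[side] / cnt))
    # guarantee every trivial split is present
    for leaf in taxa:
        side = frozenset(taxa_set - {leaf}) if leaf == min(taxa) else frozenset([leaf])
        if not any(s.side == side for s in splits):
            splits.append(Split(side=side, support=0.0, weight=0.0))
    splits.sort(key=lambda s: (len(s.side), sorted(s.side)))
    return SplitSet(taxa=taxa, splits=splits)


def write_splits_nexus(splitset: SplitSet, path) -> None:
    """SplitsTree-consumable nexus splits block."""
    taxa = splitset.taxa
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    lines = ["#nexus", "", "BEGIN Taxa;", f"DIMENSIONS ntax={len(taxa)};",
             "TAXLABELS"]
    lines += [f"[{i + 1}] '{t}'" for i, t in enumerate(taxa)]
    lines += [";", "END;", "", "BEGIN Splits;",
              f"DIMENSIONS ntax={len(taxa)} nsplits={len(splitset.splits)};",
              "FORMAT labels=no weights=yes confidences=yes;", "MATRIX"]
    for si, s in enumerate(splitset.splits):
        members = " ".join(str(idx[t]) for t in sorted(s.side, key=lambda t: idx[t]))
        lines.append(f"[{si + 1}, size={len(s.side)}]\t{s.weight:.6g}\t"
                     f"{s.support:.4g}\t{members},")
    lines += [";", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def random_additive_tree(labels: list[str], rng: np.random.Generator,
                         bl_range: tuple[float, float] = (0.1, 1.0),
                         ) -> tuple[PhyloTree, DistanceMatrix]:
    """Random unrooted binary tree with positive branch lengths and its
    (additive) leaf distance matrix — the tree-metric oracle for NJ."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def bl() -> float:
        return float(rng.uniform(*bl_range))

    # maintain a list of edges (parent, child-slot) by growing from a
    # 3-leaf star, attaching each new leaf to a uniformly random edge
    root = TreeNode(children=[(TreeNode(name=labels[0]), bl()),
                              (TreeNode(name=labels[1]), bl()),
                              (TreeNode(name=labels[2]), bl())])
    edges: list[tuple[TreeNode, int]] = [(root, 0), (root, 1), (root, 2)]
    for name in labels[3:]:
        parent, slot = edges[int(rng.integers(len(edges)))]
        child, old_bl = parent.children[slot]
        split_at = float(rng.uniform(0.25, 0.75)) * old_bl
        mid = TreeNode(children=[(child, old_bl - split_at),
                                 (TreeNode(name=name), bl())])
        parent.children[slot] = (mid, split_at)
        edges = _collect_edges(root)
    tree = PhyloTree(root=root)
    return tree, tree.distance_matrix()


def _collect_edges(root: TreeNode) -> list[tuple[TreeNode, int]]:
    out = []

    def walk(node: TreeNode):
        for i, (child, _) in enumerate(node.children):
            out.append((node, i))
            walk(child)

    walk(root)
    return out
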