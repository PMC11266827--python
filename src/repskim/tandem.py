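"""Tandem-repeat cluster characterization and 5S rDNA graph typing.

A high-copy tandem repeat read cluster behaves like a circular sequence:
its k-mer graph contains a heavy cycle whose length is the monomer.  This
module extracts that cycle greedily over a sweep of k values, scores it by
k-mer coverage (frequency mass of the cycle's k-mers over all k-mer
frequency mass), computes the connected-component index C of the cluster
subgraph, and types 5S rDNA clusters by counting intergenic-spacer (IGS)
loops: reads matching the conserved 5S gene are removed and the remaining
spacer reads are re-clustered, one sub-cluster per ribotype loop.
Graph shapes 1/2/3 (one circular loop; two or three IGS loops joined at
the conserved gene) then index the number of 5S ribotypes, and hence
subgenomes, in the sample.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .graph import (DisjointSet, HitTable, ReadGraph, RepeatCluster,
                    cluster_reads, find_similarity_hits)
from .synth import ReadSet

DEFAULT_K_SWEEP = (11, 15, 19, 23, 27)


class ClassificationError(ValueError):
    """A 5S cluster without gene-matching reads cannot be typed."""


def c_index(n_nodes: int, edges_a: np.ndarray, edges_b: np.ndarray) -> float:
    """Largest connected component size / number of nodes."""
    if n_nodes <= 0:
        raise ValueError("empty graph")
    dsu = DisjointSet(n_nodes)
    for x, y in zip(edges_a.tolist(), edges_b.tolist()):
        dsu.union(x, y)
    labels = dsu.labels()
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max()) / n_nodes


def _revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


@dataclass
class TandemConsensus:
    tandem: bool
    consensus: np.ndarray | None  # one linear monomer of the circular path
    kmer_coverage: float
    k: int

    @property
    def consensus_length(self) -> int:
        return 0 if self.consensus is None else len(self.consensus)

    @property
    def consensus_str(self) -> str:
        return "" if self.consensus is None else _seq.decode(self.consensus)


def _directed_kmer_counts(mat: np.ndarray, k: int) -> dict[int, int]:
    """Directed k-mer occurrence counts over reads plus their reverse
    complements (strand-symmetric by construction)."""
    both = np.concatenate([mat, _seq.revcomp_rows(mat)])
    n, L = both.shape
    W = L - k + 1
    safe = np.where(both < 4, both, 0).astype(np.int64)
    code = np.zeros((n, W), dtype=np.int64)
    for i in range(k):
        code = (code << 2) | safe[:, i:i + W]
    valid = np.ones((n, W), dtype=bool)
    bad = both >= 4
    if bad.any():
        for i in range(k):
            valid &= ~bad[:, i:i + W]
    vals, cnt = np.unique(code[valid], return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


def _greedy_cycle(counts: dict[int, int], k: int, min_count: int):
    """Follow heaviest successors from the heaviest k-mer until a k-mer on
    the current path repeats (cycle) or no successor survives (dead end)."""
    if not counts:
        return None
    mx = max(counts.values())
    start = min(c for c, v in counts.items() if v == mx)
    mask = (1 << (2 * (k - 1))) - 1
    path: list[int] = []
    seen: dict[int, int] = {}
    node = start
    while True:
        if node in seen:
            return path[seen[node]:]
        seen[node] = len(path)
        path.append(node)
        suffix = (node & mask) << 2
        best, best_cnt = None, 0
        for b in range(4):
            nxt = suffix | b
            cnt = counts.get(nxt, 0)
            if cnt >= min_count and cnt > best_cnt:
                best, best_cnt = nxt, cnt
        if best is None:
            return None
        node = best


def kmer_consensus(reads: ReadSet | np.ndarray,
                   k_candidates: tuple[int, ...] = DEFAULT_K_SWEEP,
                   min_count: int = 2) -> TandemConsensus:
    """Monomer consensus of a tandem cluster by greedy max-weight cycle.

    For each k the k-mer frequency graph (both strands) is walked greedily
    from the heaviest k-mer; the k-mer coverage is the frequency mass of
    the cycle's k-mers (both orientations) over all k-mer mass.  The k
    maximizing coverage wins.  Clusters whose graphs contain no cycle are
    flagged non-tandem.
    """
    mat = reads.seqs if isinstance(reads, ReadSet) else np.asarray(reads)
    if mat.shape[1] <= max(k_candidates):
        raise ValueError("reads shorter than the largest k")
    best: TandemConsensus | None = None
    for k in k_candidates:
        counts = _directed_kmer_counts(mat, k)
        cycle = _greedy_cycle(counts, k, min_count)
        if cycle is None or len(cycle) < k:
            continue
        on_path = set()
        num = 0
        for code in cycle:
            canon = min(code, _revcomp_code(code, k))
            if canon not in on_path:
                on_path.add(canon)
                num += counts.get(code, 0) + counts.get(_revcomp_code(code, k), 0)
        den = sum(counts.values())
        coverage = num / den if den else 0.0
        consensus = np.array([(c >> (2 * (k - 1))) & 3 for c in cycle],
                             dtype=np.uint8)
        cand = TandemConsensus(True, consensus, float(coverage), k)
        if (best is None or cand.kmer_coverage > best.kmer_coverage
                or (cand.kmer_coverage == best.kmer_coverage
                    and cand.consensus_length > best.consensus_length)):
            best = cand
    if best is None:
        return TandemConsensus(False, None, 0.0, 0)
    return best


# ---------------------------------------------------------------------------
# 5S graph typing


def _best_identity_vs_exemplar(mat: np.ndarray, exemplar: np.ndarray,
                               min_overlap: int) -> np.ndarray:
    """Best ungapped-overlap identity of each read against an exemplar
    sequence (both strands), requiring at least ``min_overlap`` columns."""
    L = mat.shape[1]
    M = len(exemplar)
    best = np.zeros(mat.shape[0])
    for target in (exemplar, _seq.revcomp(exemplar)):
        for offset in range(-(L - min_overlap), M - min_overlap + 1):
            lo = max(0, offset)
            hi = min(L + offset, M)
            if hi - lo < min_overlap:
                continue
            x = mat[:, lo - offset:hi - offset]
            y = target[lo:hi]
            ident = ((x == y) & (x < 4)).mean(axis=1)
            np.maximum(best, ident, out=best)
    return best


@dataclass
class FiveSTyping:
    loop_count: int
    graph_type: int
    n_gene_reads: int
    n_igs_reads: int
    loop_sizes: list[int]


def classify_5s_graph(cluster_reads_mat: np.ndarray, gene_exemplar: np.ndarray,
                      min_gene_identity: float = 0.80, min_gene_overlap: int = 40,
                      min_identity: float = 0.90, min_overlap: int = 55,
                      min_loop_fraction: float = 0.05) -> FiveSTyping:
    """Count IGS loops of a 5S rDNA cluster and assign graph type 1/2/3.

    Reads matching the conserved gene exemplar (>= 80% identity over >= 40
    bp by default) form the loop junction and are set aside; the remaining
    spacer reads are re-clustered under the standard 90%/55 contract, and
    each sub-cluster holding at least 5% of the cluster's reads counts as
    one IGS loop.
    """
    n_total = cluster_reads_mat.shape[0]
    if n_total == 0:
        raise ClassificationError("empty cluster")
    ident = _best_identity_vs_exemplar(cluster_reads_mat, gene_exemplar,
                                       min_gene_overlap)
    gene_mask = ident >= min_gene_identity
    if not gene_mask.any():
        raise ClassificationError("no reads match the 5S gene exemplar")
    igs = cluster_reads_mat[~gene_mask]
    loop_sizes: list[int] = []
    if igs.shape[0] >= 2:
        hits = find_similarity_hits(igs, min_identity, min_overlap)
        graph = ReadGraph(igs.shape[0], hits)
        clusters, _ = cluster_reads(graph)
        min_size = min_loop_fraction * n_total
        loop_sizes = [c.size for c in clusters if c.size >= min_size]
    loop_count = len(loop_sizes)
    graph_type = min(max(loop_count, 1), 3)
    return FiveSTyping(loop_count=loop_count, graph_type=graph_type,
                       n_gene_reads=int(gene_mask.sum()),
                       n_igs_reads=int((~gene_mask).sum()),
                       loop_sizes=loop_sizes)


@dataclass
class TandemGraphProfile:
    """Table-shaped summary of one tandem cluster (5S rDNA style)."""

    cluster_id: int
    n_reads: int
    genome_proportion: float
    consensus: str
    consensus_length: int
    kmer_coverage: float
    C_index: float
    loop_count: int
    graph_type: int


def profile_tandem_cluster(cluster: RepeatCluster, reads: ReadSet,
                           hits: HitTable, total_reads: int,
                           gene_exemplar: np.ndarray | None = None,
                           ) -> TandemGraphProfile:
    """Assemble the full tandem profile of one cluster.

    ``hits`` is the hit table of the whole analysis; edges are restricted
    to the cluster to compute C.  5S loop typing runs only when a gene
    exemplar is supplied.
    """
    members = cluster.members
    memberset = np.zeros(hits.n_reads, dtype=bool)
    memberset[members] = True
    sel = memberset[hits.a] & memberset[hits.b]
    remap = np.full(hits.n_reads, -1, dtype=np.int64)
    remap[members] = np.arange(len(members))
    C = c_index(len(members), remap[hits.a[sel]], remap[hits.b[sel]])

    mat = reads.seqs[members]
    cons = kmer_consensus(mat)
    if gene_exemplar is not None and cons.tandem:
        typing = classify_5s_graph(mat, gene_exemplar)
        loop_count, graph_type = typing.loop_count, typing.graph_type
    elif cons.tandem:
        loop_count, graph_type = 1, 1
    else:
        loop_count, graph_type = 0, 0
    return TandemGraphProfile(
        cluster_id=cluster.cluster_id, n_reads=len(members),
        genome_proportion=len(members) / total_reads,
        consensus=cons.consensus_str, consensus_length=cons.consensus_length,
        kmer_coverage=cons.kmer_coverage, C_index=C,
        loop_count=loop_count, graph_type=graph_type)
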