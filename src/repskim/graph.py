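"""All-vs-all read similarity graph and cluster extraction.

Two reads are linked when they admit an ungapped overlap alignment (either
orientation) of length >= ``min_overlap`` whose identity, computed over the
overlap only, is >= ``min_identity`` (defaults 55 bp / 90%, the standard
graph-clustering contract for repeat identification from skim reads).

Candidate pairs are seeded by shared k-mers (both strands) and every
candidate is verified exactly, so no reported hit ever violates the
contract.  ``brute_force_hits`` scans all offsets of all pairs and serves
as the independent oracle at small n.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .synth import ReadSet

ORIENT_SAME = 0
ORIENT_REVERSE = 1

_EPS = 1e-12


@dataclass
class HitTable:
    """Edge list of the read-similarity graph (one row per unordered pair)."""

    a: np.ndarray  # int64, a < b
    b: np.ndarray
    overlap: np.ndarray  # int64
    identity: np.ndarray  # float64
    orientation: np.ndarray  # uint8: 0 same, 1 reverse
    n_reads: int

    @property
    def n_hits(self) -> int:
        return len(self.a)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.a.tolist(), self.b.tolist()))

    def to_dataframe(self, ids: list[str] | None = None) -> pd.DataFrame:
        name = (lambda i: ids[i]) if ids is not None else (lambda i: int(i))
        return pd.DataFrame({
            "read_a": [name(i) for i in self.a],
            "read_b": [name(i) for i in self.b],
            "overlap": self.overlap,
            "identity": np.round(self.identity, 6),
            "orientation": np.where(self.orientation == ORIENT_SAME, "same", "reverse"),
        })


@dataclass
class RepeatCluster:
    """A connected group of reads, ranked by size (cluster_id 1 = largest)."""

    cluster_id: int
    members: np.ndarray  # sorted read indices
    size_fraction: float
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ReadGraph:
    """Read-similarity graph plus per-sample node bookkeeping."""

    n_reads: int
    hits: HitTable
    sample_idx: np.ndarray | None = None
    sample_codes: list[str] | None = None

    @classmethod
    def from_readset(cls, reads: ReadSet, hits: HitTable) -> "ReadGraph":
        return cls(reads.n_reads, hits, reads.sample_idx, list(reads.sample_codes))


class DisjointSet:
    """Array-based union-find with path halving."""

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return int(x)

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        if ry < rx:  # keep smallest index as root -> deterministic
            rx, ry = ry, rx
        self.parent[ry] = rx
        return True

    def labels(self) -> np.ndarray:
        p = self.parent
        # flatten completely
        for i in range(len(p)):
            r = i
            while p[r] != r:
                r = p[r]
            p[i] = r
        return p.copy()


# ---------------------------------------------------------------------------
# k-mer machinery


def _kmer_entries(mat: np.ndarray, k: int):
    """Canonical k-mer table of a read matrix.

    Returns (code, read, pos, strand) arrays where ``strand`` is 0 when the
    forward k-mer is the canonical one.  Windows containing N are dropped.
    """
    n, L = mat.shape
    if k > L:
        raise ValueError("k longer than read length")
    W = L - k + 1
    safe = np.where(mat < 4, mat, 0).astype(np.int64)
    fwd = np.zeros((n, W), dtype=np.int64)
    for i in range(k):
        fwd = (fwd << 2) | safe[:, i:i + W]
    rc_mat = _seq.revcomp_rows(mat)
    safe_rc = np.where(rc_mat < 4, rc_mat, 0).astype(np.int64)
    rcod = np.zeros((n, W), dtype=np.int64)
    for i in range(k):
        rcod = (rcod << 2) | safe_rc[:, i:i + W]
    rc = rcod[:, ::-1]  # rc[:, p] = revcomp of fwd[:, p]

    valid = np.ones((n, W), dtype=bool)
    bad = mat >= 4
    if bad.any():
        for i in range(k):
            valid &= ~bad[:, i:i + W]

    strand = (rc < fwd).astype(np.uint8)
    code = np.minimum(fwd, rc)
    read = np.broadcast_to(np.arange(n, dtype=np.int64)[:, None], (n, W))
    pos = np.broadcast_to(np.arange(W, dtype=np.int64)[None, :], (n, W))
    v = valid.ravel()
    return code.ravel()[v], read.ravel()[v], pos.ravel()[v], strand.ravel()[v]


def _candidate_tuples(mat: np.ndarray, k: int):
    """Unique (a, b, orientation, offset) candidates from shared k-mers.

    offset is the start of read b (in the compared orientation) within
    read a's coordinates; a < b always.
    """
    n, L = mat.shape
    code, read, pos, strand = _kmer_entries(mat, k)
    order = np.argsort(code, kind="stable")
    code, read, pos, strand = code[order], read[order], pos[order], strand[order]
    boundaries = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(code)]])

    A, B, OR, OFF = [], [], [], []
    W1 = L - k  # pos of last k-mer window
    for s, e in zip(starts, ends):
        m = e - s
        if m < 2:
            continue
        r = read[s:e]
        p = pos[s:e]
        st = strand[s:e]
        iu, ju = np.triu_indices(m, 1)
        keep = r[iu] != r[ju]
        if not keep.any():
            continue
        iu, ju = iu[keep], ju[keep]
        ra, rb = r[iu], r[ju]
        pa, pb = p[iu], p[ju]
        sa, sb = st[iu], st[ju]
        # enforce a < b by swapping
        swap = ra > rb
        ra2 = np.where(swap, rb, ra)
        rb2 = np.where(swap, ra, rb)
        pa2 = np.where(swap, pb, pa)
        pb2 = np.where(swap, pa, pb)
        sa2 = np.where(swap, sb, sa)
        sb2 = np.where(swap, sa, sb)
        same = sa2 == sb2
        off = np.where(same, pa2 - pb2, pa2 - (W1 - pb2))
        A.append(ra2)
        B.append(rb2)
        OR.append((~same).astype(np.int64))
        OFF.append(off)
    if not A:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, empty
    a = np.concatenate(A)
    b = np.concatenate(B)
    o = np.concatenate(OR)
    off = np.concatenate(OFF)
    key = ((a * n + b) * 2 + o) * (2 * L + 1) + (off + L)
    _, first = np.unique(key, return_index=True)
    return a[first], b[first], o[first], off[first]


def _verify_batch(mat: np.ndarray, rc_mat: np.ndarray, a, b, orient, off,
                  min_identity: float, min_overlap: int):
    """Vectorized overlap verification of candidate alignments."""
    L = mat.shape[1]
    overlap = L - np.abs(off)
    ok = overlap >= min_overlap
    a, b, orient, off, overlap = a[ok], b[ok], orient[ok], off[ok], overlap[ok]
    matches = np.zeros(len(a), dtype=np.int64)
    for o_flag, other in ((ORIENT_SAME, mat), (ORIENT_REVERSE, rc_mat)):
        sel_or = orient == o_flag
        if not sel_or.any():
            continue
        for offset in np.unique(off[sel_or]):
            sel = sel_or & (off == offset)
            ia, ib = a[sel], b[sel]
            if offset >= 0:
                x = mat[ia][:, offset:]
                y = other[ib][:, :L - offset]
            else:
                x = mat[ia][:, :L + offset]
                y = other[ib][:, -offset:]
            matches[sel] = ((x == y) & (x < 4)).sum(axis=1)
    identity = matches / overlap
    good = identity >= min_identity - _EPS
    return a[good], b[good], overlap[good], identity[good], orient[good], off[good]


def _best_per_pair(a, b, overlap, identity, orient, off, n: int) -> HitTable:
    if len(a) == 0:
        e = np.empty(0, dtype=np.int64)
        return HitTable(e, e, e.copy(), np.empty(0), e.astype(np.uint8), n)
    # best = max identity, then longest overlap, then same before reverse,
    # then smallest offset (deterministic)
    order = np.lexsort((off, orient, -overlap, -identity, a * n + b))
    a, b = a[order], b[order]
    overlap, identity = overlap[order], identity[order]
    orient = orient[order]
    pair = a * n + b
    first = np.concatenate([[True], np.diff(pair) != 0])
    return HitTable(a[first], b[first], overlap[first], identity[first],
                    orient[first].astype(np.uint8), n)


def find_similarity_hits(reads: ReadSet | np.ndarray, min_identity: float = 0.90,
                         min_overlap: int = 55, k: int = 13) -> HitTable:
    """Seeded exact overlap search over all read pairs.

    Every unordered pair admitting a qualifying ungapped overlap whose
    alignment retains at least one shared k-mer is reported with its
    best-scoring overlap.
    """
    mat = reads.seqs if isinstance(reads, ReadSet) else np.asarray(reads)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValueError("need a non-empty read matrix")
    if not 0 < min_identity <= 1 or min_overlap < 1:
        raise ValueError("bad thresholds")
    a, b, orient, off = _candidate_tuples(mat, k)
    rc_mat = _seq.revcomp_rows(mat)
    res = _verify_batch(mat, rc_mat, a, b, orient, off, min_identity, min_overlap)
    return _best_per_pair(*res, n=mat.shape[0])


def brute_force_hits(reads: ReadSet | np.ndarray, min_identity: float = 0.90,
                     min_overlap: int = 55) -> HitTable:
    """Reference all-offset overlap scan (quadratic; small inputs only)."""
    mat = reads.seqs if isinstance(reads, ReadSet) else np.asarray(reads)
    n, L = mat.shape
    rc_mat = _seq.revcomp_rows(mat)
    A, B, OV, ID, OR = [], [], [], [], []
    for i in range(n):
        xi = mat[i]
        for j in range(i + 1, n):
            best = None
            for o_flag, yj in ((ORIENT_SAME, mat[j]), (ORIENT_REVERSE, rc_mat[j])):
                for offset in range(-(L - min_overlap), L - min_overlap + 1):
                    if offset >= 0:
                        x, y = xi[offset:], yj[:L - offset]
                    else:
                        x, y = xi[:L + offset], yj[-offset:]
                    overlap = len(x)
                    matches = int(((x == y) & (x < 4)).sum())
                    ident = matches / overlap
                    if ident < min_identity - _EPS:
                        continue
                    cand = (ident, overlap, -o_flag, -offset)
                    if best is None or cand > best[0]:
                        best = (cand, overlap, ident, o_flag)
            if best is not None:
                A.append(i)
                B.append(j)
                OV.append(best[1])
                ID.append(best[2])
                OR.append(best[3])
    return HitTable(np.array(A, dtype=np.int64), np.array(B, dtype=np.int64),
                    np.array(OV, dtype=np.int64), np.array(ID, dtype=float),
                    np.array(OR, dtype=np.uint8), n)


# ---------------------------------------------------------------------------
# clustering


def _rank_components(labels: np.ndarray, total_reads: int):
    roots, inverse, sizes = np.unique(labels, return_inverse=True,
                                      return_counts=True)
    clusters = []
    unclustered = []
    comp_members = {}
    order = np.argsort(inverse, kind="stable")
    sorted_idx = np.arange(len(labels))[order]
    boundaries = np.cumsum(sizes)
    start = 0
    for ci, end in enumerate(boundaries):
        members = np.sort(sorted_idx[start:end])
        start = end
        if len(members) == 1:
            unclustered.append(int(members[0]))
        else:
            comp_members[ci] = members
    ranked = sorted(comp_members.values(),
                    key=lambda m: (-len(m), int(m[0])))
    clusters = [RepeatCluster(cluster_id=r + 1, members=m,
                              size_fraction=len(m) / total_reads)
                for r, m in enumerate(ranked)]
    return clusters, sorted(unclustered)


def _attach_sample_counts(clusters, sample_idx, sample_codes):
    if sample_idx is None:
        return
    for c in clusters:
        counts = np.bincount(sample_idx[c.members], minlength=len(sample_codes))
        c.sample_counts = {code: int(x) for code, x in zip(sample_codes, counts)
                           if x > 0}


def cluster_reads(graph: ReadGraph, total_reads: int | None = None,
                  refine_modularity: float | None = None,
                  ) -> tuple[list[RepeatCluster], list[int]]:
    """Connected components of the similarity graph, ranked by size.

    Singletons are returned separately as unclustered.  When
    ``refine_modularity`` is set, components whose Louvain partition exceeds
    that modularity are split into communities.
    """
    n = graph.n_reads
    total = total_reads if total_reads is not None else n
    dsu = DisjointSet(n)
    for x, y in zip(graph.hits.a.tolist(), graph.hits.b.tolist()):
        dsu.union(x, y)
    labels = dsu.labels()

    if refine_modularity is not None and graph.hits.n_hits:
        labels = _refine_components(labels, graph.hits, refine_modularity)

    clusters, unclustered = _rank_components(labels, total)
    _attach_sample_counts(clusters, graph.sample_idx, graph.sample_codes)
    return clusters, unclustered


def _refine_components(labels, hits: HitTable, threshold: float):
    import networkx as nx

    labels = labels.copy()
    next_label = int(labels.max()) + 1
    edge_root = labels[hits.a]
    for root in np.unique(edge_root):
        sel = edge_root == root
        G = nx.Graph()
        G.add_edges_from(zip(hits.a[sel].tolist(), hits.b[sel].tolist()))
        if G.number_of_nodes() < 4:
            continue
        comms = nx.community.louvain_communities(G, seed=0)
        if len(comms) < 2:
            continue
        q = nx.community.modularity(G, comms)
        if q > threshold:
            for comm in comms:
                for node in comm:
                    labels[node] = next_label
                next_label += 1
    return labels


def filter_top_clusters(clusters: list[RepeatCluster], total_reads: int,
                        threshold: float = 0.0001) -> list[RepeatCluster]:
    """Keep clusters holding at least ``threshold`` of the analysed reads
    (default 0.01%, the standard top-cluster size cut)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return [c for c in clusters if c.size / total_reads >= threshold]


def _verify_pair(mat, rc_mat, ra, rb, orient, offset, min_identity, min_overlap):
    L = mat.shape[1]
    overlap = L - abs(offset)
    if overlap < min_overlap:
        return False
    y_mat = mat if orient == ORIENT_SAME else rc_mat
    if offset >= 0:
        x = mat[ra, offset:]
        y = y_mat[rb, :L - offset]
    else:
        x = mat[ra, :L + offset]
        y = y_mat[rb, -offset:]
    matches = int(((x == y) & (x < 4)).sum())
    return matches >= (min_identity - _EPS) * overlap


def cluster_streaming(reads: ReadSet, min_identity: float = 0.90,
                      min_overlap: int = 55, k: int = 13,
                      total_reads: int | None = None,
                      ) -> tuple[list[RepeatCluster], list[int]]:
    """Memory-light clustering for large read sets.

    Walks the shared-k-mer buckets and merges components through exact
    verification of the k-mer-implied overlap, without materializing the
    full hit list.  Edges obey the same identity/overlap contract as
    :func:`find_similarity_hits`; in the deep-coverage regime of repeat
    clusters the resulting components coincide with the full construction.
    """
    mat = reads.seqs
    n, L = mat.shape
    total = total_reads if total_reads is not None else n
    rc_mat = _seq.revcomp_rows(mat)
    code, read, pos, strand = _kmer_entries(mat, k)
    order = np.argsort(code, kind="stable")
    code, read, pos, strand = code[order], read[order], pos[order], strand[order]
    # keep only buckets of size >= 2
    boundaries = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(code)]])
    sizes = ends - starts
    multi = sizes >= 2

    dsu = DisjointSet(n)
    W1 = L - k
    find = dsu.find
    for s, e in zip(starts[multi].tolist(), ends[multi].tolist()):
        r = read[s:e]
        p = pos[s:e]
        st = strand[s:e]
        # order members along the implied alignment axis so consecutive
        # members maximize their pairwise overlap; chain-verify neighbours
        key = np.where(st == 0, p, W1 - p)
        order = np.argsort(key, kind="stable")
        r, p, st = r[order], p[order], st[order]
        kk = key[order]
        m = e - s
        max_shift = L - min_overlap

        def attempt(u, t):
            ru, rt = int(r[u]), int(r[t])
            if ru == rt or find(ru) == find(rt):
                return
            if st[u] == st[t]:
                orient, offset = ORIENT_SAME, int(p[u]) - int(p[t])
            else:
                orient, offset = ORIENT_REVERSE, int(p[u]) - (W1 - int(p[t]))
            if _verify_pair(mat, rc_mat, ru, rt, orient, offset,
                            min_identity, min_overlap):
                dsu.union(ru, rt)

        # consecutive members share the largest overlaps; the farthest
        # member within the admissible shift provides the minimum-overlap
        # alignment that junction reads (partial family content) need
        lo = 0
        for t in range(m):
            if t:
                attempt(t - 1, t)
            while kk[t] - kk[lo] > max_shift:
                lo += 1
            if lo < t - 1:
                attempt(lo, t)

    labels = dsu.labels()
    clusters, unclustered = _rank_components(labels, total)
    _attach_sample_counts(clusters, reads.sample_idx, reads.sample_codes)
    return clusters, unclustered


# ---------------------------------------------------------------------------
# organelle pre-filter


def filter_organelle(reads: ReadSet, organelle_ref: np.ndarray, k: int = 24,
                     min_matches: int = 2) -> tuple[ReadSet, int]:
    """Drop read pairs matching an organelle reference.

    A pair is discarded when either mate shares at least ``min_matches``
    k-mer occurrences (either strand) with the reference.  Returns the
    retained reads (pairing preserved) and the number of pairs discarded.
    """
    if len(organelle_ref) == 0:
        raise ValueError("organelle reference is empty")
    if k > reads.read_length:
        raise ValueError("k longer than read length")
    ref = np.asarray(organelle_ref)
    ref_codes, _, _, _ = _kmer_entries(ref[None, :], k)
    refset = set(ref_codes.tolist())

    code, read, _, _ = _kmer_entries(reads.seqs, k)
    hits_per_read = np.zeros(reads.n_reads, dtype=np.int64)
    in_ref = np.fromiter((c in refset for c in code.tolist()),
                         count=len(code), dtype=bool)
    np.add.at(hits_per_read, read[in_ref], 1)

    bad_read = hits_per_read >= min_matches
    bad_pair = bad_read[0::2] | bad_read[1::2]
    keep = np.repeat(~bad_pair, 2)
    return reads.subset(np.flatnonzero(keep)), int(bad_pair.sum())
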