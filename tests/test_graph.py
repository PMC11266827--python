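"""Similarity-graph contract: hit finding vs the brute-force oracle,
strand closure, clustering and the organelle pre-filter."""
import numpy as np
import pytest

from repskim import _seq
from repskim.graph import (HitTable, ReadGraph, brute_force_hits,
                           cluster_reads, cluster_streaming,
                           filter_organelle, filter_top_clusters,
                           find_similarity_hits, RepeatCluster)
from repskim.synth import ReadSet, skim_reads


def _mat(*seqs):
    return np.stack([_seq.encode(s) for s in seqs])


def _random_read(rng, n=101):
    return _seq.decode(_seq.random_seq(rng, n))


class TestFindSimilarityHits:
    def test_identical_reads_single_full_hit(self, rng):
        r = _random_read(rng)
        hits = find_similarity_hits(_mat(r, r))
        assert hits.n_hits == 1
        assert hits.overlap[0] == 101
        assert hits.identity[0] == 1.0
        assert hits.orientation[0] == 0

    def test_reverse_complement_hit(self, rng):
        r = _seq.random_seq(rng, 101)
        hits = find_similarity_hits(np.stack([r, _seq.revcomp(r)]))
        assert hits.n_hits == 1
        assert hits.orientation[0] == 1
        assert hits.identity[0] == 1.0

    @pytest.mark.parametrize("n_mm,expect_hit", [(3, True), (7, False)])
    def test_identity_threshold_on_60bp_overlap(self, rng, n_mm, expect_hit):
        a = _seq.random_seq(rng, 101)
        b = np.concatenate([a[41:].copy(), _seq.random_seq(rng, 41)])
        mm_pos = np.linspace(5, 55, n_mm).astype(int)
        b[mm_pos] = (b[mm_pos] + 1) % 4
        hits = find_similarity_hits(np.stack([a, b]))
        if expect_hit:
            assert hits.n_hits == 1
            assert hits.overlap[0] == 60
            assert hits.identity[0] == pytest.approx((60 - n_mm) / 60)
        else:
            assert hits.n_hits == 0

    def test_strand_closure(self, two_family_reads):
        reads, _ = two_family_reads
        sub = reads.seqs[:80]
        hits = find_similarity_hits(sub)
        hits_rc = find_similarity_hits(_seq.revcomp_rows(sub))
        assert hits.pair_set() == hits_rc.pair_set()

    def test_seeded_equals_bruteforce_on_simulated_reads(self, two_family_reads):
        reads, _ = two_family_reads
        sub = reads.seqs[:70]
        seeded = find_similarity_hits(sub)
        brute = brute_force_hits(sub)
        assert seeded.pair_set() == brute.pair_set()
        # scores agree where both report a pair
        bi = {(a, b): i for i, (a, b) in enumerate(zip(brute.a, brute.b))}
        for i, (a, b) in enumerate(zip(seeded.a, seeded.b)):
            j = bi[(a, b)]
            assert seeded.overlap[i] == brute.overlap[j]
            assert seeded.identity[i] == pytest.approx(brute.identity[j])


class TestClustering:
    def test_edgeless_graph_all_unclustered(self):
        empty = np.empty(0, dtype=np.int64)
        hits = HitTable(empty, empty, empty.copy(), np.empty(0),
                        empty.astype(np.uint8), 10)
        clusters, unclustered = cluster_reads(ReadGraph(10, hits))
        assert clusters == []
        assert unclustered == list(range(10))

    def test_complete_graph_single_cluster(self, rng):
        r = _random_read(rng)
        mat = _mat(*[r] * 50)
        hits = find_similarity_hits(mat)
        clusters, unclustered = cluster_reads(ReadGraph(50, hits))
        assert len(clusters) == 1
        assert clusters[0].size == 50
        assert unclustered == []

    def test_two_planted_families_partition_by_provenance(self, two_family_reads):
        reads, _ = two_family_reads
        hits = find_similarity_hits(reads)
        clusters, _ = cluster_reads(ReadGraph.from_readset(reads, hits))
        big = [c for c in clusters if c.size >= 20]
        assert len(big) == 2
        for c in big:
            prov = reads.provenance[c.members]
            prov = prov[prov >= 0]
            # clean families: every labelled member from one family
            assert len(np.unique(prov)) == 1

    def test_streaming_partition_matches_full_clustering(self, two_family_reads):
        reads, _ = two_family_reads
        hits = find_similarity_hits(reads)
        full, _ = cluster_reads(ReadGraph.from_readset(reads, hits))
        stream, _ = cluster_streaming(reads)
        full_sets = sorted(frozenset(c.members.tolist()) for c in full
                           if c.size >= 20)
        stream_sets = sorted(frozenset(c.members.tolist()) for c in stream
                             if c.size >= 20)
        assert full_sets == stream_sets

    def test_majority_provenance_recovery_rate(self):
        from repskim.synth import (GenomeSpec, MonoploidBlueprint,
                                   RepeatFamilySpec, build_genome)
        fams = (RepeatFamilySpec("fa", "LTR-Gypsy", 1000, 30, 0.04),
                RepeatFamilySpec("fb", "LTR-Copia", 1000, 30, 0.05))
        bp = MonoploidBlueprint(background_length=100_000, families=fams,
                                site_spacing=300)
        spec = GenomeSpec(sample_code="RCVR", subgenomes=(bp,), seed=21)
        genome, truth = build_genome(spec)
        reads = skim_reads(genome, coverage=0.4, sample_code="RCVR",
                           rng=np.random.default_rng(21), truth=truth)
        hits = find_similarity_hits(reads)
        clusters, _ = cluster_reads(ReadGraph.from_readset(reads, hits))
        good = total = 0
        for c in clusters:
            prov = reads.provenance[c.members]
            labelled = prov[prov >= 0]
            if len(labelled) == 0:
                continue
            majority = np.bincount(labelled).argmax()
            good += int((prov == majority).sum())
            total += c.size
        assert total > 200
        assert good / total >= 0.95

    def test_cluster_ranking_and_tiebreak(self):
        a = np.array([0, 2, 5], dtype=np.int64)
        b = np.array([1, 3, 6], dtype=np.int64)
        hits = HitTable(a, b, np.full(3, 60), np.ones(3),
                        np.zeros(3, dtype=np.uint8), 8)
        clusters, unclustered = cluster_reads(ReadGraph(8, hits))
        assert [c.size for c in clusters] == [2, 2, 2]
        # equal sizes -> ordered by smallest member id
        assert [int(c.members[0]) for c in clusters] == [0, 2, 5]
        assert [c.cluster_id for c in clusters] == [1, 2, 3]
        assert unclustered == [4, 7]


class TestFilterTopClusters:
    def _clusters(self, sizes, total):
        return [RepeatCluster(i + 1, np.arange(s), s / total)
                for i, s in enumerate(sizes)]

    def test_001_percent_threshold(self):
        kept = filter_top_clusters(self._clusters([11, 9], 100_000), 100_000)
        assert [c.size for c in kept] == [11]

    def test_zero_threshold_keeps_all(self):
        kept = filter_top_clusters(self._clusters([11, 9], 100_000), 100_000,
                                   threshold=0.0)
        assert len(kept) == 2

    def test_three_cluster_example(self):
        kept = filter_top_clusters(self._clusters([500, 10, 9], 100_000),
                                   100_000)
        assert [c.size for c in kept] == [500, 10]


class TestOrganelleFilter:
    def _readset(self, mats):
        mat = np.stack(mats)
        n = mat.shape[0]
        return ReadSet(mat, np.zeros(n, dtype=np.int32), ["ORGA"],
                       np.repeat(np.arange(n // 2), 2),
                       np.tile(np.array([1, 2], dtype=np.uint8), n // 2))

    def test_plastome_substring_discards_pair(self, rng):
        ref = _seq.random_seq(rng, 10_000)
        mate1 = ref[100:201].copy()
        mate2 = _seq.random_seq(rng, 101)
        reads = self._readset([mate1, mate2])
        kept, n_discarded = filter_organelle(reads, ref)
        assert n_discarded == 1
        assert kept.n_reads == 0

    def test_single_shared_kmer_is_retained(self, rng):
        ref = _seq.random_seq(rng, 10_000)
        mate1 = np.concatenate([ref[:24].copy(), _seq.random_seq(rng, 77)])
        mate2 = _seq.random_seq(rng, 101)
        reads = self._readset([mate1, mate2])
        kept, n_discarded = filter_organelle(reads, ref)
        assert n_discarded == 0
        assert kept.n_reads == 2

    def test_random_reads_never_collide(self, rng):
        ref = _seq.random_seq(rng, 10_000)
        mats = [_seq.random_seq(rng, 101) for _ in range(1000)]
        kept, n_discarded = filter_organelle(self._readset(mats), ref)
        assert n_discarded == 0
        assert kept.n_reads == 1000

    def test_k_longer_than_read_raises(self, rng):
        reads = self._readset([_seq.random_seq(rng, 101)] * 2)
        with pytest.raises(ValueError):
            filter_organelle(reads, _seq.random_seq(rng, 1000), k=102)
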