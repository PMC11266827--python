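"""Genome-size arithmetic, annotation votes and abundance accounting."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from repskim import _seq
from repskim.graph import RepeatCluster
from repskim.quantify import (ALL_REPEATS, GenomeSizeRecord, RepeatLibrary,
                              UNCLASSIFIED, annotate_cluster, fold_ratio,
                              load_sample_table, monoploid_size, pg_to_mbp,
                              quantify)
from repskim.synth import ReadSet


class TestGenomeSizeArithmetic:
    @pytest.mark.parametrize("two_c,nx,expect", [
        (3.774, 4, 0.944),   # large ancestral allotetraploid
        (2.204, 6, 0.367),   # recent allohexaploid
        (1.0, 2, 0.5),
        (0.713, 2, 0.357),   # .3565 must round half-up
    ])
    def test_monoploid_size(self, two_c, nx, expect):
        assert monoploid_size(two_c, nx) == expect

    def test_monoploid_size_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            monoploid_size(0.0, 2)
        with pytest.raises(ValueError):
            monoploid_size(1.0, 1)

    @pytest.mark.parametrize("pg,mbp", [
        (3.774, 3690), (0.564, 551), (1.0, 978),
    ])
    def test_pg_to_mbp(self, pg, mbp):
        assert pg_to_mbp(pg) == mbp

    def test_record_holoploid_and_monoploid_mbp(self):
        big = GenomeSizeRecord.from_pg("big", 3.774, 4)
        small = GenomeSizeRecord.from_pg("small", 0.564, 2)
        assert (big.holoploid_mbp, big.monoploid_mbp) == (3690, 922)
        assert (small.holoploid_mbp, small.monoploid_mbp) == (551, 275)

    @pytest.mark.parametrize("a,b,expect", [
        (67.97, 20.77, 3.3), (3690, 551, 6.7), (5, 5, 1.0),
    ])
    def test_fold_ratio(self, a, b, expect):
        assert fold_ratio(a, b) == expect

    def test_fold_ratio_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_ratio(1.0, 0.0)

    def test_sample_table_shape(self):
        df = load_sample_table()
        assert len(df) == 44
        assert set(df["nx"]) == {2, 4, 6}

    @given(st.floats(0.01, 10.0), st.sampled_from([2, 4, 6]))
    def test_monoploid_size_three_decimals(self, two_c, nx):
        two_c = round(two_c, 3)
        v = monoploid_size(two_c, nx)
        assert v == round(v, 3)
        assert abs(v - two_c / nx) <= 0.0005 + 1e-12


def _exact_reads(consensus, n, offset_step=7, length=101):
    rows = [consensus[(i * offset_step) % (len(consensus) - length):]
            [:length] for i in range(n)]
    mat = np.stack(rows)
    return mat


class TestAnnotateCluster:
    def _library(self, rng):
        a = _seq.random_seq(rng, 1000)
        b = _seq.random_seq(rng, 1000)
        return a, b, RepeatLibrary({"Retand": [a], "Tekay": [b]})

    def _readset(self, mat):
        n = mat.shape[0]
        return ReadSet(mat, np.zeros(n, dtype=np.int32), ["ANNO"],
                       np.arange(n), np.ones(n, dtype=np.uint8))

    def test_pure_cluster_votes_unanimously(self, rng):
        a, _, lib = self._library(rng)
        mat = _exact_reads(a, 30)
        cluster = RepeatCluster(1, np.arange(30), 1.0)
        ann = annotate_cluster(cluster, self._readset(mat), lib)
        assert ann.lineage == "Retand"
        assert ann.vote_fraction == 1.0

    def test_unrelated_reads_are_unclassified(self, rng):
        _, _, lib = self._library(rng)
        mat = np.stack([_seq.random_seq(rng, 101) for _ in range(10)])
        cluster = RepeatCluster(1, np.arange(10), 1.0)
        ann = annotate_cluster(cluster, self._readset(mat), lib)
        assert ann.lineage == UNCLASSIFIED

    def test_mixed_cluster_majority_vote(self, rng):
        a, b, lib = self._library(rng)
        mat = np.concatenate([_exact_reads(a, 60), _exact_reads(b, 40)])
        cluster = RepeatCluster(1, np.arange(100), 1.0)
        ann = annotate_cluster(cluster, self._readset(mat), lib)
        assert ann.lineage == "Retand"
        assert ann.vote_fraction == pytest.approx(0.6)

    def test_below_min_vote_is_unclassified(self, rng):
        a, b, lib = self._library(rng)
        mat = np.concatenate([_exact_reads(a, 40), _exact_reads(b, 60)])
        cluster = RepeatCluster(1, np.arange(100), 1.0)
        ann = annotate_cluster(cluster, self._readset(mat), lib, min_vote=0.7)
        assert ann.lineage == UNCLASSIFIED


class TestQuantify:
    def _ann(self, cid, lineage):
        from repskim.quantify import RepeatAnnotation
        return RepeatAnnotation(cid, lineage, 1.0)

    def test_worked_example(self):
        cluster = RepeatCluster(1, np.arange(500), 0.05,
                                sample_counts={"S001": 500})
        rec = GenomeSizeRecord("S001", 0.818, 2, 0.409, 800, 400)
        table = quantify([cluster], [self._ann(1, "satellite")],
                         {"S001": 10_000}, {"S001": rec})
        sat = table[(table.lineage == "satellite")].iloc[0]
        assert sat.proportion == pytest.approx(0.05)
        assert sat.mbp == pytest.approx(20.0)

    def test_no_clusters_all_zero(self):
        table = quantify([], [], {"S001": 1000}, {})
        assert (table.proportion == 0).all()

    def test_all_repeats_row_sums_lineages(self):
        c1 = RepeatCluster(1, np.arange(100), 0.1, {"S001": 100})
        c2 = RepeatCluster(2, np.arange(50), 0.05, {"S001": 50})
        table = quantify([c1, c2],
                         [self._ann(1, "Retand"), self._ann(2, "Tekay")],
                         {"S001": 1000}, {})
        total = table[table.lineage == ALL_REPEATS].iloc[0].proportion
        parts = table[table.lineage != ALL_REPEATS].proportion.sum()
        assert total == pytest.approx(parts) == pytest.approx(0.15)

    def test_adding_reads_never_decreases_proportion(self):
        for extra in (0, 10, 25):
            c = RepeatCluster(1, np.arange(100 + extra), 0.0,
                              {"S001": 100 + extra})
            t = quantify([c], [self._ann(1, "Retand")], {"S001": 1000}, {})
            prop = t[t.lineage == "Retand"].iloc[0].proportion
            assert prop == pytest.approx((100 + extra) / 1000)

    def test_unknown_sample_raises(self):
        c = RepeatCluster(1, np.arange(10), 0.1, {"GHOST": 10})
        with pytest.raises(KeyError):
            quantify([c], [self._ann(1, "Retand")], {"S001": 100}, {})
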