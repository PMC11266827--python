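"""Generator invariants: additive lengths, planted-truth conservation,
polyploid dilution, read sampling and determinism."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from repskim import _seq
from repskim.synth import (FiveSUnitSpec, GenomeSpec, MonoploidBlueprint,
                           RepeatFamilySpec, SizingError, build_genome,
                           make_polyploid, simulate_monoploid, skim_reads)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSimulateMonoploid:
    def test_lengths_are_additive(self):
        bp = MonoploidBlueprint(
            background_length=100_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 1000, 10, 0.0),))
        seq, truth = simulate_monoploid(bp, _rng())
        assert len(seq) == 110_000
        assert truth.planted_bases["f"] == 10_000
        assert truth.planted_bases["f"] / len(seq) == pytest.approx(10_000 / 110_000)

    def test_no_families_returns_background(self):
        bp = MonoploidBlueprint(background_length=5_000)
        seq, truth = simulate_monoploid(bp, _rng())
        assert len(seq) == 5_000
        assert truth.planted_bases == {}

    def test_copy_divergence_matches_spec(self):
        bp = MonoploidBlueprint(
            background_length=60_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 500, 50, 0.05),))
        seq, truth = simulate_monoploid(bp, _rng(3))
        cons = truth.consensus["f"]
        idents = [_seq.hamming_identity(seq[s:e], cons)
                  for s, e in truth.intervals["f"]]
        # mean per-base identity ~ 0.95 within 3 SD of the binomial mean
        sd = np.sqrt(0.05 * 0.95 / (500 * 50))
        assert abs(np.mean(idents) - 0.95) < 3 * sd

    def test_intervals_cover_planted_bases_exactly(self):
        bp = MonoploidBlueprint(
            background_length=20_000,
            families=(RepeatFamilySpec("t", "satellite", 200, 30, 0.01,
                                       tandem=True),
                      RepeatFamilySpec("d", "LTR-Copia", 400, 10, 0.02)))
        seq, truth = simulate_monoploid(bp, _rng(5))
        for fam, n_bases in truth.planted_bases.items():
            assert sum(e - s for s, e in truth.intervals[fam]) == n_bases
        assert len(seq) == 20_000 + sum(truth.planted_bases.values())

    def test_overfull_blueprint_raises(self):
        bp = MonoploidBlueprint(
            background_length=1_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 20, 900, 0.0),),
            site_spacing=50)
        with pytest.raises(SizingError):
            simulate_monoploid(bp, _rng())

    def test_site_spacing_is_respected(self):
        bp = MonoploidBlueprint(
            background_length=50_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 100, 50, 0.0),),
            site_spacing=300)
        _, truth = simulate_monoploid(bp, _rng(9))
        iv = sorted(truth.intervals["f"])
        gaps = [s2 - e1 for (_, e1), (s2, _) in zip(iv, iv[1:])]
        assert min(gaps) >= 300


class TestPolyploid:
    def test_identical_subgenomes_keep_proportions(self):
        bp = MonoploidBlueprint(
            background_length=9_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 500, 2, 0.0),))
        m = simulate_monoploid(bp, _rng(1))
        genome, truth = make_polyploid([m, m], nx=2)
        assert truth.holoploid_length == 2 * m[1].length
        assert truth.proportions["f"] == pytest.approx(1000 / 10_000)

    def test_union_dilutes_private_families(self):
        bpx = MonoploidBlueprint(
            background_length=9_000,
            families=(RepeatFamilySpec("x", "LTR-Gypsy", 500, 2, 0.0),))
        bpy = MonoploidBlueprint(
            background_length=9_000,
            families=(RepeatFamilySpec("y", "LTR-Copia", 500, 2, 0.0),))
        mx = simulate_monoploid(bpx, _rng(1))
        my = simulate_monoploid(bpy, _rng(2))
        _, truth = make_polyploid([mx, my], nx=2)
        assert truth.proportions["x"] == pytest.approx(0.05)
        assert truth.proportions["y"] == pytest.approx(0.05)
        # half of each monoploid's own 10%
        assert truth.proportions["x"] == pytest.approx(
            mx[1].planted_bases["x"] / mx[1].length / 2)

    def test_ribotype_count_counts_distinct_igs(self):
        igs = [_seq.decode(_seq.random_seq(_rng(i), 200)) for i in range(2)]
        bps = [MonoploidBlueprint(
            background_length=5_000,
            five_s=FiveSUnitSpec(igs_variants=(igs[i],), array_copies=5))
            for i in range(2)]
        monos = [simulate_monoploid(bp, _rng(10 + i)) for i, bp in enumerate(bps)]
        _, truth = make_polyploid(monos, nx=2)
        assert truth.ribotype_count == 2

    def test_empty_subgenome_list_raises(self):
        with pytest.raises(ValueError):
            make_polyploid([], nx=0)


class TestSkimReads:
    def test_pair_count_formula(self):
        genome = _seq.random_seq(_rng(), 1_000_000)
        reads = skim_reads(genome, coverage=0.1, sample_code="SKIM",
                           rng=_rng(1))
        assert reads.n_reads == 2 * int(np.floor(0.1 * 1_000_000 / 202))

    @pytest.mark.parametrize("coverage", [0.0, -0.1, 0.6])
    def test_bad_coverage_raises(self, coverage):
        genome = _seq.random_seq(_rng(), 10_000)
        with pytest.raises(ValueError):
            skim_reads(genome, coverage=coverage, sample_code="SKIM",
                       rng=_rng())

    def test_genome_shorter_than_insert_raises(self):
        with pytest.raises(ValueError):
            skim_reads(_seq.random_seq(_rng(), 300), coverage=0.1,
                       sample_code="SKIM", rng=_rng())

    def test_error_free_reads_are_genome_substrings(self):
        genome = _seq.random_seq(_rng(4), 50_000)
        reads = skim_reads(genome, coverage=0.1, sample_code="SKIM",
                           rng=_rng(5), error_rate=0.0)
        gstr = _seq.decode(genome)
        grc = _seq.decode(_seq.revcomp(genome))
        for i in range(reads.n_reads):
            s = _seq.decode(reads.seqs[i])
            assert s in gstr or s in grc

    def test_headers_carry_sample_code_and_mates(self):
        genome = _seq.random_seq(_rng(), 20_000)
        reads = skim_reads(genome, coverage=0.1, sample_code="AB12",
                           rng=_rng())
        assert reads.read_id(0) == "AB12000000/1"
        assert reads.read_id(1) == "AB12000000/2"
        assert all(rid.startswith("AB12") for rid in reads.ids)

    def test_determinism_is_byte_identical(self):
        bp = MonoploidBlueprint(
            background_length=20_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 500, 5, 0.02),))
        spec = GenomeSpec(sample_code="DTRM", subgenomes=(bp, bp), seed=99)
        out = []
        for _ in range(2):
            genome, truth = build_genome(spec)
            reads = skim_reads(genome, coverage=0.2, sample_code="DTRM",
                               rng=_rng(99), truth=truth)
            out.append(reads.seqs.tobytes())
        assert out[0] == out[1]

    def test_read_sampling_tracks_planted_proportion(self):
        bp = MonoploidBlueprint(
            background_length=800_000,
            families=(RepeatFamilySpec("f", "LTR-Gypsy", 1000, 200, 0.0),),
            site_spacing=300)
        spec = GenomeSpec(sample_code="SMPL", subgenomes=(bp,), seed=11)
        genome, truth = build_genome(spec)
        reads = skim_reads(genome, coverage=0.5, sample_code="SMPL",
                           rng=_rng(11), truth=truth)
        n_pairs = reads.n_reads // 2
        assert n_pairs >= 2000
        frac = float(np.mean(reads.provenance == 0))
        p = truth.proportions["f"]
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n_pairs)


@given(st.integers(0, 2**31 - 1), st.integers(20, 400))
def test_revcomp_is_an_involution(seed, n):
    seq = _seq.random_seq(np.random.default_rng(seed), n)
    assert np.array_equal(_seq.revcomp(_seq.revcomp(seq)), seq)


@given(st.floats(0.0, 0.25), st.integers(0, 2**31 - 1))
def test_mutate_rate_zero_or_bounded(rate, seed):
    rng = np.random.default_rng(seed)
    seq = _seq.random_seq(rng, 300)
    mut = _seq.mutate(seq, rate, rng)
    diff = np.mean(mut != seq)
    assert diff <= max(3 * np.sqrt(rate / 300) + rate, 0.0) + 1e-12
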