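"""Synthetic genome-skimming data with planted repeat truth.

This module emulates the inputs of a low-coverage ("genome skimming")
repeatome survey: multi-sample, multi-ploidy genomes carrying dispersed
retrotransposon/transposon families with tunable copy number and
divergence, tandem satellite arrays, and 5S rDNA arrays built from a
conserved gene plus ribotype-specific intergenic spacers (IGS).  Every
planted base is tracked, so downstream estimates can be scored against
exact ground truth.

All randomness flows from explicit :class:`numpy.random.Generator`
instances; identical specs and seeds give byte-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _seq

LINEAGES = ("LTR-Gypsy", "LTR-Copia", "DNA-transposon", "satellite", "rDNA-5S", "other")

FIVE_S_FAMILY = "5S_rDNA"


class SizingError(ValueError):
    """Raised when a blueprint's repeats cannot fit its background."""


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One planted repeat family of a monoploid blueprint.

    divergence is the expected per-base substitution fraction of each copy
    relative to the family consensus.  Dispersed families are scattered at
    random non-overlapping positions; tandem families form one head-to-tail
    array.
    """

    name: str
    lineage: str
    monomer_length: int
    copies_per_monoploid: int
    divergence: float = 0.0
    tandem: bool = False
    consensus: str | None = None  # drawn at random when omitted

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.monomer_length < 20:
            raise ValueError("monomer_length must be >= 20")
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError("divergence must lie in [0, 0.25]")
        if self.copies_per_monoploid < 0:
            raise ValueError("copies_per_monoploid must be >= 0")
        if self.consensus is not None and len(self.consensus) != self.monomer_length:
            raise ValueError("consensus length must equal monomer_length")


@dataclass(frozen=True)
class FiveSUnitSpec:
    """A 5S rDNA locus: conserved gene + one IGS variant per ribotype.

    Each ribotype is planted as its own tandem array of (gene + IGS) units,
    emulating distinct 5S loci/subgenome ribotypes.
    """

    gene_length: int = 120
    igs_variants: tuple[str, ...] = ()
    array_copies: int = 30
    divergence: float = 0.005
    gene_seq: str | None = None

    def __post_init__(self):
        if self.gene_length < 60:
            raise ValueError("gene_length must be >= 60")
        if not 1 <= len(self.igs_variants) <= 4:
            raise ValueError("need 1-4 IGS variants")
        if self.array_copies < 1:
            raise ValueError("array_copies must be >= 1")
        if self.gene_seq is not None and len(self.gene_seq) != self.gene_length:
            raise ValueError("gene_seq length must equal gene_length")


@dataclass(frozen=True)
class MonoploidBlueprint:
    """One monoploid complement: background plus planted repeats.

    ``site_spacing`` enforces a minimum background gap (bp) between
    insertion sites; 0 means fully uniform placement.  A few hundred bp of
    spacing keeps separately planted families from being fused by chains
    of physically overlapping reads, which is the controlled condition the
    recovery experiments need (real genomes do nest their repeats).
    """

    background_length: int
    families: tuple[RepeatFamilySpec, ...] = ()
    five_s: FiveSUnitSpec | None = None
    site_spacing: int = 0

    def __post_init__(self):
        if self.background_length < 1000:
            raise ValueError("background_length must be >= 1000")
        if self.site_spacing < 0:
            raise ValueError("site_spacing must be >= 0")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("family names must be unique")


@dataclass(frozen=True)
class GenomeSpec:
    """One sample: nx monoploid complements plus a 4-character code."""

    sample_code: str
    subgenomes: tuple[MonoploidBlueprint, ...]
    seed: int

    def __post_init__(self):
        if len(self.sample_code) != 4:
            raise ValueError("sample_code must be exactly 4 characters")
        if not self.subgenomes:
            raise ValueError("need at least one subgenome")

    @property
    def nx(self) -> int:
        return len(self.subgenomes)


@dataclass
class MonoploidTruth:
    """Planted truth for one monoploid complement."""

    length: int
    family_names: list[str]
    lineages: dict[str, str]
    intervals: dict[str, list[tuple[int, int]]]
    planted_bases: dict[str, int]
    consensus: dict[str, np.ndarray]
    igs_variants: list[str] = field(default_factory=list)
    gene_seq: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth of one holoploid genome (for scoring estimates)."""

    holoploid_length: int
    family_names: list[str]
    lineages: dict[str, str]
    intervals: dict[str, list[tuple[int, int]]]
    planted_bases: dict[str, int]
    consensus: dict[str, np.ndarray]
    igs_variants: list[str]
    gene_seq: str | None

    @property
    def proportions(self) -> dict[str, float]:
        return {f: b / self.holoploid_length for f, b in self.planted_bases.items()}

    @property
    def ribotype_count(self) -> int:
        return len(set(self.igs_variants))

    def family_map(self) -> np.ndarray:
        """Per-base family index over the holoploid genome (-1 = background)."""
        fam = np.full(self.holoploid_length, -1, dtype=np.int16)
        for i, name in enumerate(self.family_names):
            for s, e in self.intervals[name]:
                fam[s:e] = i
        return fam


def _draw_copies(consensus: np.ndarray, n: int, divergence: float,
                 rng: np.random.Generator) -> list[np.ndarray]:
    if n == 0:
        return []
    tiled = np.tile(consensus, (n, 1))
    mutated = _seq.mutate(tiled, divergence, rng)
    return [mutated[i] for i in range(n)]


def simulate_monoploid(blueprint: MonoploidBlueprint,
                       rng: np.random.Generator) -> tuple[np.ndarray, MonoploidTruth]:
    """Build one monoploid sequence and its planted truth.

    Dispersed copies land at uniformly random, non-overlapping background
    positions; tandem families and each 5S ribotype form contiguous
    head-to-tail arrays at a single random position.
    """
    background = _seq.random_seq(rng, blueprint.background_length)

    segments: list[list[np.ndarray]] = []  # one list of copies per insertion site
    seg_family: list[str] = []
    family_names: list[str] = []
    lineages: dict[str, str] = {}
    consensus: dict[str, np.ndarray] = {}
    igs_variants: list[str] = []
    gene_seq_str: str | None = None

    for fam in blueprint.families:
        cons = (_seq.encode(fam.consensus) if fam.consensus is not None
                else _seq.random_seq(rng, fam.monomer_length))
        family_names.append(fam.name)
        lineages[fam.name] = fam.lineage
        consensus[fam.name] = cons
        copies = _draw_copies(cons, fam.copies_per_monoploid, fam.divergence, rng)
        if not copies:
            continue
        if fam.tandem:
            segments.append(copies)
            seg_family.append(fam.name)
        else:
            for c in copies:
                segments.append([c])
                seg_family.append(fam.name)

    if blueprint.five_s is not None:
        fs = blueprint.five_s
        gene = (_seq.encode(fs.gene_seq) if fs.gene_seq is not None
                else _seq.random_seq(rng, fs.gene_length))
        gene_seq_str = _seq.decode(gene)
        family_names.append(FIVE_S_FAMILY)
        lineages[FIVE_S_FAMILY] = "rDNA-5S"
        for igs_str in fs.igs_variants:
            igs = _seq.encode(igs_str)
            unit = np.concatenate([gene, igs])
            consensus.setdefault(FIVE_S_FAMILY, unit)
            copies = _draw_copies(unit, fs.array_copies, fs.divergence, rng)
            segments.append(copies)
            seg_family.append(FIVE_S_FAMILY)
            igs_variants.append(igs_str)

    n_sites = len(segments)
    if n_sites:
        span = blueprint.background_length - (n_sites - 1) * blueprint.site_spacing
        if span < n_sites:
            raise SizingError("repeat insertions exceed background capacity")
        # distinct insertion points with the required minimum gap,
        # shuffled so which segment lands where is random
        raw = np.sort(rng.choice(span + 1, size=n_sites, replace=False))
        sites = raw + blueprint.site_spacing * np.arange(n_sites)
    else:
        sites = np.empty(0, dtype=int)
    order = rng.permutation(n_sites)

    pieces: list[np.ndarray] = []
    intervals: dict[str, list[tuple[int, int]]] = {f: [] for f in family_names}
    pos = 0  # position in output
    prev = 0  # position in background
    for site, seg_idx in zip(sites, order):
        site = int(site)
        pieces.append(background[prev:site])
        pos += site - prev
        prev = site
        for copy in segments[seg_idx]:
            pieces.append(copy)
            intervals[seg_family[seg_idx]].append((pos, pos + len(copy)))
            pos += len(copy)
    pieces.append(background[prev:])
    seq = np.concatenate(pieces) if pieces else background

    planted = {f: sum(e - s for s, e in intervals[f]) for f in family_names}
    truth = MonoploidTruth(length=len(seq), family_names=family_names,
                           lineages=lineages, intervals=intervals,
                           planted_bases=planted, consensus=consensus,
                           igs_variants=igs_variants, gene_seq=gene_seq_str)
    return seq, truth


def make_polyploid(monoploids: list[tuple[np.ndarray, MonoploidTruth]],
                   nx: int) -> tuple[np.ndarray, SyntheticTruth]:
    """Concatenate nx monoploid complements into one holoploid genome.

    Truth proportions are recomputed over the holoploid length; interval
    coordinates are shifted to holoploid coordinates.
    """
    if not monoploids:
        raise ValueError("empty subgenome list")
    if len(monoploids) != nx:
        raise ValueError(f"expected {nx} subgenome sequences, got {len(monoploids)}")

    family_names: list[str] = []
    lineages: dict[str, str] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    planted: dict[str, int] = {}
    consensus: dict[str, np.ndarray] = {}
    igs_variants: list[str] = []
    gene_seq = None

    seqs = []
    offset = 0
    for seq, mt in monoploids:
        seqs.append(seq)
        for f in mt.family_names:
            if f not in family_names:
                family_names.append(f)
                lineages[f] = mt.lineages[f]
                intervals[f] = []
                planted[f] = 0
                consensus[f] = mt.consensus[f]
            intervals[f].extend((s + offset, e + offset) for s, e in mt.intervals[f])
            planted[f] += mt.planted_bases[f]
        igs_variants.extend(mt.igs_variants)
        if mt.gene_seq is not None:
            gene_seq = mt.gene_seq
        offset += mt.length

    genome = np.concatenate(seqs)
    truth = SyntheticTruth(holoploid_length=len(genome), family_names=family_names,
                           lineages=lineages, intervals=intervals,
                           planted_bases=planted, consensus=consensus,
                           igs_variants=igs_variants, gene_seq=gene_seq)
    return genome, truth


def build_genome(spec: GenomeSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate every subgenome of ``spec`` and fuse them into a holoploid."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(spec.subgenomes))
    monos = [simulate_monoploid(bp, np.random.default_rng(child))
             for bp, child in zip(spec.subgenomes, children)]
    return make_polyploid(monos, spec.nx)


@dataclass
class ReadSet:
    """A paired, sample-tagged short-read collection.

    Reads are stored as one uint8 matrix (all reads share one length).
    Mates are interleaved: rows 2i and 2i+1 are pair i.  ``provenance``
    holds the majority planted-family index per read (-1 = background /
    unknown), available for simulated data only.
    """

    seqs: np.ndarray  # (n_reads, read_length) uint8
    sample_idx: np.ndarray  # (n_reads,) int32 into sample_codes
    sample_codes: list[str]
    pair_idx: np.ndarray  # (n_reads,) int64 pair number within sample
    mate: np.ndarray  # (n_reads,) uint8, 1 or 2
    provenance: np.ndarray | None = None  # (n_reads,) int16
    family_names: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def read_id(self, i: int) -> str:
        code = self.sample_codes[self.sample_idx[i]]
        return f"{code}{int(self.pair_idx[i]):06d}/{int(self.mate[i])}"

    @property
    def ids(self) -> list[str]:
        return [self.read_id(i) for i in range(self.n_reads)]

    def sample_of(self, i: int) -> str:
        return self.sample_codes[self.sample_idx[i]]

    def analysed_counts(self) -> dict[str, int]:
        counts = np.bincount(self.sample_idx, minlength=len(self.sample_codes))
        return {code: int(c) for code, c in zip(self.sample_codes, counts)}

    def subset(self, indices) -> "ReadSet":
        idx = np.asarray(indices)
        prov = None if self.provenance is None else self.provenance[idx]
        return ReadSet(self.seqs[idx], self.sample_idx[idx], list(self.sample_codes),
                       self.pair_idx[idx], self.mate[idx], prov,
                       list(self.family_names))

    @staticmethod
    def concat(readsets: list["ReadSet"]) -> "ReadSet":
        if not readsets:
            raise ValueError("nothing to concatenate")
        codes: list[str] = []
        fams: list[str] = []
        for rs in readsets:
            for c in rs.sample_codes:
                if c in codes:
                    raise ValueError(f"duplicate sample code {c!r}")
            codes.extend(rs.sample_codes)
            for f in rs.family_names:
                if f not in fams:
                    fams.append(f)
        seqs = np.concatenate([rs.seqs for rs in readsets])
        offsets = np.cumsum([0] + [len(rs.sample_codes) for rs in readsets[:-1]])
        sidx = np.concatenate([rs.sample_idx + off
                               for rs, off in zip(readsets, offsets)]).astype(np.int32)
        pidx = np.concatenate([rs.pair_idx for rs in readsets])
        mate = np.concatenate([rs.mate for rs in readsets])
        if all(rs.provenance is not None for rs in readsets):
            prov = np.concatenate([
                _remap_provenance(rs, fams) for rs in readsets])
        else:
            prov = None
        return ReadSet(seqs, sidx, codes, pidx, mate, prov, fams)


def _remap_provenance(rs: ReadSet, fams: list[str]) -> np.ndarray:
    lut = np.full(len(rs.family_names) + 1, -1, dtype=np.int16)
    for i, f in enumerate(rs.family_names):
        lut[i] = fams.index(f)
    return lut[rs.provenance]


def skim_reads(genome: np.ndarray, coverage: float, sample_code: str,
               rng: np.random.Generator, read_length: int = 101,
               insert_range: tuple[int, int] = (123, 329),
               error_rate: float = 0.005,
               truth: SyntheticTruth | None = None) -> ReadSet:
    """Draw paired-end skim reads from a genome.

    The number of pairs is floor(coverage * genome_length / (2 * read_length));
    fragments are uniform over the genome, the second mate is
    reverse-complemented, and sequencing errors are independent per-base
    substitutions at ``error_rate``.
    """
    G = len(genome)
    if not 0 < coverage <= 0.5:
        raise ValueError("coverage must lie in (0, 0.5]")
    lo, hi = insert_range
    if lo < read_length:
        raise ValueError("minimum insert must be >= read_length")
    if lo > hi:
        raise ValueError("bad insert range")
    if G < hi:
        raise ValueError("genome shorter than maximum insert")
    if len(sample_code) != 4:
        raise ValueError("sample_code must be exactly 4 characters")

    n_pairs = int(math.floor(coverage * G / (2 * read_length)))
    inserts = rng.integers(lo, hi + 1, size=n_pairs)
    starts = np.floor(rng.random(n_pairs) * (G - inserts + 1)).astype(np.int64)

    win = np.arange(read_length)
    m1 = genome[starts[:, None] + win]
    m2_fwd_start = starts + inserts - read_length
    m2 = _seq.revcomp_rows(genome[m2_fwd_start[:, None] + win])

    seqs = np.empty((2 * n_pairs, read_length), dtype=np.uint8)
    seqs[0::2] = m1
    seqs[1::2] = m2
    seqs = _seq.mutate(seqs, error_rate, rng)

    prov = None
    fam_names: list[str] = []
    if truth is not None:
        fam_names = list(truth.family_names)
        fammap = truth.family_map()
        read_starts = np.empty(2 * n_pairs, dtype=np.int64)
        read_starts[0::2] = starts
        read_starts[1::2] = m2_fwd_start
        windows = fammap[read_starts[:, None] + win]
        n_fam = len(fam_names)
        counts = np.stack([(windows == f).sum(axis=1) for f in range(n_fam)],
                          axis=1) if n_fam else np.zeros((2 * n_pairs, 0), int)
        prov = np.full(2 * n_pairs, -1, dtype=np.int16)
        if n_fam:
            best = np.argmax(counts, axis=1)
            majority = counts[np.arange(2 * n_pairs), best] >= (read_length + 1) // 2
            prov[majority] = best[majority].astype(np.int16)

    pair_idx = np.repeat(np.arange(n_pairs, dtype=np.int64), 2)
    mate = np.tile(np.array([1, 2], dtype=np.uint8), n_pairs)
    sample_idx = np.zeros(2 * n_pairs, dtype=np.int32)
    return ReadSet(seqs, sample_idx, [sample_code], pair_idx, mate, prov, fam_names)
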