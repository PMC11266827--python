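"""Cluster annotation and repeat abundance arithmetic.

Converts cluster read counts into the standard repeatome quantities:
per-sample genome proportions, absolute amounts in Mbp of the monoploid
(1Cx) genome, holoploid/monoploid genome sizes in Mbp, and fold ratios.

Genome-size conventions: 2C is the holoploid (unreplicated somatic) DNA
amount in pg; the monoploid 1Cx amount is 2C divided by the ploidy nx
(e.g. tetraploids carry four monoploid complements per 2C nucleus).  The
pg->Mbp constant is 978 Mbp/pg, with truncation at each conversion step.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_FLOOR, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd

from .graph import RepeatCluster, _kmer_entries
from .synth import ReadSet

UNCLASSIFIED = "Unclassified"
ALL_REPEATS = "All repeats"

PG_PER_MBP = 978


def monoploid_size(two_C_pg: float, nx: int) -> float:
    """1Cx in pg: 2C / nx, rounded half-up to 3 decimals."""
    if two_C_pg <= 0:
        raise ValueError("two_C_pg must be positive")
    if nx < 2:
        raise ValueError("nx must be >= 2")
    q = Decimal(str(two_C_pg)) / Decimal(nx)
    return float(q.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def pg_to_mbp(pg: float) -> int:
    """DNA amount pg -> integer Mbp at 978 Mbp/pg, truncated."""
    if pg <= 0:
        raise ValueError("pg must be positive")
    v = Decimal(str(pg)) * PG_PER_MBP
    return int(v.to_integral_value(rounding=ROUND_FLOOR))


def fold_ratio(a: float, b: float) -> float:
    """a/b rounded half-up to one decimal."""
    if b == 0:
        raise ZeroDivisionError("fold_ratio denominator is zero")
    q = Decimal(str(a)) / Decimal(str(b))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenomeSizeRecord:
    sample: str
    two_C_pg: float
    nx: int
    one_Cx_pg: float
    holoploid_mbp: int
    monoploid_mbp: int

    @classmethod
    def from_pg(cls, sample: str, two_C_pg: float, nx: int) -> "GenomeSizeRecord":
        holo = pg_to_mbp(two_C_pg)
        return cls(sample=sample, two_C_pg=two_C_pg, nx=nx,
                   one_Cx_pg=monoploid_size(two_C_pg, nx),
                   holoploid_mbp=holo, monoploid_mbp=holo // nx)


def load_sample_table() -> pd.DataFrame:
    """Bundled Brachypodium sample table (species, code, 2n, 2C pg, nx, 1Cx pg)."""
    with resources.files("repskim.data").joinpath(
            "brachypodium_samples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# annotation


@dataclass(frozen=True)
class RepeatAnnotation:
    cluster_id: int
    lineage: str
    vote_fraction: float


class RepeatLibrary:
    """Labelled repeat reference library used for cluster annotation."""

    def __init__(self, entries: dict[str, list[np.ndarray]], k: int = 13):
        if not entries:
            raise ValueError("empty repeat library")
        self.lineages = sorted(entries)
        self.k = k
        self._kmer_to_lineage: dict[int, int] = {}
        for li, lineage in enumerate(self.lineages):
            for seq in entries[lineage]:
                codes, _, _, _ = _kmer_entries(np.asarray(seq)[None, :], k)
                for c in codes.tolist():
                    # first lineage wins shared k-mers (deterministic order)
                    self._kmer_to_lineage.setdefault(c, li)

    def vote_reads(self, mat: np.ndarray) -> np.ndarray:
        """Per-read winning lineage index (-1 when no library k-mer matches)."""
        code, read, _, _ = _kmer_entries(mat, self.k)
        n = mat.shape[0]
        counts = np.zeros((n, len(self.lineages)), dtype=np.int64)
        lut = self._kmer_to_lineage
        for c, r in zip(code.tolist(), read.tolist()):
            li = lut.get(c)
            if li is not None:
                counts[r, li] += 1
        best = np.argmax(counts, axis=1)
        votes = np.where(counts[np.arange(n), best] > 0, best, -1)
        return votes.astype(np.int64)


def annotate_cluster(cluster: RepeatCluster, reads: ReadSet,
                     library: RepeatLibrary,
                     min_vote: float = 0.5) -> RepeatAnnotation:
    """Plurality k-mer vote of a cluster's reads against the library."""
    votes = library.vote_reads(reads.seqs[cluster.members])
    voting = votes[votes >= 0]
    if len(voting) == 0:
        return RepeatAnnotation(cluster.cluster_id, UNCLASSIFIED, 0.0)
    counts = np.bincount(voting, minlength=len(library.lineages))
    winner = int(np.argmax(counts))
    vote_fraction = counts[winner] / len(voting)
    lineage = library.lineages[winner] if vote_fraction >= min_vote else UNCLASSIFIED
    return RepeatAnnotation(cluster.cluster_id, lineage, float(vote_fraction))


def annotate_clusters(clusters: list[RepeatCluster], reads: ReadSet,
                      library: RepeatLibrary,
                      min_vote: float = 0.5) -> list[RepeatAnnotation]:
    return [annotate_cluster(c, reads, library, min_vote) for c in clusters]


# ---------------------------------------------------------------------------
# abundance table


def quantify(clusters: list[RepeatCluster],
             annotations: list[RepeatAnnotation],
             analysed_counts: dict[str, int],
             size_records: dict[str, GenomeSizeRecord]) -> pd.DataFrame:
    """Per sample x lineage genome proportions and Mbp/1Cx amounts.

    proportion(sample, lineage) = reads of that sample in clusters of that
    lineage / analysed reads of that sample; amount = proportion *
    monoploid_mbp.  An 'All repeats' row per sample sums the lineages.
    """
    ann_by_id = {a.cluster_id: a for a in annotations}
    tallies: dict[tuple[str, str], int] = {}
    for c in clusters:
        lineage = ann_by_id[c.cluster_id].lineage
        for sample, n in c.sample_counts.items():
            if sample not in analysed_counts:
                raise KeyError(f"unknown sample code {sample!r}")
            tallies[(sample, lineage)] = tallies.get((sample, lineage), 0) + n

    rows = []
    lineages = sorted({lin for (_, lin) in tallies})
    for sample in sorted(analysed_counts):
        total = analysed_counts[sample]
        mono_mbp = size_records[sample].monoploid_mbp if sample in size_records else None
        s_sum = 0.0
        for lineage in lineages:
            prop = tallies.get((sample, lineage), 0) / total
            s_sum += prop
            rows.append({"sample": sample, "lineage": lineage,
                         "proportion": prop,
                         "mbp": prop * mono_mbp if mono_mbp is not None else np.nan})
        rows.append({"sample": sample, "lineage": ALL_REPEATS,
                     "proportion": s_sum,
                     "mbp": s_sum * mono_mbp if mono_mbp is not None else np.nan})
    return pd.DataFrame(rows, columns=["sample", "lineage", "proportion", "mbp"])
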