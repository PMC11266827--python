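"""Hs/Ho landscape: intraspecific vs interspecific similarity-hit ratios.

For every read of an annotated repeat cluster, Hs counts its similarity
edges to reads of the same sample and Ho counts edges to reads of other
samples.  Conserved repeat families give Hs ~ Ho (log ratio near 0);
families diverged between samples lose cross-sample edges and shift the
log ratio to positive values.  Ho is normalized by analysed-read totals,
(n_same - 1) / n_other, so unequal coverage between samples does not bias
the ratio; reads with zero same-sample or zero cross-sample hits are
excluded from the histograms and reported separately (a family private to
one sample shows up entirely in the excluded count).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import HitTable, RepeatCluster
from .quantify import RepeatAnnotation

LOG_BIN_EDGES = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.1), 10)


class SingleSampleError(ValueError):
    """Hs/Ho is undefined for single-sample datasets."""


def hs_ho(hits: HitTable, sample_idx: np.ndarray, sample_codes: list[str],
          clusters: list[RepeatCluster], annotations: list[RepeatAnnotation],
          analysed_counts: dict[str, int]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read Hs/Ho records for reads of annotated clusters.

    Returns (records, exclusions): records has one row per read with both
    Hs > 0 and Ho_raw > 0 (columns read, sample, lineage, hs, ho_raw,
    ho_norm, log_ratio); exclusions counts the zero-hit reads per lineage.
    """
    if len({sample_codes[i] for i in np.unique(sample_idx)}) < 2:
        raise SingleSampleError("need >= 2 samples for Hs/Ho ratios")

    n = hits.n_reads
    same = sample_idx[hits.a] == sample_idx[hits.b]
    hs_counts = np.zeros(n, dtype=np.int64)
    ho_counts = np.zeros(n, dtype=np.int64)
    np.add.at(hs_counts, hits.a[same], 1)
    np.add.at(hs_counts, hits.b[same], 1)
    np.add.at(ho_counts, hits.a[~same], 1)
    np.add.at(ho_counts, hits.b[~same], 1)

    total_analysed = sum(analysed_counts.values())
    rows = []
    excl = []
    ann_by_id = {a.cluster_id: a for a in annotations}
    for cluster in clusters:
        ann = ann_by_id.get(cluster.cluster_id)
        if ann is None:
            continue
        lineage = ann.lineage
        n_excluded = 0
        for r in cluster.members.tolist():
            code = sample_codes[sample_idx[r]]
            n_same = analysed_counts[code]
            n_other = total_analysed - n_same
            hs = int(hs_counts[r])
            ho_raw = int(ho_counts[r])
            if hs == 0 or ho_raw == 0:
                n_excluded += 1
                continue
            ho_norm = ho_raw * (n_same - 1) / n_other
            rows.append({"read": r, "sample": code, "lineage": lineage,
                         "hs": hs, "ho_raw": ho_raw, "ho_norm": ho_norm,
                         "log_ratio": float(np.log10(hs / ho_norm))})
        excl.append({"cluster_id": cluster.cluster_id, "lineage": lineage,
                     "excluded": n_excluded, "cluster_size": cluster.size})
    records = pd.DataFrame(rows, columns=["read", "sample", "lineage", "hs",
                                          "ho_raw", "ho_norm", "log_ratio"])
    exclusions = pd.DataFrame(excl, columns=["cluster_id", "lineage",
                                             "excluded", "cluster_size"])
    return records, exclusions


@dataclass
class LandscapeHistogram:
    lineage: str
    edges: np.ndarray
    counts: np.ndarray
    n_records: int

    @property
    def mode_center(self) -> float | None:
        if self.counts.sum() == 0:
            return None
        i = int(np.argmax(self.counts))
        return float((self.edges[i] + self.edges[i + 1]) / 2)

    @property
    def empty(self) -> bool:
        return self.n_records == 0

    def to_frame(self) -> pd.DataFrame:
        centers = (self.edges[:-1] + self.edges[1:]) / 2
        return pd.DataFrame({"lineage": self.lineage,
                             "bin_center": np.round(centers, 3),
                             "count": self.counts})


def landscape_histograms(records: pd.DataFrame) -> dict[str, LandscapeHistogram]:
    """Fixed-bin log10(Hs/Ho) histograms per lineage (width 0.1 on [-3, 3]).

    Values beyond the range are clipped into the edge bins so that counts
    always sum to the number of defined records.
    """
    out: dict[str, LandscapeHistogram] = {}
    for lineage, grp in records.groupby("lineage"):
        vals = np.clip(grp["log_ratio"].to_numpy(), LOG_BIN_EDGES[0] + 1e-9,
                       LOG_BIN_EDGES[-1] - 1e-9)
        counts, _ = np.histogram(vals, bins=LOG_BIN_EDGES)
        out[lineage] = LandscapeHistogram(lineage=lineage, edges=LOG_BIN_EDGES,
                                          counts=counts, n_records=len(grp))
    return out
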