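"""Repeat abundance vs genome size statistics.

Pearson correlation of per-lineage repeat amounts with monoploid genome
size, the average contribution of each repeat to pairwise genome-size
differences, and Kruskal-Wallis rank tests across sample groups.

The pairwise-contribution statistic: over all unordered sample pairs with
GS_i > GS_j, a lineage contributes (A_i - A_j) / (GS_i - GS_j) * 100
percent of that pair's genome-size difference; per-pair negative shares
are floored at zero by default (a repeat cannot "explain" a difference it
opposes) and the mean over pairs is reported.  The signed variant is kept
behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    lineage: str
    r: float
    R2: float
    p: float
    n: int


@dataclass(frozen=True)
class ContributionResult:
    lineage: str
    min_mbp: float
    max_mbp: float
    mean_contribution_pct: float


@dataclass(frozen=True)
class RankTestResult:
    lineage: str
    H: float
    p: float
    groups: tuple[str, ...]


def pearson_r2(abundance, one_cx, lineage: str = "") -> CorrelationResult:
    """Pearson r of lineage abundance vs 1Cx; R2 = r^2, p two-sided (t, n-2 df)."""
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(one_cx, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(lineage=lineage, r=r, R2=r * r,
                             p=float(res.pvalue), n=len(x))


def pairwise_contribution(amounts_mbp, genome_sizes_mbp, lineage: str = "",
                          floor_negative: bool = True) -> ContributionResult:
    """Average percent contribution of one repeat to pairwise GS differences."""
    a = np.asarray(amounts_mbp, dtype=float)
    gs = np.asarray(genome_sizes_mbp, dtype=float)
    if len(a) != len(gs) or len(a) < 2:
        raise ValueError("need >= 2 samples")
    iu, ju = np.triu_indices(len(a), 1)
    dg = gs[iu] - gs[ju]
    da = a[iu] - a[ju]
    # orient every pair so the genome-size difference is positive
    sign = np.sign(dg)
    usable = dg != 0
    if not usable.any():
        raise ValueError("all genome sizes equal")
    c = (da[usable] * sign[usable]) / np.abs(dg[usable]) * 100.0
    if floor_negative:
        c = np.maximum(c, 0.0)
    return ContributionResult(lineage=lineage, min_mbp=float(a.min()),
                              max_mbp=float(a.max()),
                              mean_contribution_pct=float(c.mean()))


def kruskal_wallis(values_by_group: dict[str, "np.ndarray | list"],
                   lineage: str = "") -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if sum(len(a) for a in arrays) < 2:
        raise ValueError("need >= 2 observations in total")
    if np.ptp(np.concatenate(arrays)) == 0:
        # identical observations everywhere: H = 0, p = 1 by convention
        return RankTestResult(lineage=lineage, H=0.0, p=1.0,
                              groups=tuple(groups))
    H, p = sps.kruskal(*arrays)
    return RankTestResult(lineage=lineage, H=float(H), p=float(p),
                          groups=tuple(groups))
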