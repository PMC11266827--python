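"""Planted-truth study designs.

Each function builds a synthetic genome-skimming experiment under fixed,
documented conditions, runs the relevant pipeline stages, and returns the
measurements next to the planted truth.  Tests and the acceptance script
both consume these, so the conditions live in exactly one place.

All sizes are desk-scale by design: large enough for the binomial error
bands and type-recovery rates they are scored against, small enough to run
on one CPU in minutes (see docs/methods.md for the sizing rationale).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .graph import (ReadGraph, brute_force_hits, cluster_reads,
                    cluster_streaming, filter_top_clusters,
                    find_similarity_hits)
from .landscape import hs_ho, landscape_histograms
from .network import (consensus_network, neighbor_joining,
                      observed_expected_matrix, to_distance)
from .quantify import RepeatLibrary, annotate_clusters, quantify
from .stats import kruskal_wallis
from .synth import (FiveSUnitSpec, GenomeSpec, MonoploidBlueprint,
                    RepeatFamilySpec, ReadSet, build_genome, skim_reads)
from .tandem import classify_5s_graph


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _consensus_str(rng: np.random.Generator, n: int) -> str:
    return _seq.decode(_seq.random_seq(rng, n))


# ---------------------------------------------------------------------------
# planted-proportion recovery (the flagship quantification experiment)

#: the five planted families: (name, lineage, monomer bp, proportion of the
#: monoploid, per-copy divergence, tandem?)
PROPORTION_FAMILIES = (
    ("Retand", "LTR-Gypsy", 3000, 0.25, 0.02, False),
    ("Tekay", "LTR-Gypsy", 3000, 0.15, 0.03, False),
    ("Angela", "LTR-Copia", 2500, 0.08, 0.02, False),
    ("SIRE", "LTR-Copia", 2000, 0.03, 0.01, False),
    ("satellite", "satellite", 170, 0.01, 0.01, True),
)


@dataclass
class ProportionRecovery:
    truth: dict[tuple[str, str], float]  # (sample, family) -> planted fraction
    estimate: dict[tuple[str, str], float]
    z: dict[tuple[str, str], float]
    n_pairs_per_sample: int
    n_reads_total: int
    n_clusters_kept: int

    @property
    def max_abs_z(self) -> float:
        return max(abs(v) for v in self.z.values())


def proportion_recovery_scenario(seed: int, monoploid_bp: int = 10_000_000,
                                 coverage: float = 0.1,
                                 n_samples: int = 3) -> ProportionRecovery:
    """Three diploid samples, five families spanning 1-25%, skimmed at 0.1x.

    Clusters reads of all samples jointly, annotates clusters against the
    planted consensus library, and scores per-sample per-family proportion
    estimates in binomial standard deviations (read pairs as the sampling
    unit, which upper-bounds the mate-correlation variance).
    """
    master, *sample_rngs = _spawn(seed, n_samples + 1)

    consensus = {name: _consensus_str(master, length)
                 for name, _, length, _, _, _ in PROPORTION_FAMILIES}
    fams = []
    planted_total = 0
    for name, lineage, length, prop, div, tandem in PROPORTION_FAMILIES:
        copies = int(round(prop * monoploid_bp / length))
        planted_total += copies * length
        fams.append(RepeatFamilySpec(name=name, lineage=lineage,
                                     monomer_length=length,
                                     copies_per_monoploid=copies,
                                     divergence=div, tandem=tandem,
                                     consensus=consensus[name]))
    background = monoploid_bp - planted_total
    blueprint = MonoploidBlueprint(background_length=background,
                                   families=tuple(fams), site_spacing=300)

    readsets, truths = [], []
    for i, rng in enumerate(sample_rngs):
        code = f"SA{i:02d}"
        spec = GenomeSpec(sample_code=code, subgenomes=(blueprint, blueprint),
                          seed=int(rng.integers(2**31)))
        genome, truth = build_genome(spec)
        reads = skim_reads(genome, coverage=coverage, sample_code=code,
                           rng=rng, truth=truth)
        readsets.append(reads)
        truths.append((code, truth))
        del genome

    reads = ReadSet.concat(readsets)
    clusters, _ = cluster_streaming(reads)
    clusters = filter_top_clusters(clusters, reads.n_reads)
    library = RepeatLibrary({name: [_seq.encode(consensus[name])]
                             for name, *_ in PROPORTION_FAMILIES})
    annotations = annotate_clusters(clusters, reads, library)
    counts = reads.analysed_counts()
    table = quantify(clusters, annotations, counts, {})

    n_pairs = counts[truths[0][0]] // 2
    truth_d, est_d, z_d = {}, {}, {}
    for code, truth in truths:
        props = truth.proportions
        for name, *_ in PROPORTION_FAMILIES:
            p = props[name]
            sel = (table["sample"] == code) & (table["lineage"] == name)
            est = float(table.loc[sel, "proportion"].sum())
            sd = np.sqrt(p * (1 - p) / n_pairs)
            truth_d[(code, name)] = p
            est_d[(code, name)] = est
            z_d[(code, name)] = (est - p) / sd
    return ProportionRecovery(truth=truth_d, estimate=est_d, z=z_d,
                              n_pairs_per_sample=n_pairs,
                              n_reads_total=reads.n_reads,
                              n_clusters_kept=len(clusters))


# ---------------------------------------------------------------------------
# seeded-vs-brute-force hit finder agreement


def hit_oracle_scenario(seed: int, n_pairs: int = 100):
    """~200 skim reads from a two-family genome; seeded finder vs oracle.

    Families are planted without per-copy divergence and reads carry no
    errors, so every qualifying overlap retains intact seed k-mers and the
    two hit finders must agree exactly.
    """
    rng = np.random.default_rng(seed)
    fams = tuple(
        RepeatFamilySpec(name=n, lineage="LTR-Gypsy", monomer_length=m,
                         copies_per_monoploid=c, divergence=0.0)
        for n, m, c in (("famA", 600, 8), ("famB", 500, 6)))
    bp = MonoploidBlueprint(background_length=37_000, families=fams)
    spec = GenomeSpec(sample_code="ORCL", subgenomes=(bp,),
                      seed=int(rng.integers(2**31)))
    genome, truth = build_genome(spec)
    coverage = n_pairs * 202 / len(genome)
    reads = skim_reads(genome, coverage=coverage, sample_code="ORCL",
                       rng=rng, error_rate=0.0, truth=truth)
    seeded = find_similarity_hits(reads)
    brute = brute_force_hits(reads)
    sp, bp_ = seeded.pair_set(), brute.pair_set()
    return {"n_reads": reads.n_reads, "n_hits_seeded": len(sp),
            "n_hits_brute": len(bp_),
            "n_mismatch": len(sp.symmetric_difference(bp_))}


# ---------------------------------------------------------------------------
# 5S ribotype graph typing


def fives_typing_trial(n_ribotypes: int, seed: int) -> dict:
    """One simulated 5S locus set with ``n_ribotypes`` IGS variants.

    Skims a small genome holding one tandem 5S array per ribotype, jointly
    clusters the reads, and types the largest (5S) cluster by IGS loop
    counting.  Returns the recovered graph type next to the truth.
    """
    rng = np.random.default_rng(seed)
    igs = tuple(_consensus_str(rng, 260) for _ in range(n_ribotypes))
    five_s = FiveSUnitSpec(gene_length=120, igs_variants=igs,
                           array_copies=100, divergence=0.005)
    bp = MonoploidBlueprint(background_length=40_000, five_s=five_s)
    spec = GenomeSpec(sample_code="R5S0", subgenomes=(bp,),
                      seed=int(rng.integers(2**31)))
    genome, truth = build_genome(spec)
    reads = skim_reads(genome, coverage=0.5, sample_code="R5S0", rng=rng,
                       error_rate=0.003, truth=truth)
    hits = find_similarity_hits(reads)
    graph = ReadGraph.from_readset(reads, hits)
    clusters, _ = cluster_reads(graph)
    if not clusters:
        return {"truth": n_ribotypes, "graph_type": 0, "loop_count": 0}
    top = clusters[0]
    typing = classify_5s_graph(reads.seqs[top.members],
                               _seq.encode(truth.gene_seq))
    return {"truth": n_ribotypes, "graph_type": typing.graph_type,
            "loop_count": typing.loop_count, "cluster_size": top.size,
            "n_reads": reads.n_reads}


def fives_typing_recovery(seed: int, n_trials: int = 20) -> dict[int, int]:
    """Correct graph-type calls per ribotype count over seeded trials."""
    rng = np.random.default_rng(seed)
    out = {}
    for r in (1, 2, 3):
        correct = 0
        for _ in range(n_trials):
            trial = fives_typing_trial(r, int(rng.integers(2**31)))
            if trial["graph_type"] == r:
                correct += 1
        out[r] = correct
    return out


# ---------------------------------------------------------------------------
# six-taxon network recovery

NETWORK_TAXA = ("TAXA", "TAXB", "TAXC", "TAXD", "TAXE", "TAXF")
#: the three cherries of the true species tree ((A,B),(C,D),(E,F))
TRUE_SPLITS = (frozenset({"TAXA", "TAXB"}), frozenset({"TAXC", "TAXD"}),
               frozenset({"TAXE", "TAXF"}))


def network_recovery_trial(seed: int, n_families: int = 10,
                           coverage: float = 0.15) -> dict:
    """End-to-end repeat phylogenetics on six samples from a known tree.

    Repeat consensus sequences accumulate substitutions along the species
    tree (cherry branches 0.01, central branches 0.03 subs/site); each
    sample is skimmed, clustered jointly, per-cluster observed/expected
    matrices are inverted into distances, NJ trees built, and the
    consensus network checked for the three true cherry splits.
    """
    master = np.random.default_rng(seed)
    monomer, copies = 1000, 12
    roots = [_seq.random_seq(master, monomer) for _ in range(n_families)]

    species_consensus: dict[str, list[np.ndarray]] = {t: [] for t in NETWORK_TAXA}
    for root in roots:
        for cherry in (("TAXA", "TAXB"), ("TAXC", "TAXD"), ("TAXE", "TAXF")):
            parent = _seq.mutate(root, 0.03, master)
            for taxon in cherry:
                species_consensus[taxon].append(_seq.mutate(parent, 0.01, master))

    readsets = []
    for taxon in NETWORK_TAXA:
        fams = tuple(
            RepeatFamilySpec(name=f"fam{i:02d}", lineage="LTR-Gypsy",
                             monomer_length=monomer, copies_per_monoploid=copies,
                             divergence=0.005,
                             consensus=_seq.decode(species_consensus[taxon][i]))
            for i in range(n_families))
        bp = MonoploidBlueprint(background_length=180_000, families=fams,
                                site_spacing=300)
        spec = GenomeSpec(sample_code=taxon, subgenomes=(bp, bp),
                          seed=int(master.integers(2**31)))
        genome, truth = build_genome(spec)
        readsets.append(skim_reads(genome, coverage=coverage, sample_code=taxon,
                                   rng=master, error_rate=0.003, truth=truth))

    reads = ReadSet.concat(readsets)
    hits = find_similarity_hits(reads)
    graph = ReadGraph.from_readset(reads, hits)
    clusters, _ = cluster_reads(graph)
    clusters = filter_top_clusters(clusters, reads.n_reads)

    trees, excluded = [], 0
    for cluster in clusters:
        try:
            mat = observed_expected_matrix(cluster, hits, reads.sample_idx,
                                           list(NETWORK_TAXA))
        except ValueError:
            excluded += 1
            continue
        dist = to_distance(mat)
        if dist is None:
            excluded += 1
            continue
        trees.append(neighbor_joining(dist))

    if not trees:
        return {"recovered": False, "n_trees": 0, "excluded": excluded,
                "supports": {}}
    net = consensus_network(trees, min_support=0.1)
    supports = {}
    for side in TRUE_SPLITS:
        split = net.find(side)
        supports[tuple(sorted(side))] = 0.0 if split is None else split.support
    recovered = all(s >= 0.5 for s in supports.values())
    return {"recovered": recovered, "n_trees": len(trees), "excluded": excluded,
            "supports": supports, "n_clusters": len(clusters),
            "n_reads": reads.n_reads}


def network_recovery_rate(seed: int, n_runs: int = 10) -> dict:
    rng = np.random.default_rng(seed)
    runs = [network_recovery_trial(int(rng.integers(2**31)))
            for _ in range(n_runs)]
    return {"n_success": sum(r["recovered"] for r in runs), "n_runs": n_runs,
            "runs": runs}


# ---------------------------------------------------------------------------
# Hs/Ho landscape


def _evenly_diverged(cons: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Substitute ``fraction`` of the bases at evenly interspersed positions.

    Even spacing guarantees every alignment window carries its share of the
    fixed differences, which is the idealized condition for a family
    uniformly diverged between samples (random placement leaves locally
    conserved windows that blur the Hs/Ho contrast).
    """
    L = len(cons)
    n_sub = int(round(L * fraction))
    pos = np.unique(np.round(np.linspace(0, L - 1, n_sub)).astype(int))
    out = cons.copy()
    out[pos] = (out[pos] + rng.integers(1, 4, size=len(pos))) % 4
    return out


def hsho_scenario(seed: int, between_divergence: float = 0.08) -> dict:
    """Two equal-coverage samples sharing a conserved and a diverged family.

    The conserved family uses one consensus in both samples; the diverged
    family's consensus differs by ``between_divergence`` between samples
    (fixed differences evenly interspersed along the monomer), with
    within-sample copy heterogeneity keeping same-sample read pairs under
    the 10% mismatch ceiling and pushing cross-sample pairs over it.
    """
    master = np.random.default_rng(seed)
    monomer, copies = 600, 80
    conserved = _consensus_str(master, monomer)
    div_a = _seq.random_seq(master, monomer)
    div_b = _evenly_diverged(div_a, between_divergence, master)

    readsets = []
    for code, div_cons in (("HSA0", div_a), ("HSB0", div_b)):
        fams = (
            RepeatFamilySpec(name="conserved", lineage="LTR-Gypsy",
                             monomer_length=monomer, copies_per_monoploid=copies,
                             divergence=0.005, consensus=conserved),
            RepeatFamilySpec(name="diverged", lineage="LTR-Copia",
                             monomer_length=monomer, copies_per_monoploid=copies,
                             divergence=0.03, consensus=_seq.decode(div_cons)),
        )
        bp = MonoploidBlueprint(background_length=130_000, families=fams,
                                site_spacing=300)
        spec = GenomeSpec(sample_code=code, subgenomes=(bp, bp),
                          seed=int(master.integers(2**31)))
        genome, truth = build_genome(spec)
        readsets.append(skim_reads(genome, coverage=0.45, sample_code=code,
                                   rng=master, error_rate=0.003, truth=truth))

    reads = ReadSet.concat(readsets)
    hits = find_similarity_hits(reads)
    graph = ReadGraph.from_readset(reads, hits)
    clusters, _ = cluster_reads(graph)
    clusters = filter_top_clusters(clusters, reads.n_reads)
    library = RepeatLibrary({"conserved": [_seq.encode(conserved)],
                             "diverged": [div_a]})
    annotations = annotate_clusters(clusters, reads, library)
    records, exclusions = hs_ho(hits, reads.sample_idx, reads.sample_codes,
                                clusters, annotations, reads.analysed_counts())
    hists = landscape_histograms(records)
    modes = {lin: h.mode_center for lin, h in hists.items()}
    return {"records": records, "exclusions": exclusions, "histograms": hists,
            "modes": modes, "n_reads": reads.n_reads}


# ---------------------------------------------------------------------------
# Kruskal-Wallis null calibration


def kw_type1_error(seed: int, n_replicates: int = 1000, group_size: int = 8,
                   n_groups: int = 3, alpha: float = 0.05) -> dict:
    """Rejection rate of the KW test on identically distributed groups."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = {f"g{i}": rng.normal(size=group_size) for i in range(n_groups)}
        if kruskal_wallis(groups).p < alpha:
            rejections += 1
    return {"rate": rejections / n_replicates, "n_replicates": n_replicates,
            "alpha": alpha}


# ---------------------------------------------------------------------------
# toy pipeline dataset (smoke-scale, all stages)


def toy_genome_specs(seed: int, n_samples: int = 3):
    """Three small diploid samples (~2,000 read pairs each at 0.5x) with
    dispersed families, a satellite, and a single-ribotype 5S locus."""
    master = np.random.default_rng(seed)
    cons = {
        "Retand": _consensus_str(master, 2000),
        "Tekay": _consensus_str(master, 2000),
        "SIRE": _consensus_str(master, 2000),
        "satellite": _consensus_str(master, 300),
    }
    igs = _consensus_str(master, 250)
    gene = _consensus_str(master, 120)
    specs = []
    for i in range(n_samples):
        fams = (
            RepeatFamilySpec("Retand", "LTR-Gypsy", 2000, 6, 0.02,
                             consensus=cons["Retand"]),
            RepeatFamilySpec("Tekay", "LTR-Gypsy", 2000, 6, 0.03,
                             consensus=cons["Tekay"]),
            RepeatFamilySpec("SIRE", "LTR-Copia", 2000, 6, 0.01,
                             consensus=cons["SIRE"]),
            RepeatFamilySpec("satellite", "satellite", 300, 27, 0.01,
                             tandem=True, consensus=cons["satellite"]),
        )
        five_s = FiveSUnitSpec(gene_length=120, igs_variants=(igs,),
                               array_copies=40, divergence=0.005, gene_seq=gene)
        bp = MonoploidBlueprint(background_length=350_000, families=fams,
                                five_s=five_s, site_spacing=300)
        specs.append(GenomeSpec(sample_code=f"TY{i:02d}", subgenomes=(bp, bp),
                                seed=int(master.integers(2**31))))
    library = RepeatLibrary({name: [_seq.encode(s)] for name, s in cons.items()}
                            | {"rDNA_5S": [_seq.encode(gene + igs)]})
    return specs, library, _seq.encode(gene)
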