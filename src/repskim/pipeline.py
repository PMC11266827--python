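"""End-to-end pipeline: simulate -> preprocess -> cluster -> quantify ->
tandem profiles -> Hs/Ho -> matrices -> NJ -> network -> stats.

Every stage logs machine-readable counts (reads in/out, clusters,
exclusions) into the result bundle and to ``<outdir>/pipeline_log.json``;
with a fixed seed the written artifacts are byte-identical across runs.
A stage failure aborts with the stage name, except the Hs/Ho stage on
single-sample inputs, whose defined error is recorded and skipped.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .graph import (ReadGraph, cluster_reads, cluster_streaming,
                    filter_organelle, filter_top_clusters,
                    find_similarity_hits)
from .landscape import SingleSampleError, hs_ho, landscape_histograms
from .network import (consensus_network, neighbor_joining,
                      observed_expected_matrix, to_distance,
                      write_splits_nexus)
from .quantify import (GenomeSizeRecord, RepeatLibrary, annotate_clusters,
                       quantify)
from .stats import pairwise_contribution, pearson_r2
from .synth import GenomeSpec, ReadSet, build_genome, skim_reads
from .tandem import profile_tandem_cluster


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig,
                 genome_specs: list[GenomeSpec],
                 library: RepeatLibrary,
                 gene_exemplar: np.ndarray | None = None,
                 size_records: dict[str, GenomeSizeRecord] | None = None,
                 organelle_ref: np.ndarray | None = None) -> dict:
    """Run every stage on simulated inputs; return the result bundle."""
    config.validate()
    outdir = io.ensure_dir(config.outdir)
    log: dict[str, dict] = {}
    bundle: dict = {"log": log}
    size_records = size_records or {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except SingleSampleError as err:
                log[name] = {"skipped": True, "error": str(err)}
                bundle.setdefault("errors", {})[name] = str(err)
                return None
            except Exception as err:  # noqa: BLE001 - abort with stage name
                raise StageError(name, err) from err
        return deco

    # --- simulate -----------------------------------------------------
    @stage("simulate")
    def reads() -> ReadSet:
        readsets = []
        ss = np.random.SeedSequence(config.seed)
        for spec, child in zip(genome_specs, ss.spawn(len(genome_specs))):
            genome, truth = build_genome(spec)
            rng = np.random.default_rng(child)
            readsets.append(skim_reads(
                genome, coverage=config.coverage, sample_code=spec.sample_code,
                rng=rng, read_length=config.read_length,
                insert_range=(config.insert_min, config.insert_max),
                error_rate=config.error_rate, truth=truth))
        rs = ReadSet.concat(readsets)
        log["simulate"] = {"samples": len(readsets), "reads": rs.n_reads}
        return rs

    # --- preprocess ---------------------------------------------------
    @stage("preprocess")
    def reads2() -> ReadSet:
        rs = io.length_filter(reads, config.read_length)
        n_discarded = 0
        if config.organelle_filter and organelle_ref is not None:
            rs, n_discarded = filter_organelle(rs, organelle_ref,
                                               config.organelle_k,
                                               config.organelle_min_matches)
        io.write_fasta(rs, outdir / "reads.fasta")
        log["preprocess"] = {"reads": rs.n_reads,
                             "organelle_pairs_discarded": n_discarded}
        return rs

    counts = reads2.analysed_counts()

    # --- similarity graph + clusters ----------------------------------
    @stage("cluster")
    def clustered():
        if reads2.n_reads > config.streaming_threshold:
            clusters, unclustered = cluster_streaming(
                reads2, config.min_identity, config.min_overlap, config.seed_k)
            hits = None
        else:
            hits = find_similarity_hits(reads2, config.min_identity,
                                        config.min_overlap, config.seed_k)
            graph = ReadGraph.from_readset(reads2, hits)
            clusters, unclustered = cluster_reads(graph)
            io.write_hitsort(hits, reads2, outdir / "hitsort.tsv")
        top = filter_top_clusters(clusters, reads2.n_reads,
                                  config.size_threshold)
        io.write_clusters(top, reads2, outdir / "clusters.tsv")
        log["cluster"] = {"clusters": len(clusters), "top_clusters": len(top),
                          "unclustered": len(unclustered),
                          "hits": None if hits is None else hits.n_hits}
        return hits, top

    hits, top_clusters = clustered

    # --- annotate + quantify ------------------------------------------
    @stage("quantify")
    def abundance():
        annotations = annotate_clusters(top_clusters, reads2, library,
                                        config.min_vote)
        table = quantify(top_clusters, annotations, counts, size_records)
        table.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        log["quantify"] = {"lineages": int(table["lineage"].nunique())}
        return annotations, table

    annotations, abundance_table = abundance

    # --- tandem profiles ----------------------------------------------
    @stage("tandem")
    def tandem_profiles():
        if hits is None:
            log["tandem"] = {"skipped": True,
                             "reason": "no hit table in streaming mode"}
            return []
        profiles = []
        for cluster, ann in zip(top_clusters, annotations):
            if cluster.size < 20:  # tandem statistics are meaningless below this
                continue
            exemplar = gene_exemplar if ann.lineage.lower().startswith(
                ("rdna", "5s")) else None
            prof = profile_tandem_cluster(cluster, reads2, hits,
                                          reads2.n_reads, exemplar)
            if prof.consensus_length or prof.graph_type:
                profiles.append((ann.lineage, prof))
        rows = [{"cluster_id": p.cluster_id, "lineage": lin,
                 "n_reads": p.n_reads,
                 "genome_proportion": round(p.genome_proportion, 6),
                 "consensus_length": p.consensus_length,
                 "kmer_coverage": round(p.kmer_coverage, 4),
                 "C_index": round(p.C_index, 4),
                 "graph_type": p.graph_type}
                for lin, p in profiles]
        pd.DataFrame(rows).to_csv(outdir / "tandem_profiles.tsv", sep="\t",
                                  index=False)
        with open(outdir / "tandem_consensus.fasta", "w") as fh:
            for lin, p in profiles:
                if p.consensus:
                    fh.write(f">cluster{p.cluster_id}_{lin}\n{p.consensus}\n")
        log["tandem"] = {"profiles": len(profiles)}
        return profiles

    # --- Hs/Ho landscape ----------------------------------------------
    @stage("hsho")
    def hsho_result():
        if hits is None:
            log["hsho"] = {"skipped": True,
                           "reason": "no hit table in streaming mode"}
            return None
        records, exclusions = hs_ho(hits, reads2.sample_idx,
                                    reads2.sample_codes, top_clusters,
                                    annotations, counts)
        hists = landscape_histograms(records)
        frames = [h.to_frame() for h in hists.values()]
        if frames:
            pd.concat(frames).to_csv(outdir / "hsho_histograms.tsv", sep="\t",
                                     index=False)
        modes = {lin: h.mode_center for lin, h in hists.items()}
        log["hsho"] = {"records": len(records),
                       "excluded": int(exclusions["excluded"].sum()),
                       "modes": modes}
        return {"records": records, "exclusions": exclusions,
                "histograms": hists, "modes": modes}

    # --- matrices + NJ + network --------------------------------------
    @stage("network")
    def network_result():
        if hits is None or len(reads2.sample_codes) < 3:
            log["network"] = {"skipped": True,
                              "reason": "needs a hit table and >= 3 samples"}
            return None
        samples = list(reads2.sample_codes)
        trees, retained, excluded = [], 0, 0
        for cluster in top_clusters:
            try:
                mat = observed_expected_matrix(cluster, hits,
                                               reads2.sample_idx, samples)
            except ValueError:
                excluded += 1
                continue
            dist = to_distance(mat)
            if dist is None:
                excluded += 1
                continue
            retained += 1
            trees.append((cluster.cluster_id, neighbor_joining(dist)))
        with open(outdir / "nj_trees.nwk", "w") as fh:
            for cid, tree in trees:
                fh.write(tree.newick() + "\n")
        net = None
        if trees:
            net = consensus_network([t for _, t in trees], config.min_support)
            write_splits_nexus(net, outdir / "consensus_splits.nex")
        log["network"] = {"retained": retained, "excluded": excluded,
                          "top_clusters": len(top_clusters)}
        return {"trees": trees, "network": net, "excluded": excluded,
                "retained": retained}

    # --- genome-size statistics ---------------------------------------
    @stage("stats")
    def stats_result():
        if not size_records:
            log["stats"] = {"skipped": True, "reason": "no genome sizes"}
            return None
        rows = []
        one_cx = {s: r.monoploid_mbp for s, r in size_records.items()}
        for lineage, grp in abundance_table.groupby("lineage"):
            grp = grp.set_index("sample")["mbp"].dropna()
            shared = [s for s in one_cx if s in grp.index]
            if len(shared) < 3:
                continue
            amounts = grp.loc[shared].to_numpy()
            sizes = np.array([one_cx[s] for s in shared], dtype=float)
            row = {"lineage": lineage, "n": len(shared)}
            try:
                corr = pearson_r2(amounts, sizes, lineage)
                row.update(R2=corr.R2, p=corr.p)
            except ValueError:
                row.update(R2=np.nan, p=np.nan)
            try:
                contrib = pairwise_contribution(amounts, sizes, lineage)
                row.update(min_mbp=contrib.min_mbp, max_mbp=contrib.max_mbp,
                           contribution_pct=contrib.mean_contribution_pct)
            except ValueError:
                row.update(min_mbp=np.nan, max_mbp=np.nan,
                           contribution_pct=np.nan)
            rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "genome_size_stats.tsv", sep="\t", index=False)
        log["stats"] = {"lineages": len(rows)}
        return df

    bundle.update(reads=reads2, clusters=top_clusters, hits=hits,
                  annotations=annotations, abundance=abundance_table,
                  tandem=tandem_profiles, hsho=hsho_result,
                  network=network_result, stats=stats_result)
    with open(outdir / "pipeline_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return bundle
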