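#!/usr/bin/env python
"""Run the full desk-scale pipeline on the bundled toy dataset.

Three diploid samples (~2,000 read pairs each at 0.5x) carrying three
dispersed TE families, a tandem satellite and a single-ribotype 5S locus
are simulated, clustered, annotated, profiled and networked.  Bulky
artifacts (reads, hitsort) land under scratch/; the stage log and the
abundance summary are copied into results/.
"""
import json
import shutil
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from repskim.config import PipelineConfig
from repskim.pipeline import run_pipeline
from repskim.scenarios import toy_genome_specs

SEED = 20240710


def main():
    outdir = ROOT / "scratch" / "toy_pipeline"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    specs, library, gene = toy_genome_specs(SEED)
    cfg = PipelineConfig(seed=SEED, outdir=str(outdir), coverage=0.5)
    bundle = run_pipeline(cfg, specs, library, gene_exemplar=gene)

    log = bundle["log"]
    print("pipeline stages:")
    print(json.dumps(log, indent=1, default=str))
    for small in ("abundance.tsv", "tandem_profiles.tsv",
                  "genome_size_stats.tsv", "pipeline_log.json"):
        src = outdir / small
        if src.exists():
            shutil.copy(src, results / f"01_{small}")
    n_fam = (bundle["abundance"]["lineage"] != "All repeats").sum()
    print(f"\nfound {log['cluster']['top_clusters']} clusters over "
          f"{log['preprocess']['reads']} reads; "
          f"{n_fam} sample x lineage abundance rows; "
          f"{log['network']['retained']} clusters survived for the network.")


if __name__ == "__main__":
    main()
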