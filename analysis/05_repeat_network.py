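#!/usr/bin/env python
"""Repeat-based phylogenomic network on six samples from a known tree.

Repeat families evolve along a three-cherry species tree; per-cluster
observed/expected edge matrices are inverted into distances, NJ trees
built per cluster, and their consensus split network checked for the true
cherries.  Writes the split-support summary to results/ (the pipeline
driver 01 writes newick trees and a SplitsTree splits block for its run).
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from repskim.scenarios import network_recovery_trial

SEED = 20240710


def main():
    trial = network_recovery_trial(SEED)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    rows = [{"split": " | ".join(side), "support": support}
            for side, support in trial["supports"].items()]
    pd.DataFrame(rows).to_csv(results / "05_network_supports.tsv",
                              sep="\t", index=False)
    print(f"clusters: {trial['n_clusters']}, NJ trees: {trial['n_trees']}, "
          f"excluded (incomplete/zero matrices): {trial['excluded']}")
    for side, support in trial["supports"].items():
        print(f"  true split {side}: support {support:.2f}")
    print("all true splits at support >= 0.5:", trial["recovered"])


if __name__ == "__main__":
    main()
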