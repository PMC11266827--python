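#!/usr/bin/env python
"""Hs/Ho diversification landscape on a conserved vs diverged family pair.

Two equal-coverage samples share one conserved repeat family and one
family diverged 8% between them.  Per-read intraspecific/interspecific
hit ratios are histogrammed per lineage on the log10 scale: the conserved
family peaks at 0, the diverged one well to the right.
Writes results/04_hsho_histograms.tsv and prints the mode positions.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from repskim.scenarios import hsho_scenario

SEED = 20240710


def main():
    out = hsho_scenario(SEED)
    frames = [h.to_frame() for h in out["histograms"].values()]
    df = pd.concat(frames)
    df = df[df["count"] > 0]
    path = ROOT / "results" / "04_hsho_histograms.tsv"
    path.parent.mkdir(exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    print("records per lineage:")
    print(out["records"].groupby("lineage")["log_ratio"]
          .agg(["count", "median"]).round(3).to_string())
    print("\nhistogram mode centers (log10 Hs/Ho):")
    for lin, mode in sorted(out["modes"].items()):
        print(f"  {lin:10s} {mode:+.2f}")


if __name__ == "__main__":
    main()
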