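#!/usr/bin/env python
"""Genome-size arithmetic over the bundled 44-accession sample table.

Recomputes monoploid (1Cx) sizes from 2C and ploidy, converts the extreme
genome sizes to Mbp (978 Mbp/pg, floored), and reports the holoploid and
repeatome fold ranges.  Flags any published row whose printed 1Cx value
disagrees with the 2C/nx rule.  Writes results/06_genome_sizes.tsv.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from repskim.quantify import GenomeSizeRecord, fold_ratio, load_sample_table


def main():
    table = load_sample_table()
    recs = [GenomeSizeRecord.from_pg(r.code, r.two_C_pg, int(r.nx))
            for r in table.itertuples()]
    table["one_Cx_recomputed"] = [r.one_Cx_pg for r in recs]
    table["holoploid_mbp"] = [r.holoploid_mbp for r in recs]
    table["monoploid_mbp"] = [r.monoploid_mbp for r in recs]
    table["consistent"] = table["one_Cx_pg"] == table["one_Cx_recomputed"]
    out = ROOT / "results" / "06_genome_sizes.tsv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t", index=False)

    big = max(recs, key=lambda r: r.holoploid_mbp)
    small = min(recs, key=lambda r: r.holoploid_mbp)
    print(f"largest genome:  {big.sample:12s} {big.holoploid_mbp} Mbp "
          f"(monoploid {big.monoploid_mbp} Mbp)")
    print(f"smallest genome: {small.sample:12s} {small.holoploid_mbp} Mbp "
          f"(monoploid {small.monoploid_mbp} Mbp)")
    print(f"holoploid fold range: "
          f"{fold_ratio(big.holoploid_mbp, small.holoploid_mbp)}")
    print(f"repeatome percentage fold range (67.97% vs 20.77%): "
          f"{fold_ratio(67.97, 20.77)}")
    bad = table[~table.consistent]
    print(f"\nrows consistent with 1Cx = 2C/nx: "
          f"{int(table.consistent.sum())}/{len(table)}")
    if len(bad):
        print("inconsistent published rows (printed vs recomputed):")
        print(bad[["code", "two_C_pg", "nx", "one_Cx_pg",
                   "one_Cx_recomputed"]].to_string(index=False))


if __name__ == "__main__":
    main()
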