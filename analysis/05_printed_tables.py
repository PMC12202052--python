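#!/usr/bin/env python
"""Arithmetic consistency of the published comparative tables.

Recomputes the coding fraction ("gene length / genome") column of the
assembly-statistics table and the ortholog-cluster totals (proteins,
singleton clusters, singleton percentage) from the table cells shipped
with the package, and writes results/tables/table_checks.json.
"""

import argparse
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from gak.stats import cluster_table_checks, coding_fraction


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    data = resources.files("gak") / "data"
    t1 = pd.read_csv(data / "table1_assembly_stats.tsv", sep="\t")
    t3 = pd.read_csv(data / "table3_protein_clusters.tsv", sep="\t")

    coding = {}
    for _, row in t1.iterrows():
        computed = coding_fraction(int(row["gene_length"]), int(row["total_length"]))
        coding[row["organism"]] = {"computed": computed,
                                   "printed": float(row["printed_coding_percent"]),
                                   "match": computed == round(float(
                                       row["printed_coding_percent"]), 2)}
        flag = "OK" if coding[row["organism"]]["match"] else "MISMATCH"
        print(f"{row['organism']:28s} coding {computed:6.2f}%  [{flag}]")

    clusters = cluster_table_checks(
        [(int(r["n_proteins"]), int(r["n_clusters"]), int(r["n_singletons"]))
         for _, r in t3.iterrows()])
    print(f"cluster totals: {clusters['total_proteins']:,} proteins, "
          f"{clusters['total_singleton_clusters']:,} singleton clusters "
          f"({clusters['singleton_percent']}%)")

    with open(args.out_dir / "table_checks.json", "w") as out:
        json.dump({"coding_fraction": coding, "clusters": clusters}, out, indent=1)
        out.write("\n")


if __name__ == "__main__":
    main()
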