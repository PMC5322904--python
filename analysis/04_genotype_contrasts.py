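#!/usr/bin/env python
"""Genotype contrasts and library clustering.

Tests, per abundant miRNA group, whether truncation-linked categories drop in
the sdn-like background and whether TR+TA mass shifts to TR-only in the
heso1-like background (Welch t on per-replicate proportions, significance
stars at 0.05/0.01/0.001); clusters all libraries on log2(RPM+1) at
isoform-category resolution.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from isotail.compare import bh_adjust, cluster_libraries, sum_truncation_test, two_group_test
from isotail.pipeline import category_rpm_table

BASE = Path(__file__).resolve().parents[1] / "results"
IN, OUT = BASE / "quantification", BASE / "comparison"

CONTRASTS = [
    ("hen1_like", "hen1_sdn_like", ("p_TR", "p_TRTA")),
    ("hen1_like", "hen1_heso1_like", ("p_TR", "p_TRTA")),
    ("wildtype_like", "hen1_like", ("p_TR", "p_TRTA", "p_TA")),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    comp = pd.read_csv(IN / "composition.tsv", sep="\t")
    comp["genotype"] = comp["library_id"].str.rsplit("_", n=1).str[0]
    kept = pd.read_csv(IN / "abundant_groups.tsv", sep="\t")["group_name"]

    rows = []
    for geno_a, geno_b, metrics in CONTRASTS:
        for group in kept:
            sub = comp[comp["group_name"] == group]
            va_tbl = sub[sub["genotype"] == geno_a].set_index("library_id")
            vb_tbl = sub[sub["genotype"] == geno_b].set_index("library_id")
            for metric in metrics:
                res = two_group_test(
                    va_tbl[metric], vb_tbl[metric],
                    group_name=group, metric_name=metric,
                )
                rows.append({"contrast": f"{geno_a}_vs_{geno_b}",
                             **dataclasses.asdict(res)})
            total = sum_truncation_test(
                va_tbl["p_TR"], va_tbl["p_TRTA"],
                vb_tbl["p_TR"], vb_tbl["p_TRTA"], group_name=group,
            )
            rows.append({"contrast": f"{geno_a}_vs_{geno_b}",
                         **dataclasses.asdict(total)})
    contrasts = pd.DataFrame(rows)
    contrasts["p_bh"] = bh_adjust(contrasts["p_value"].fillna(1.0))
    contrasts.to_csv(OUT / "contrasts.tsv", sep="\t", index=False)

    for name, sub in contrasts.groupby("contrast"):
        sig = sub[sub["stars"] != ""]
        down = (sig["direction"] < 0).sum()
        print(f"{name}: {len(sig)}/{len(sub)} significant tests "
              f"({down} reductions)")

    dist, newick = cluster_libraries(category_rpm_table(comp))
    dist.rename_axis("library_id").to_csv(OUT / "distances.tsv", sep="\t")
    (OUT / "dendrogram.nwk").write_text(newick + "\n")
    print(f"dendrogram: {newick}")


if __name__ == "__main__":
    main()
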