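#!/usr/bin/env python
"""Quantify isoform compositions, apply the RPM > 10 abundance filter, and
build truncation-tailing matrices.

Writes the per-library composition table (counts, RPM, four-category
proportions plus truncation and TR-only ratios), the list of groups abundant
in every library, and long-form truncation-tailing matrices for those groups.
"""

from pathlib import Path

import pandas as pd

from isotail.classify import IsoformCall
from isotail.quantify import (
    abundance_filter,
    build_matrix,
    compose,
    matrix_long,
    tronly_ratio,
    truncation_ratio,
    u_fraction,
)

BASE = Path(__file__).resolve().parents[1] / "results"
IN, OUT = BASE / "classification", BASE / "quantification"
RPM_THRESHOLD = 10.0


def load_calls(path: Path) -> list[IsoformCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        IsoformCall(group_name=r["group"], tr=int(r["tr"]),
                    tail_seq=str(r["tail_seq"]), count=float(r["count"]),
                    templated_ext=int(r["templated_ext"]))
        for _, r in df.iterrows()
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    stats = pd.read_csv(IN / "library_stats.tsv", sep="\t").set_index("library_id")
    comps, mats = [], []
    calls_by_lib = {}
    for path in sorted(IN.glob("calls_*.tsv")):
        lib = path.stem.removeprefix("calls_")
        calls = load_calls(path)
        calls_by_lib[lib] = calls
        denom = stats.at[lib, "total"] - stats.at[lib, "length_filtered"]
        comps.append(compose(calls, denom, lib))
    composition = pd.concat(comps, ignore_index=True)
    composition["truncation_ratio"] = composition.apply(truncation_ratio, axis=1)
    composition["tronly_ratio"] = composition.apply(tronly_ratio, axis=1)
    composition.to_csv(OUT / "composition.tsv", sep="\t", index=False)

    kept = abundance_filter(composition, RPM_THRESHOLD)
    pd.Series(kept, name="group_name").to_csv(
        OUT / "abundant_groups.tsv", sep="\t", index=False
    )
    print(f"{len(kept)} groups at RPM > {RPM_THRESHOLD:g} in all "
          f"{composition['library_id'].nunique()} libraries")

    for lib, calls in calls_by_lib.items():
        for g in kept:
            sub = [c for c in calls if c.group_name == g]
            if sub:
                mats.append(matrix_long(build_matrix(sub, g), lib, g))
        tails = u_fraction(calls)
        print(f"{lib}: tail U-fraction {tails:.3f}")
    pd.concat(mats, ignore_index=True).to_csv(
        OUT / "matrices.tsv", sep="\t", index=False
    )

    # headline: mean truncation ratio per genotype
    composition["genotype"] = composition["library_id"].str.rsplit("_", n=1).str[0]
    headline = (
        composition.groupby("genotype")["truncation_ratio"].mean().round(4)
    )
    print("mean truncation ratio by genotype:")
    print(headline.to_string())


if __name__ == "__main__":
    main()
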