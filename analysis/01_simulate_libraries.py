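#!/usr/bin/env python
"""Simulate the study's small-RNA libraries.

Generates two replicates each of four genotype-like profiles (wild type,
hen1, hen1 sdn1 sdn2, hen1 heso1) from the built-in synthetic reference,
writing collapsed FASTA plus a per-read ground-truth manifest per library,
and the reference itself (mature/hairpin FASTA + offsets) for downstream
steps.
"""

from pathlib import Path

from isotail.refsets import write_references
from isotail.synthetic import (
    demo_reference,
    generate_library,
    preset_profiles,
    write_reads_collapsed_fasta,
)

SEED = 1
LIBRARY_SIZE = 50_000
GENOTYPES = ("wildtype_like", "hen1_like", "hen1_sdn_like", "hen1_heso1_like")
# raw reads and per-read manifests are bulky regenerable intermediates;
# they go under scratch/ while derived tables live under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    refset = demo_reference()
    write_references(refset, OUT / "mature.fa", OUT / "hairpin.fa", OUT / "offsets.tsv")
    profiles = preset_profiles(refset.group_names, library_size=LIBRARY_SIZE)
    for genotype in GENOTYPES:
        for rep in (1, 2):
            lib = f"{genotype}_r{rep}"
            reads, manifest = generate_library(profiles[genotype], refset, lib, SEED)
            write_reads_collapsed_fasta(reads, OUT / f"{lib}.fa")
            manifest.to_csv(OUT / f"{lib}.manifest.tsv", sep="\t", index=False)
            print(f"{lib}: {len(reads)} reads -> {OUT / f'{lib}.fa'}")
    print(f"reference: {len(refset)} collapsed groups "
          f"({', '.join(refset.group_names[:5])}, ...)")


if __name__ == "__main__":
    main()
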