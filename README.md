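# isotail

3′-isoform analysis for plant small-RNA sequencing libraries: classify
miRNA-derived reads by 3′ truncation and 3′ tailing, quantify isoform
compositions, and run the cross-library procedures of a genotype-contrast
study — abundance filtering, replicate statistics, enzymatic-assay control
subtraction, truncation–tailing matrices and library clustering. A synthetic
read generator with per-read ground truth makes every stage testable without
any external download.

## The problem

In *Arabidopsis*, miRNA degradation proceeds through two 3′-end marks:
exonucleolytic **truncation** (removal of 3′ nucleotides, attributed to SDN
exonucleases) and non-templated, U-rich **tailing** (added by the HESO1/URT1
nucleotidyl transferases). Both are rare in wild type, where miRNAs carry a
protective 2′-*O*-methyl group, and rampant in *hen1* mutants that lack it.
Reading these marks out of sRNA-seq libraries requires decomposing each read
relative to its mature miRNA:

```
read = mature[0 : L − tr] + tail        (L = mature length)
```

which places every read in one of four mutually exclusive categories:

| category | tr | ta = len(tail) |
|----------|-----|-----|
| FL (full length) | 0 | 0 |
| TR-only          | > 0 | 0 |
| TA-only          | 0 | > 0 |
| TR+TA            | > 0 | > 0 |

Reads are assigned to a miRNA by exact 5′-anchored prefix matching (small-RNA
reads begin at the Dicer-defined 5′ terminus; all variation of interest is at
the 3′ end). Loci producing identical mature sequences (e.g. miR165a/b) are
collapsed into one group ("miR165ab"). Per-library, per-group category
proportions, reads-per-million (RPM = count / library total × 10⁶),
truncation ratio ((TR-only + TR+TA)/total) and TR-only ratio feed the
downstream comparisons: Welch *t*-tests across replicate proportions with
significance stars (\*, \*\*, \*\*\* at 0.05/0.01/0.001), RPM > 10 abundance
filters, mock-reaction subtraction for in-vitro exonuclease assays, and
hierarchical clustering of libraries on log₂(RPM + 1).

## Worked example

```python
from isotail import (demo_reference, preset_profiles, generate_library,
                     classify_library, compose, truncation_ratio)

refset = demo_reference()                      # synthetic 11-group reference
profile = preset_profiles(refset.group_names, library_size=50_000)["hen1_like"]
reads, manifest = generate_library(profile, refset, "hen1_r1", seed=1)
calls, stats = classify_library(reads, refset)
table = compose(calls, stats.denominator, "hen1_r1")
row = table.set_index("group_name").loc["miR165ab"]
print(f"{row.total:.0f} reads  p_FL={row.p_FL:.3f}  p_TR={row.p_TR:.3f} "
      f"p_TA={row.p_TA:.3f}  p_TRTA={row.p_TRTA:.3f}")
print(f"truncation ratio = {truncation_ratio(row):.3f}")
```

prints

```
12943 reads  p_FL=0.348  p_TR=0.194 p_TA=0.153  p_TRTA=0.305
truncation ratio = 0.499
```

i.e. the classifier recovers the generator's hen1-like mixture
(0.35/0.20/0.15/0.30) for the miR165ab group, and half of its reads carry a
3′ truncation.

## Analysis workflow

The numbered drivers under `analysis/` run the full study on synthetic
libraries (two replicates × four genotype-like profiles, 50 000 reads each),
writing tables under `results/` (bulky intermediates go to `scratch/`):

```bash
python analysis/01_simulate_libraries.py   # reads + ground-truth manifests
python analysis/02_classify_reads.py       # isoform calls per library
python analysis/03_quantify_isoforms.py    # compositions, RPM filter, matrices
python analysis/04_genotype_contrasts.py   # Welch tests + stars, clustering
python analysis/05_sdn1_ip_assay.py        # mock subtraction, TR/FL ratios
```

The same stages are scriptable from one YAML config through the CLI
(`isotail run --config cfg.yaml`; also `simulate`, `classify`, `quantify`,
`validate` subcommands).

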