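# Methods

## Read model and classification

A small-RNA read derived from a mature miRNA of length *L* is modelled as

```
read = mature[0 : L − tr] + tail,      tr ≥ 0,  ta = len(tail) ≥ 0,
```

i.e. 3′-exonucleolytic truncation of `tr` nucleotides followed by addition of
a (typically non-templated, U-rich) `tail`. The pair (tr, ta) fixes the four
categories FL, TR-only, TA-only and TR+TA. The 5′ end is assumed intact:
small-RNA reads begin at the Dicer-defined 5′ terminus, and the phenomena
quantified here are exclusively 3′-end events, so the matcher allows no 5′
offsets, internal mismatches or indels. Within that model the decomposition
found by taking the longest common prefix of read and mature is unique.

Matching proceeds per read: candidate references are looked up by the read's
first `min_match` bases (default 12, ~4¹² specificity); for each candidate the
longest common prefix gives (tr, tail); candidates are accepted when
tr ≤ `max_tr` (8) and ta ≤ `max_ta` (8); among acceptors the minimal-tr
candidate wins. Exact ties between near-identical families are dropped and
counted by default (`ambiguous_policy="drop"`), or split equally
(`"fractional"`), in which case non-integer counts propagate to all tables.
Reads outside 15–30 nt are counted as length-filtered before matching; reads
failing every candidate are UNASSIGNED, never errors. The conservation
identity `assigned + unassigned + ambiguous_dropped + length_filtered =
total` is asserted in tests.

Two tail dialects exist because hairpin-templated residues downstream of the
mature 3′ end are indistinguishable from tailing without hairpin context:

- `mature_anchored` (default): every base past the matched mature prefix
  counts as tail, even if genome-templated. Rationale: a templated U would
  otherwise silently mask uridylation.
- `template_extended`: the match may continue into the hairpin's downstream
  template; the templated extension length is reported in a separate column
  while the full suffix remains the tail. Provided for sensitivity analysis.

## Reference handling

Mature and hairpin sequences load from miRBase-style FASTA; T is normalized
to U and non-ACGU(T) characters are hard errors. Loci with identical mature
sequences are collapsed into one group named stem + concatenated sorted
suffix letters (miR165a + miR165b → miR165ab), with an override table for
irregular names. Each group keeps one hairpin context supplying the
downstream template. A mature occurring at multiple positions in its hairpin
requires an explicit offsets table (mature_name, hairpin_name, offset_0based)
because the templated context would otherwise be ambiguous.

## Quantification

- **RPM** = count / denominator × 10⁶. The denominator is the library total
  after the 15–30 nt length filter (assigned + unassigned), logged per
  library; a miRNA-assigned-only denominator is selectable since either
  normalization convention is found in practice.
- **Composition**: per-group counts and proportions over the four categories;
  zero-read groups are omitted rather than emitted as NaN rows, avoiding 0/0
  downstream. Truncation ratio = (TR-only + TR+TA)/total; TR-only ratio =
  TR-only/total.
- **Abundance filter**: groups with RPM above a threshold (default 10) in
  every library (`all_libraries`) or any library (`any_library`).
- **Truncation–tailing matrix**: proportions over the (tr, ta) grid,
  (max_tr+1) × (max_ta+1). Category proportions are exactly its margins
  (asserted over random call sets).
- **Binding fractions** for Argonaute-IP libraries: a group's share of all
  assigned miRNA reads, ×100.
- **Display rounding** for printed percentage tables is half-up to one
  decimal (`decimal.Decimal`); all internal computation is full precision.

## Cross-library comparisons

- **Two-group tests**: two-sided Welch *t* on raw per-replicate proportions,
  chosen for robustness to unequal variances at the n = 2–3 replicates
  typical of these designs; a pooled-variance Student variant is selectable.
  Stars at p < 0.05/0.01/0.001. Raw p-values are reported (the star
  convention predates multiple-testing correction in this literature);
  Benjamini–Hochberg adjusted values are available as an extra column. A
  combined test on the per-replicate sum p_TR + p_TRTA catches total-
  truncation changes whose components are individually non-significant.
- **Enzymatic-assay subtraction**: replicates are pooled at count level
  *before* any ratio (pool-then-ratio, not mean-of-ratios; a regression test
  pins a fixture where the two differ). The truncated-species proportions
  (p_TR, p_TRTA) measured in the no-enzyme mock are subtracted entrywise
  from each enzyme arm, floored at zero; FL is left untouched so the TR/FL
  readout keeps its denominator. Subtraction on the RPM scale is selectable.
- **Library clustering**: log₂(RPM + 1), Euclidean distances, agglomerative
  clustering with average linkage (configurable: single/complete/average/
  ward). The feature rows are per-(group, category) RPM rather than group
  totals: genotypes in this design share abundance profiles and differ only
  in isoform composition, which group totals cannot separate. The dendrogram
  is serialized as Newick.

## Synthetic data generator

Each genotype profile specifies per-group abundance weights, a four-category
mixture (optionally per-group), truncated-geometric laws for tr and ta
lengths (P(k) ∝ q^(k−1) over 1..max; q_tr = q_ta = 0.45 by default, matching
the short-offset dominance of observed truncation–tailing matrices without
claiming their exact law), a U-biased tail composition (P(U) = 0.9,
reflecting HESO1/URT1 uridylation), a background fraction of random 15–30 nt
hairpin fragments, a per-base substitution error rate, and a library size
(default 50 000 reads). Presets:

| preset | mixture (FL/TR/TA/TR+TA) | encodes |
|---|---|---|
| wildtype_like | 0.94/0.02/0.03/0.01 | methylated, stable miRNAs |
| hen1_like | 0.35/0.20/0.15/0.30 | unmethylated: rampant truncation + tailing |
| hen1_sdn_like | 0.60/0.08/0.20/0.12 | exonucleases removed: truncation drops |
| hen1_heso1_like | 0.35/0.40/0.08/0.17 | transferase removed: TR+TA → TR-only |
| ago10_oe_like | wild type, but 0.70/0.15/0.03/0.12 for miR165/6 | selective miR165/6 destabilization |

Reproducibility: one root seed; each library's stream is derived by SHA-256
of (seed, library id), so libraries are independent yet exactly repeatable,
and identical (seed, id) pairs give byte-identical output.

**Collision control** (default on): the first tail base is resampled away
from the base the hairpin/mature would place next, so every generated read
has a single valid decomposition and ground truth is exact under either
dialect. Off, a tail starting with the just-removed mature base is legally
absorbed by the prefix matcher — a genuine ambiguity of the data, not a bug.

**Generator truncation cap**: tr is drawn from 1..6 (not the classifier's 8)
and demo-reference matures are 21–22 nt, so every truncated read stays ≥ 15
nt and every tailed read ≤ 30 nt — inside the length filter. Deeper
truncations would be silently filtered and break closed-loop accounting.

**What the generator does not model**: ligation/adapter bias, PCR
duplication structure, quality-score realism, 5′ isomiRs, internal editing,
expression differences between genotypes beyond the category mixtures, and
empirical tr/ta length laws (not recoverable from published figures).
Passing closed-loop tests therefore demonstrates correctness of the
classification and statistics machinery under the stated read model — not
performance on real libraries with 5′ heterogeneity or mismatches.

## Numerical and scale choices

- Closed-loop recovery is checked at 100 000 reads concentrated on three
  groups (~33 000 each), where the binomial standard error (~0.003) sits
  well inside the ±0.01 acceptance band; per-group checks at the skewed
  default abundance would put low-weight groups (~1 400 reads) where ±0.01
  is statistically meaningless.
- At a 1% per-base error rate the measured composition error is ~0.05, not
  ~1%: a substitution in the last `max_tr` bases re-decomposes a full-length
  read as TR+TA instead of unassigning it. The test suite pins this measured
  behaviour (≤ 0.06, dominant flow FL → TR+TA).
- Analysis drivers use 50 000-read libraries and two replicates per
  genotype; contrast power at these sizes is extreme (effects ~50× the
  replicate noise), so conclusions do not hinge on the simulated depth.
- Proportions are validated to sum to 1 within 1e-9; percentage tables use
  half-up rounding at one decimal.

## Known limitations

- Exact 5′-anchored matching cannot assign reads with 5′ isomiR offsets or
  sequencing errors in the first `min_match` bases; such reads are counted
  UNASSIGNED rather than rescued.
- Deep truncation can erase the distinction between near-identical families;
  the minimal-tr / drop-ties policy is conservative and loses those reads
  (logged) rather than guessing.
- The Welch test on n = 2 replicates has 2 degrees of freedom; stars at such
  depths indicate effect consistency more than calibrated error rates.
- The four-category model ignores tail composition beyond a U-fraction
  summary and does not attempt motif statistics.
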