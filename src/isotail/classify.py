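"""Assign reads to miRNA groups and decompose their 3' ends.

A read is matched to a mature miRNA by its 5' end only: small-RNA reads start
at the Dicer-defined 5' terminus, and all the variation of interest here
(exonucleolytic truncation, nucleotidyl-transferase tailing) happens at the
3' end.  The longest common prefix of read and mature then fixes a unique
decomposition ``read = mature[:len(mature)-tr] + tail``, from which the four
canonical categories follow:

=========  ==========  ==========
category   truncation  tail
=========  ==========  ==========
FL         tr == 0     ta == 0
TR_ONLY    tr  > 0     ta == 0
TA_ONLY    tr == 0     ta  > 0
TR_TA      tr  > 0     ta  > 0
=========  ==========  ==========
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .refsets import MiRNARef, ReferenceSet, normalize_rna

__all__ = [
    "FL", "TR_ONLY", "TA_ONLY", "TR_TA", "CATEGORIES",
    "ReadRecord", "IsoformCall", "ClassifyParams", "LibraryStats",
    "category_of", "classify_read", "classify_library",
    "read_fastq", "read_collapsed_fasta", "write_calls_tsv",
]

FL = "FL"
TR_ONLY = "TR_ONLY"
TA_ONLY = "TA_ONLY"
TR_TA = "TR_TA"
CATEGORIES = (FL, TR_ONLY, TA_ONLY, TR_TA)


def category_of(tr: int, ta: int) -> str:
    if tr == 0:
        return FL if ta == 0 else TA_ONLY
    return TR_ONLY if ta == 0 else TR_TA


@dataclass(frozen=True)
class ReadRecord:
    seq: str
    count: float = 1

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError("empty read")
        if self.count <= 0:
            raise ValueError("read count must be positive")


@dataclass(frozen=True)
class IsoformCall:
    """A read's assignment to a miRNA group and 3'-end decomposition."""

    group_name: str
    tr: int
    tail_seq: str
    count: float = 1
    templated_ext: int = 0

    @property
    def ta(self) -> int:
        return len(self.tail_seq)

    @property
    def category(self) -> str:
        return category_of(self.tr, self.ta)


@dataclass(frozen=True)
class ClassifyParams:
    """Knobs of the 5'-anchored matcher.

    max_tr/max_ta cap the accepted truncation and tail lengths (beyond them a
    read is UNASSIGNED).  min_match is the minimum exactly-matched 5' prefix;
    12 nt gives ~4^12 specificity, ample for a miRNA-sized reference.
    tail_dialect 'mature_anchored' counts every base past the matched mature
    prefix as tail even when it is genome-templated (templated U would
    otherwise mask uridylation); 'template_extended' lets the match continue
    into the hairpin and reports the templated extension separately.
    """

    max_tr: int = 8
    max_ta: int = 8
    min_match: int = 12
    tail_dialect: str = "mature_anchored"  # or "template_extended"
    ambiguous_policy: str = "drop"  # or "fractional"
    min_len: int = 15
    max_len: int = 30

    def __post_init__(self):
        if self.tail_dialect not in ("mature_anchored", "template_extended"):
            raise ValueError(f"unknown tail_dialect {self.tail_dialect!r}")
        if self.ambiguous_policy not in ("drop", "fractional"):
            raise ValueError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")


@dataclass
class LibraryStats:
    total: float = 0.0
    assigned: float = 0.0
    unassigned: float = 0.0
    ambiguous_dropped: float = 0.0
    length_filtered: float = 0.0

    @property
    def denominator(self) -> float:
        """Reads passing the length filter; default RPM denominator."""
        return self.total - self.length_filtered


def _lcp_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _match_one(read_seq: str, ref: MiRNARef, params: ClassifyParams):
    """Return (tr, tail_seq, templated_ext) for one candidate, or None."""
    matched = _lcp_len(read_seq, ref.mature_seq)
    if matched < params.min_match:
        return None
    ext = 0
    if params.tail_dialect == "template_extended" and matched == len(ref.mature_seq):
        ext = _lcp_len(read_seq[matched:], ref.downstream_template)
    tr = len(ref.mature_seq) - matched
    tail = read_seq[matched:]
    if tr > params.max_tr or len(tail) - ext > params.max_ta:
        return None
    return tr, tail, ext


def classify_read(
    read: ReadRecord,
    refset: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
) -> list[IsoformCall]:
    """Classify one read; [] means UNASSIGNED, >1 calls mean a fractional split.

    Among refs accepting the read, the one with minimal truncation wins; exact
    ties are dropped (policy 'drop') or split equally (policy 'fractional').
    """
    hits: list[tuple[int, MiRNARef, tuple]] = []
    for ref in refset.candidates(read.seq, params.min_match):
        m = _match_one(read.seq, ref, params)
        if m is not None:
            hits.append((m[0], ref, m))
    if not hits:
        return []
    best_tr = min(h[0] for h in hits)
    best = [h for h in hits if h[0] == best_tr]
    if len(best) > 1 and params.ambiguous_policy == "drop":
        return []
    share = read.count / len(best)
    return [
        IsoformCall(
            group_name=ref.group_name,
            tr=tr,
            tail_seq=tail,
            count=share,
            templated_ext=ext,
        )
        for _, ref, (tr, tail, ext) in best
    ]


def classify_library(
    reads: Iterable[ReadRecord],
    refset: ReferenceSet,
    params: ClassifyParams = ClassifyParams(),
) -> tuple[list[IsoformCall], LibraryStats]:
    """Classify a read stream; aggregate calls by (group, tr, tail).

    Reads outside the ``min_len``–``max_len`` window are counted as
    length_filtered and never reach the matcher.
    """
    stats = LibraryStats()
    agg: dict[tuple[str, int, str, int], float] = Counter()
    for read in reads:
        stats.total += read.count
        if not (params.min_len <= len(read.seq) <= params.max_len):
            stats.length_filtered += read.count
            continue
        calls = classify_read(read, refset, params)
        if not calls:
            # distinguish a true no-hit from an ambiguity drop
            had_tie = False
            if params.ambiguous_policy == "drop":
                relaxed = replace(params, ambiguous_policy="fractional")
                had_tie = len(classify_read(read, refset, relaxed)) > 1
            if had_tie:
                stats.ambiguous_dropped += read.count
            else:
                stats.unassigned += read.count
            continue
        stats.assigned += read.count
        for c in calls:
            agg[(c.group_name, c.tr, c.tail_seq, c.templated_ext)] += c.count
    calls = [
        IsoformCall(group_name=g, tr=tr, tail_seq=tail, count=n, templated_ext=ext)
        for (g, tr, tail, ext), n in sorted(agg.items())
    ]
    return calls, stats


# ---------------------------------------------------------------------------
# I/O

_COUNT_RE_DEFAULT = r"[_x](?P<count>\d+)$"


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """FASTQ reads, quality ignored, count 1 each."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(seq=normalize_rna(str(rec.seq), where=f"read {rec.id!r}"))


def read_collapsed_fasta(
    path: str | Path, count_regex: str = _COUNT_RE_DEFAULT
) -> Iterator[ReadRecord]:
    """Collapsed FASTA with multiplicity encoded in headers like 'id_x53'."""
    pattern = re.compile(count_regex)
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.search(rec.id)
        count = int(m.group("count")) if m else 1
        yield ReadRecord(
            seq=normalize_rna(str(rec.seq), where=f"read {rec.id!r}"), count=count
        )


def write_calls_tsv(path: str | Path, library: str, calls: list[IsoformCall]) -> None:
    with open(path, "w") as fh:
        fh.write("library\tgroup\ttr\ttail_seq\tta\tcategory\tcount\ttemplated_ext\n")
        for c in calls:
            fh.write(
                f"{library}\t{c.group_name}\t{c.tr}\t{c.tail_seq}\t{c.ta}\t"
                f"{c.category}\t{c.count:g}\t{c.templated_ext}\n"
            )
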