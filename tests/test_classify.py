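"""5'-anchored read assignment and 3'-end decomposition.

The reference behaviour is pinned by an exhaustive oracle that tries every
split of a read into (mature prefix, suffix) and keeps the split with the
longest matched prefix — independent of the production matcher's
index-and-scan implementation.
"""

import numpy as np
import pytest

from isotail.classify import (
    FL,
    TA_ONLY,
    TR_ONLY,
    TR_TA,
    ClassifyParams,
    ReadRecord,
    classify_library,
    classify_read,
    read_collapsed_fasta,
    read_fastq,
)
from isotail.refsets import MiRNARef, ReferenceSet

from conftest import MATURE_T

BASES = ["A", "C", "G", "U"]


def oracle_classify(read_seq, refset, params):
    """Exhaustive (mature-prefix, suffix) split enumeration, maximal prefix."""
    hits = []
    for ref in refset:
        valid = [
            m
            for m in range(len(ref.mature_seq) + 1)
            if read_seq[:m] == ref.mature_seq[:m]
            # maximality: the split point must be where read and mature part ways
            and (
                m == len(ref.mature_seq)
                or m == len(read_seq)
                or read_seq[m] != ref.mature_seq[m]
            )
        ]
        if not valid:
            continue
        m = max(valid)
        tr = len(ref.mature_seq) - m
        tail = read_seq[m:]
        if m >= params.min_match and tr <= params.max_tr and len(tail) <= params.max_ta:
            hits.append((tr, ref.group_name, tail))
    if not hits:
        return []
    best_tr = min(h[0] for h in hits)
    return sorted(h for h in hits if h[0] == best_tr)


class TestSpecExamples:
    @pytest.mark.parametrize(
        "read_seq,expected",
        [
            (MATURE_T, (0, "", FL)),
            (MATURE_T[0:19] + "UU", (2, "UU", TR_TA)),
            (MATURE_T + "U", (0, "U", TA_ONLY)),
            (MATURE_T[0:18], (3, "", TR_ONLY)),
        ],
    )
    def test_canonical_decompositions(self, mini_refset, read_seq, expected):
        calls = classify_read(ReadRecord(seq=read_seq), mini_refset)
        assert len(calls) == 1
        c = calls[0]
        tr, tail, cat = expected
        assert (c.tr, c.tail_seq, c.category) == (tr, tail, cat)
        # reconstruction invariant
        assert MATURE_T[: len(MATURE_T) - c.tr] + c.tail_seq == read_seq

    def test_short_match_is_unassigned(self, mini_refset):
        assert classify_read(ReadRecord(seq=MATURE_T[0:10]), mini_refset) == []

    def test_deep_truncation_beyond_cap_unassigned(self, mini_refset):
        read = MATURE_T[0:12]  # tr = 9 > max_tr 8, but matched 12 >= min_match
        assert classify_read(ReadRecord(seq=read), mini_refset) == []

    def test_long_tail_beyond_cap_unassigned(self, mini_refset):
        read = MATURE_T + "U" * 9
        assert classify_read(ReadRecord(seq=read), mini_refset) == []


class TestTemplateExtendedDialect:
    def test_templated_extension_recorded(self, mini_refset, mini_ref):
        assert mini_ref.downstream_template.startswith("GG")
        read = MATURE_T + "GGU"  # GG templated, U non-templated
        params = ClassifyParams(tail_dialect="template_extended")
        (c,) = classify_read(ReadRecord(seq=read), mini_refset, params)
        assert (c.tr, c.tail_seq, c.templated_ext) == (0, "GGU", 2)
        # mature-anchored dialect calls the same read a 3-nt tail
        (c2,) = classify_read(ReadRecord(seq=read), mini_refset)
        assert (c2.tr, c2.tail_seq, c2.templated_ext) == (0, "GGU", 0)


class TestAmbiguity:
    @pytest.fixture()
    def twin_refset(self):
        # two matures identical over their first 16 nt; a 16-nt read ties
        a = "ACGUACGUACGUACGU" + "AAAAA"
        b = "ACGUACGUACGUACGU" + "CCCCC"
        hp_a, hp_b = "GG" + a + "UUUUU", "GG" + b + "UUUUU"
        return ReferenceSet(
            refs=[
                MiRNARef("miRa", ("miRa",), a, "HPa", hp_a, 2),
                MiRNARef("miRb", ("miRb",), b, "HPb", hp_b, 2),
            ]
        )

    def test_exact_tie_dropped_by_default(self, twin_refset):
        read = ReadRecord(seq="ACGUACGUACGUACGU")
        assert classify_read(read, twin_refset) == []

    def test_fractional_policy_splits_count_equally(self, twin_refset):
        read = ReadRecord(seq="ACGUACGUACGUACGU", count=3)
        params = ClassifyParams(ambiguous_policy="fractional")
        calls = classify_read(read, twin_refset, params)
        assert sorted(c.group_name for c in calls) == ["miRa", "miRb"]
        assert all(c.count == pytest.approx(1.5) for c in calls)

    def test_minimal_truncation_wins_over_deeper_match(self, twin_refset):
        # 17-nt read matching miRa over 17 (tr=4) and miRb over 16 (tr=5)
        read = ReadRecord(seq="ACGUACGUACGUACGUA")
        (c,) = classify_read(read, twin_refset)
        assert c.group_name == "miRa" and c.tr == 4

    def test_tie_counted_in_library_stats(self, twin_refset):
        reads = [ReadRecord(seq="ACGUACGUACGUACGU", count=2)]
        _, stats = classify_library(reads, twin_refset)
        assert stats.ambiguous_dropped == 2
        assert stats.assigned == stats.unassigned == 0


class TestOracleEquivalence:
    def test_random_reads_match_exhaustive_decomposition(self):
        """1000 random (mature, read) trials agree with the split-enumeration
        oracle on assignment, truncation and tail."""
        rng = np.random.default_rng(42)
        params = ClassifyParams()
        for _ in range(1000):
            mature = "".join(rng.choice(BASES, size=21))
            hairpin = "GG" + mature + "".join(rng.choice(BASES, size=10))
            refset = ReferenceSet(
                refs=[MiRNARef("miRx", ("miRx",), mature, "HP", hairpin, 2)]
            )
            if rng.random() < 0.5:
                read_seq = "".join(rng.choice(BASES, size=int(rng.integers(1, 31))))
            else:  # reads derived from the mature: decomposition cases
                tr = int(rng.integers(0, 11))
                ta = int(rng.integers(0, 11))
                read_seq = mature[: 21 - tr] + "".join(rng.choice(BASES, size=ta))
                if not read_seq:
                    continue
            got = classify_read(ReadRecord(seq=read_seq), refset, params)
            want = oracle_classify(read_seq, refset, params)
            got_t = sorted((c.tr, c.group_name, c.tail_seq) for c in got)
            assert got_t == want, f"read={read_seq} mature={mature}"


class TestLibraryAggregation:
    def test_identical_reads_aggregate_counts(self, mini_refset):
        reads = [ReadRecord(seq=MATURE_T, count=3), ReadRecord(seq=MATURE_T, count=2)]
        calls, stats = classify_library(reads, mini_refset)
        assert len(calls) == 1 and calls[0].count == 5
        assert stats.assigned == 5

    def test_empty_stream_zero_stats(self, mini_refset):
        calls, stats = classify_library([], mini_refset)
        assert calls == [] and stats.total == 0

    def test_conservation_of_counts(self, refset):
        rng = np.random.default_rng(7)
        reads = []
        for _ in range(300):
            n = int(rng.integers(10, 32))
            reads.append(
                ReadRecord(seq="".join(rng.choice(BASES, size=n)),
                           count=int(rng.integers(1, 5)))
            )
        for ref in list(refset)[:3]:
            reads.append(ReadRecord(seq=ref.mature_seq, count=10))
        _, stats = classify_library(reads, refset)
        assert (
            stats.assigned + stats.unassigned + stats.ambiguous_dropped
            + stats.length_filtered
            == pytest.approx(stats.total)
        )
        assert stats.assigned >= 30

    def test_order_invariance(self, refset):
        rng = np.random.default_rng(11)
        reads = []
        for ref in refset:
            for tr in (0, 1, 2):
                reads.append(ReadRecord(seq=ref.mature_seq[: len(ref.mature_seq) - tr]))
                reads.append(ReadRecord(seq=ref.mature_seq + "UU"))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        calls_a, _ = classify_library(reads, refset)
        calls_b, _ = classify_library(shuffled, refset)
        assert calls_a == calls_b

    def test_raising_caps_never_decreases_assigned(self, mini_refset):
        reads = [
            ReadRecord(seq=MATURE_T[: 21 - tr] + "U" * ta)
            for tr in range(0, 8)
            for ta in range(0, 10)
        ]
        prev = -1.0
        for cap in (2, 4, 6, 8, 10):
            _, stats = classify_library(
                reads, mini_refset,
                ClassifyParams(max_tr=cap, max_ta=cap, min_len=10),
            )
            assert stats.assigned >= prev
            prev = stats.assigned

    def test_length_filter_applied(self, mini_refset):
        reads = [ReadRecord(seq=MATURE_T[:14]), ReadRecord(seq=MATURE_T + "U" * 12)]
        _, stats = classify_library(reads, mini_refset)
        assert stats.length_filtered == 2


class TestIO:
    def test_fastq_and_collapsed_fasta_roundtrip(self, tmp_path, mini_refset):
        fq = tmp_path / "reads.fastq"
        fq.write_text(
            "@r1\n" + MATURE_T.replace("U", "T") + "\n+\n" + "I" * 21 + "\n"
        )
        fa = tmp_path / "reads.fa"
        fa.write_text(">r1_x5\n" + MATURE_T.replace("U", "T") + "\n")
        (rq,) = list(read_fastq(fq))
        (rc,) = list(read_collapsed_fasta(fa))
        assert rq.seq == rc.seq == MATURE_T
        assert rq.count == 1 and rc.count == 5
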