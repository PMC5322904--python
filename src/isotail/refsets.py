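"""miRNA reference handling: mature + hairpin sequences with templated 3' context.

A mature miRNA is frequently encoded by several loci producing an identical
mature sequence (e.g. miR165a and miR165b in Arabidopsis).  For 3'-end isoform
analysis such loci are indistinguishable at the read level, so identical mature
sequences are collapsed into a single named group ("miR165ab").  Each group
keeps one hairpin context so that read bases extending past the mature 3' end
can be split into genome-templated extension and genuinely non-templated tail.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_RNA_OK = re.compile(r"^[ACGU]+$")

__all__ = [
    "MiRNARef",
    "ReferenceSet",
    "ReferenceError",
    "normalize_rna",
    "load_references",
    "downstream_context",
    "collapse_group_name",
    "write_references",
]


class ReferenceError(ValueError):
    """Raised when a miRNA reference file violates the loading contract."""


def normalize_rna(seq: str, *, where: str = "sequence") -> str:
    """Uppercase and convert T->U; reject non-ACGU(T) characters."""
    s = str(seq).upper().replace("T", "U")
    if not _RNA_OK.match(s):
        bad = sorted(set(s) - set("ACGU"))
        raise ReferenceError(f"non-ACGUT characters {bad} in {where}")
    return s


@dataclass(frozen=True)
class MiRNARef:
    """One collapsed mature-miRNA group together with its hairpin context.

    ``downstream_template`` holds the hairpin bases immediately 3' of the
    mature end; it is empty when the mature sequence reaches the hairpin
    boundary.
    """

    group_name: str
    member_names: tuple[str, ...]
    mature_seq: str
    hairpin_name: str
    hairpin_seq: str
    mature_offset: int

    def __post_init__(self) -> None:
        end = self.mature_offset + len(self.mature_seq)
        if self.hairpin_seq[self.mature_offset:end] != self.mature_seq:
            raise ReferenceError(
                f"{self.group_name}: mature sequence does not occur in hairpin "
                f"{self.hairpin_name} at offset {self.mature_offset}"
            )

    @property
    def downstream_template(self) -> str:
        return self.hairpin_seq[self.mature_offset + len(self.mature_seq):]


@dataclass
class ReferenceSet:
    """Collection of collapsed miRNA groups with a 5'-prefix lookup index."""

    refs: list[MiRNARef]
    _prefix_index: dict[int, dict[str, list[MiRNARef]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        names = [r.group_name for r in self.refs]
        if len(set(names)) != len(names):
            raise ReferenceError("duplicate group names in ReferenceSet")
        seqs = [r.mature_seq for r in self.refs]
        if len(set(seqs)) != len(seqs):
            raise ReferenceError(
                "two groups share an identical mature sequence; "
                "they should have been collapsed"
            )

    def __iter__(self):
        return iter(self.refs)

    def __len__(self) -> int:
        return len(self.refs)

    def group(self, name: str) -> MiRNARef:
        for r in self.refs:
            if r.group_name == name:
                return r
        raise KeyError(name)

    @property
    def group_names(self) -> list[str]:
        return [r.group_name for r in self.refs]

    def prefix_index(self, k: int) -> dict[str, list[MiRNARef]]:
        """5' k-mer -> candidate refs; k is the minimum assignable length."""
        if k not in self._prefix_index:
            idx: dict[str, list[MiRNARef]] = {}
            for r in self.refs:
                idx.setdefault(r.mature_seq[:k], []).append(r)
            self._prefix_index[k] = idx
        return self._prefix_index[k]

    def candidates(self, read_seq: str, k: int) -> list[MiRNARef]:
        return self.prefix_index(k).get(read_seq[:k], [])


def collapse_group_name(member_names: list[str]) -> str:
    """Collapse locus names sharing a stem into stem + joined suffixes.

    miR165a + miR165b -> "miR165ab".  Names without a common stem are joined
    with "/" so nothing is ever silently lost.
    """
    if len(member_names) == 1:
        return member_names[0]
    ordered = sorted(member_names)
    m = [re.match(r"^(.*?)([a-z]\d*\*?)$", n) for n in ordered]
    if all(m) and len({x.group(1) for x in m}) == 1:  # type: ignore[union-attr]
        stem = m[0].group(1)  # type: ignore[union-attr]
        return stem + "".join(x.group(2) for x in m)  # type: ignore[union-attr]
    return "/".join(ordered)


def _read_fasta(path: str | Path, what: str) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ReferenceError(f"duplicate record ID {rec.id!r} in {what} FASTA")
        records[rec.id] = normalize_rna(str(rec.seq), where=f"{what} record {rec.id!r}")
    if not records:
        raise ReferenceError(f"no records found in {what} FASTA {path}")
    return records


def _read_offsets(path: str | Path) -> dict[str, tuple[str, int]]:
    table: dict[str, tuple[str, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"mature_name", "hairpin_name", "offset_0based"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ReferenceError(
                f"offsets table must have columns {sorted(required)}"
            )
        for row in reader:
            table[row["mature_name"]] = (
                row["hairpin_name"],
                int(row["offset_0based"]),
            )
    return table


def _hairpin_for(name: str, hairpins: dict[str, str]) -> str:
    """miRBase pairs mature 'miR165a' with hairpin 'MIR165a'/'mir165a'."""
    if name in hairpins:
        return name
    lowered = {h.lower(): h for h in hairpins}
    for cand in (name.lower(), name.lower().replace("mir", "mir")):
        if cand in lowered:
            return lowered[cand]
    raise ReferenceError(f"no hairpin record found for mature {name!r}")


def load_references(
    mature_fasta: str | Path,
    hairpin_fasta: str | Path,
    offsets: str | Path | None = None,
    group_names: dict[frozenset, str] | None = None,
) -> ReferenceSet:
    """Load mature + hairpin FASTA, collapse identical matures into groups.

    Every mature record must either appear in the (optional) offsets table or
    be locatable as an exact, unique substring of its same-named hairpin.
    ``group_names`` optionally overrides the automatic collapsed names, keyed
    by frozenset of member locus names.
    """
    matures = _read_fasta(mature_fasta, "mature")
    hairpins = _read_fasta(hairpin_fasta, "hairpin")
    offset_table = _read_offsets(offsets) if offsets else {}

    located: dict[str, tuple[str, int]] = {}
    for name, seq in matures.items():
        if name in offset_table:
            hp_name, off = offset_table[name]
            if hp_name not in hairpins:
                raise ReferenceError(
                    f"offsets table names unknown hairpin {hp_name!r} for {name!r}"
                )
            if hairpins[hp_name][off:off + len(seq)] != seq:
                raise ReferenceError(
                    f"mature {name!r} does not match hairpin {hp_name!r} "
                    f"at offset {off}"
                )
            located[name] = (hp_name, off)
            continue
        hp_name = _hairpin_for(name, hairpins)
        hp = hairpins[hp_name]
        first = hp.find(seq)
        if first < 0:
            raise ReferenceError(
                f"mature {name!r} not found in its hairpin {hp_name!r}"
            )
        if hp.find(seq, first + 1) >= 0:
            raise ReferenceError(
                f"mature {name!r} occurs more than once in hairpin {hp_name!r}; "
                "an explicit offsets table is required"
            )
        located[name] = (hp_name, first)

    # collapse identical mature sequences
    by_seq: dict[str, list[str]] = {}
    for name in sorted(matures):
        by_seq.setdefault(matures[name], []).append(name)

    refs = []
    for seq, members in sorted(by_seq.items(), key=lambda kv: sorted(kv[1])[0]):
        members = sorted(members)
        override = (group_names or {}).get(frozenset(members))
        gname = override or collapse_group_name(members)
        # representative hairpin context: first member's hairpin
        hp_name, off = located[members[0]]
        refs.append(
            MiRNARef(
                group_name=gname,
                member_names=tuple(members),
                mature_seq=seq,
                hairpin_name=hp_name,
                hairpin_seq=hairpins[hp_name],
                mature_offset=off,
            )
        )
    return ReferenceSet(refs=refs)


def downstream_context(ref: MiRNARef, n: int) -> str:
    """Up to ``n`` hairpin bases immediately 3' of the mature end."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return ref.downstream_template[:n]


def write_references(
    refset: ReferenceSet,
    mature_fasta: str | Path,
    hairpin_fasta: str | Path,
    offsets: str | Path,
) -> None:
    """Serialize a ReferenceSet back to mature/hairpin FASTA + offsets TSV.

    Round-trips with :func:`load_references` (locus-level records restored).
    """
    with open(mature_fasta, "w") as mf:
        for ref in refset:
            for member in ref.member_names:
                mf.write(f">{member}\n{ref.mature_seq}\n")
    seen: set[str] = set()
    with open(hairpin_fasta, "w") as hf:
        for ref in refset:
            if ref.hairpin_name not in seen:
                seen.add(ref.hairpin_name)
                hf.write(f">{ref.hairpin_name}\n{ref.hairpin_seq}\n")
    with open(offsets, "w", newline="") as of:
        writer = csv.writer(of, delimiter="\t", lineterminator="\n")
        writer.writerow(["mature_name", "hairpin_name", "offset_0based"])
        for ref in refset:
            for member in ref.member_names:
                writer.writerow([member, ref.hairpin_name, ref.mature_offset])
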