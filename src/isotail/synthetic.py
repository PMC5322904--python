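"""Synthetic small-RNA library generator with per-read ground truth.

The generator emulates the statistical structure of seedling small-RNA
libraries as seen through a 3'-isoform lens: each miRNA group gets an
abundance weight and a four-category mixture (FL / TR-only / TA-only /
TR+TA); truncation and tail lengths follow truncated geometric laws
(short offsets dominate, as in real truncation-tailing matrices); tails are
U-biased, reflecting HESO1/URT1 uridylation; a configurable fraction of
reads is background (random hairpin fragments); and sequencing error is a
per-base substitution process.  Every emitted read is paired with a manifest
row recording its ground truth, so the classifier can be scored read-by-read.

The preset profiles encode the qualitative genotype contrasts the analysis
is built to detect: wild-type-like libraries are dominated by full-length
methylated miRNAs; hen1-like libraries (no 2'-O-methylation) show rampant
truncation and uridylation; hen1 sdn-like libraries lose much of that
truncation (SDN exonucleases removed); hen1 heso1-like libraries shift
TR+TA mass toward TR-only (the uridylyl transferase removed); and
ago10-oe-like libraries elevate truncation of miR165/6 specifically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import FL, TA_ONLY, TR_ONLY, TR_TA, ReadRecord, category_of
from .refsets import MiRNARef, ReferenceSet

__all__ = [
    "CategoryMix",
    "GenotypeProfile",
    "preset_profiles",
    "demo_reference",
    "generate_library",
    "recovery_report",
    "write_reads_fastq",
    "write_reads_collapsed_fasta",
]

_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class CategoryMix:
    p_FL: float
    p_TR: float
    p_TA: float
    p_TRTA: float

    def __post_init__(self):
        s = self.p_FL + self.p_TR + self.p_TA + self.p_TRTA
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"category probabilities sum to {s}, not 1")
        if min(self.p_FL, self.p_TR, self.p_TA, self.p_TRTA) < 0:
            raise ValueError("negative category probability")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_FL, self.p_TR, self.p_TA, self.p_TRTA)


@dataclass(frozen=True)
class GenotypeProfile:
    """Study conditions for one simulated genotype.

    ``abundance`` maps group name -> relative weight; ``default_mix`` applies
    to every group unless overridden in ``group_mix``.  ``q_tr``/``q_ta`` are
    the geometric decay parameters of the truncation/tail length laws
    (P(len = k) proportional to q**(k-1) over 1..max).  ``tail_probs`` is the
    per-base tail composition, U-biased by default.  ``collision_control``
    rejects tail first-bases equal to the templated downstream base so every
    generated read has an unambiguous ground-truth decomposition.
    """

    name: str
    abundance: dict[str, float]
    default_mix: CategoryMix
    group_mix: dict[str, CategoryMix] = field(default_factory=dict)
    q_tr: float = 0.45
    q_ta: float = 0.45
    max_tr: int = 6
    max_ta: int = 8
    tail_probs: dict[str, float] = field(
        default_factory=lambda: {"U": 0.9, "A": 0.1 / 3, "C": 0.1 / 3, "G": 0.1 / 3}
    )
    background_fraction: float = 0.0
    error_rate: float = 0.0
    library_size: int = 50_000
    collision_control: bool = True

    def __post_init__(self):
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        s = sum(self.tail_probs.get(b, 0.0) for b in _BASES)
        if abs(s - 1.0) > 1e-9:
            raise ValueError("tail base probabilities must sum to 1")
        if any(w < 0 for w in self.abundance.values()) or not self.abundance:
            raise ValueError("abundance weights must be non-empty and >= 0")

    def mix_for(self, group: str) -> CategoryMix:
        return self.group_mix.get(group, self.default_mix)


def preset_profiles(
    group_names: list[str] | None = None,
    library_size: int = 50_000,
    error_rate: float = 0.0,
    background_fraction: float = 0.0,
) -> dict[str, GenotypeProfile]:
    """Named genotype profiles differing only in their category mixtures.

    Groups matching 'miR165'/'miR166' receive the miR165/6-specific overrides
    in the ago10_oe_like profile.
    """
    if group_names is None:
        group_names = demo_reference().group_names
    # skewed but fixed abundance: realistic libraries are dominated by a few
    # miRNAs; weights decay geometrically over the sorted group list
    abundance = {g: 0.75 ** i for i, g in enumerate(sorted(group_names))}
    common = dict(
        abundance=abundance,
        library_size=library_size,
        error_rate=error_rate,
        background_fraction=background_fraction,
    )
    wt = CategoryMix(0.94, 0.02, 0.03, 0.01)
    hen1 = CategoryMix(0.35, 0.20, 0.15, 0.30)
    hen1_sdn = CategoryMix(0.60, 0.08, 0.20, 0.12)
    hen1_heso1 = CategoryMix(0.35, 0.40, 0.08, 0.17)
    mir1656 = {
        g: CategoryMix(0.70, 0.15, 0.03, 0.12)
        for g in group_names
        if g.startswith(("miR165", "miR166"))
    }
    return {
        "wildtype_like": GenotypeProfile(
            name="wildtype_like", default_mix=wt, **common
        ),
        "hen1_like": GenotypeProfile(name="hen1_like", default_mix=hen1, **common),
        "hen1_sdn_like": GenotypeProfile(
            name="hen1_sdn_like", default_mix=hen1_sdn, **common
        ),
        "hen1_heso1_like": GenotypeProfile(
            name="hen1_heso1_like", default_mix=hen1_heso1, **common
        ),
        "ago10_oe_like": GenotypeProfile(
            name="ago10_oe_like", default_mix=wt, group_mix=mir1656, **common
        ),
    }


# ---------------------------------------------------------------------------
# demo reference (synthetic)


def demo_reference(n_extra: int = 6, seed: int = 165166) -> ReferenceSet:
    """A small synthetic miRNA reference for simulations and tests.

    Sequences are random 21-22-mers embedded in random 90-nt hairpins; they
    are NOT real miRNA sequences, only named after the field's conventions.
    Two locus pairs (miR165a/b, miR167a/b) share identical mature sequences
    to exercise group collapsing.  First-12-nt prefixes are unique across
    groups so 5'-anchored assignment is unambiguous.
    """
    rng = np.random.default_rng(seed)
    base_names = ["miR165ab", "miR166a", "miR167ab", "miR168a", "miR173a"]
    extra = [f"miR9{i:02d}a" for i in range(n_extra)]
    members = {
        "miR165ab": ("miR165a", "miR165b"),
        "miR167ab": ("miR167a", "miR167b"),
    }
    refs: list[MiRNARef] = []
    prefixes: set[str] = set()
    for name in base_names + extra:
        while True:
            length = int(rng.integers(21, 23))
            mature = "".join(rng.choice(_BASES, size=length))
            if mature[:12] not in prefixes:
                prefixes.add(mature[:12])
                break
        offset = int(rng.integers(5, 20))
        tail_len = 90 - offset - length
        upstream = "".join(rng.choice(_BASES, size=offset))
        downstream = "".join(rng.choice(_BASES, size=tail_len))
        hairpin = upstream + mature + downstream
        # a second accidental occurrence would make the context ambiguous
        assert hairpin.count(mature) == 1
        refs.append(
            MiRNARef(
                group_name=name,
                member_names=members.get(name, (name,)),
                mature_seq=mature,
                hairpin_name="MIR" + name[3:],
                hairpin_seq=hairpin,
                mature_offset=offset,
            )
        )
    return ReferenceSet(refs=refs)


# ---------------------------------------------------------------------------
# generation


def _derive_rng(root_seed: int, library_id: str) -> np.random.Generator:
    """Stable per-library stream: hash of (root seed, library id)."""
    digest = hashlib.sha256(f"{root_seed}:{library_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _trunc_geometric(rng: np.random.Generator, q: float, kmax: int) -> int:
    probs = np.array([q ** (k - 1) for k in range(1, kmax + 1)])
    probs /= probs.sum()
    return int(rng.choice(np.arange(1, kmax + 1), p=probs))


def _draw_tail(
    rng: np.random.Generator,
    length: int,
    tail_probs: dict[str, float],
    forbidden_first: str | None,
) -> str:
    probs = np.array([tail_probs.get(b, 0.0) for b in _BASES])
    tail = list(rng.choice(_BASES, size=length, p=probs))
    if forbidden_first is not None and tail and tail[0] == forbidden_first:
        # renormalize over the remaining bases for the first position
        mask = np.array([b != forbidden_first for b in _BASES])
        p = probs * mask
        if p.sum() <= 0:
            p = mask.astype(float)  # degenerate tail law: fall back to uniform
        p = p / p.sum()
        tail[0] = str(rng.choice(np.array(_BASES), p=p))
    return "".join(tail)


def generate_library(
    profile: GenotypeProfile,
    refset: ReferenceSet,
    library_id: str,
    seed: int,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Generate one library of reads plus its ground-truth manifest.

    Reads are mature[: L - tr] + tail with per-base substitution errors;
    background reads are random 15-30 nt hairpin fragments.  Deterministic
    for a given (seed, library_id).
    """
    missing = set(profile.abundance) - set(refset.group_names)
    if missing:
        raise ValueError(f"profile names unknown groups: {sorted(missing)}")
    for ref in refset:
        if ref.group_name in profile.abundance and profile.max_tr >= len(ref.mature_seq) - 1:
            raise ValueError(
                f"max_tr {profile.max_tr} too deep for {ref.group_name} "
                f"({len(ref.mature_seq)} nt)"
            )
    rng = _derive_rng(seed, library_id)
    groups = sorted(g for g in profile.abundance if profile.abundance[g] > 0)
    weights = np.array([profile.abundance[g] for g in groups], dtype=float)
    weights /= weights.sum()
    by_group = {r.group_name: r for r in refset}
    cat_names = (FL, TR_ONLY, TA_ONLY, TR_TA)

    reads: list[ReadRecord] = []
    rows: list[dict] = []
    n_background = int(round(profile.background_fraction * profile.library_size))
    n_mirna = profile.library_size - n_background

    group_draws = rng.choice(len(groups), size=n_mirna, p=weights)
    for gi in group_draws:
        ref = by_group[groups[gi]]
        mix = profile.mix_for(ref.group_name)
        cat = cat_names[int(rng.choice(4, p=np.array(mix.as_tuple())))]
        tr = (
            _trunc_geometric(rng, profile.q_tr, profile.max_tr)
            if cat in (TR_ONLY, TR_TA)
            else 0
        )
        ta = (
            _trunc_geometric(rng, profile.q_ta, profile.max_ta)
            if cat in (TA_ONLY, TR_TA)
            else 0
        )
        body = ref.mature_seq[: len(ref.mature_seq) - tr]
        # the base the hairpin would put right after the read body: for an
        # untruncated read that is the first downstream-template base, for a
        # truncated read it is the mature base that was just removed
        if profile.collision_control and ta > 0:
            nxt = (ref.mature_seq + ref.downstream_template)[len(body): len(body) + 1]
            forbidden = nxt or None
        else:
            forbidden = None
        tail = _draw_tail(rng, ta, profile.tail_probs, forbidden)
        true_seq = body + tail
        seq, err_pos = _apply_errors(rng, true_seq, profile.error_rate)
        reads.append(ReadRecord(seq=seq))
        rows.append(
            {
                "library_id": library_id,
                "read_index": len(rows),
                "seq": seq,
                "true_group": ref.group_name,
                "true_tr": tr,
                "true_ta": ta,
                "true_tail": tail,
                "true_category": category_of(tr, ta),
                "is_background": False,
                "error_positions": ",".join(map(str, err_pos)),
            }
        )
    for _ in range(n_background):
        ref = by_group[groups[int(rng.choice(len(groups), p=weights))]]
        hp = ref.hairpin_seq
        length = int(rng.integers(15, 31))
        start = int(rng.integers(0, max(1, len(hp) - length + 1)))
        true_seq = hp[start: start + length]
        seq, err_pos = _apply_errors(rng, true_seq, profile.error_rate)
        reads.append(ReadRecord(seq=seq))
        rows.append(
            {
                "library_id": library_id,
                "read_index": len(rows),
                "seq": seq,
                "true_group": "",
                "true_tr": -1,
                "true_ta": -1,
                "true_tail": "",
                "true_category": "BACKGROUND",
                "is_background": True,
                "error_positions": ",".join(map(str, err_pos)),
            }
        )
    manifest = pd.DataFrame(rows)
    assert len(manifest) == len(reads)
    return reads, manifest


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    chars = list(seq)
    positions = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in positions:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = str(rng.choice(alternatives))
    return "".join(chars), [int(i) for i in positions]


# ---------------------------------------------------------------------------
# scoring


def recovery_report(
    manifest: pd.DataFrame,
    refset: ReferenceSet,
    params=None,
) -> dict:
    """Score the classifier read-by-read against the generator's ground truth.

    Returns a confusion table (true category x called category, background
    and UNASSIGNED included), the max absolute per-group composition error,
    and the fraction of background reads that were (mis)assigned.
    """
    from .classify import ClassifyParams, classify_read

    params = params or ClassifyParams()
    called = []
    for seq in manifest["seq"]:
        if not (params.min_len <= len(seq) <= params.max_len):
            called.append("FILTERED")
            continue
        calls = classify_read(ReadRecord(seq=seq), refset, params)
        if not calls:
            called.append("UNASSIGNED")
        elif len(calls) > 1:
            called.append("AMBIGUOUS")
        else:
            called.append(calls[0].category)
    df = manifest.assign(called_category=called)
    confusion = pd.crosstab(df["true_category"], df["called_category"])

    mirna = df[~df["is_background"]]
    max_err = 0.0
    for group, sub in mirna.groupby("true_group"):
        true_p = sub["true_category"].value_counts(normalize=True)
        assigned = sub[sub["called_category"].isin(["FL", "TR_ONLY", "TA_ONLY", "TR_TA"])]
        # composition among assigned reads, mirroring what compose() reports
        called_p = (
            assigned["called_category"].value_counts(normalize=True)
            if len(assigned)
            else pd.Series(dtype=float)
        )
        for cat in ("FL", "TR_ONLY", "TA_ONLY", "TR_TA"):
            err = abs(true_p.get(cat, 0.0) - called_p.get(cat, 0.0))
            max_err = max(max_err, float(err))
    bg = df[df["is_background"]]
    bg_assigned = (
        float(
            bg["called_category"].isin(["FL", "TR_ONLY", "TA_ONLY", "TR_TA"]).mean()
        )
        if len(bg)
        else 0.0
    )
    return {
        "confusion": confusion,
        "max_composition_error": max_err,
        "background_assigned_fraction": bg_assigned,
        "per_read": df,
    }


# ---------------------------------------------------------------------------
# output formats


def write_reads_fastq(reads: list[ReadRecord], path) -> None:
    """FASTQ with constant quality 'I'; collapsed counts are expanded."""
    with open(path, "w") as fh:
        i = 0
        for r in reads:
            for _ in range(int(round(r.count))):
                fh.write(f"@read{i}\n{r.seq.replace('U', 'T')}\n+\n{'I' * len(r.seq)}\n")
                i += 1


def write_reads_collapsed_fasta(reads: list[ReadRecord], path) -> None:
    agg: dict[str, float] = {}
    for r in reads:
        agg[r.seq] = agg.get(r.seq, 0.0) + r.count
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(sorted(agg.items())):
            fh.write(f">read{i}_x{int(round(n))}\n{seq.replace('U', 'T')}\n")
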