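"""Normalized isoform quantities: RPM, category compositions, ratios, matrices.

All tables are pandas DataFrames so downstream comparisons and exports are
plain dataframe operations.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import CATEGORIES, FL, TA_ONLY, TR_ONLY, TR_TA, IsoformCall

__all__ = [
    "rpm",
    "compose",
    "truncation_ratio",
    "tronly_ratio",
    "abundance_filter",
    "binding_fraction",
    "build_matrix",
    "percent_table",
    "u_fraction",
]

_CAT_COLS = {FL: "n_FL", TR_ONLY: "n_TR", TA_ONLY: "n_TA", TR_TA: "n_TRTA"}


def rpm(count: float, library_total: float) -> float:
    """Reads per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    return count / library_total * 1e6


def compose(
    calls: Iterable[IsoformCall],
    library_total: float,
    library_id: str = "lib",
) -> pd.DataFrame:
    """Per-group four-category composition for one library.

    Returns one row per group with counts, total, rpm_total and the four
    proportions.  Groups with zero reads simply do not appear.
    ``library_total`` is the RPM denominator (reads passing the length
    filter by default; see LibraryStats.denominator).
    """
    rows: dict[str, dict[str, float]] = {}
    for c in calls:
        row = rows.setdefault(
            c.group_name, {col: 0.0 for col in _CAT_COLS.values()}
        )
        row[_CAT_COLS[c.category]] += c.count
    records = []
    for group in sorted(rows):
        r = rows[group]
        total = sum(r.values())
        if total == 0:
            continue
        records.append(
            {
                "library_id": library_id,
                "group_name": group,
                **r,
                "total": total,
                "rpm_total": rpm(total, library_total),
                "p_FL": r["n_FL"] / total,
                "p_TR": r["n_TR"] / total,
                "p_TA": r["n_TA"] / total,
                "p_TRTA": r["n_TRTA"] / total,
            }
        )
    cols = [
        "library_id", "group_name", "n_FL", "n_TR", "n_TA", "n_TRTA",
        "total", "rpm_total", "p_FL", "p_TR", "p_TA", "p_TRTA",
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def truncation_ratio(row) -> float:
    """Proportion of truncated species (TR-only + TR+TA) among all reads."""
    total = row["total"]
    if total <= 0:
        return float("nan")
    return (row["n_TR"] + row["n_TRTA"]) / total


def tronly_ratio(row) -> float:
    """Proportion of TR-only species among all reads of the group."""
    total = row["total"]
    if total <= 0:
        return float("nan")
    return row["n_TR"] / total


def abundance_filter(
    tables: pd.DataFrame,
    threshold_rpm: float = 10.0,
    mode: str = "all_libraries",
) -> list[str]:
    """Groups with rpm_total > threshold in every (or any) library.

    ``tables`` is a concatenation of compose() outputs across libraries.
    A group absent from a library has RPM 0 there, so under 'all_libraries'
    it is dropped unless present and abundant everywhere.
    """
    if mode not in ("all_libraries", "any_library"):
        raise ValueError(f"unknown mode {mode!r}")
    libs = tables["library_id"].unique()
    wide = tables.pivot_table(
        index="group_name", columns="library_id", values="rpm_total", fill_value=0.0
    ).reindex(columns=libs, fill_value=0.0)
    passing = wide.gt(threshold_rpm)
    keep = passing.all(axis=1) if mode == "all_libraries" else passing.any(axis=1)
    return sorted(wide.index[keep])


def binding_fraction(calls: Iterable[IsoformCall]) -> pd.Series:
    """Per-group share of all assigned miRNA reads, as a percentage.

    Used for Argonaute-IP libraries: a miRNA's binding to the precipitated
    AGO is quantified as its reads over all annotated-miRNA reads x 100.
    """
    totals: dict[str, float] = {}
    for c in calls:
        totals[c.group_name] = totals.get(c.group_name, 0.0) + c.count
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no assigned reads: binding fractions undefined")
    return pd.Series(
        {g: totals[g] / grand * 100.0 for g in sorted(totals)}, name="percent"
    )


def build_matrix(
    calls: Iterable[IsoformCall],
    group_name: str,
    max_tr: int = 8,
    max_ta: int = 8,
) -> pd.DataFrame:
    """Truncation-tailing matrix for one group in one library.

    Entry [tr, ta] is the proportion of the group's reads with that many
    nucleotides truncated (rows) and added (columns); entries sum to 1.
    """
    grid = np.zeros((max_tr + 1, max_ta + 1))
    total = 0.0
    for c in calls:
        if c.group_name != group_name:
            continue
        total += c.count
        grid[c.tr, c.ta] += c.count
    if total <= 0:
        raise ValueError(f"group {group_name!r} has no reads")
    grid /= total
    return pd.DataFrame(
        grid,
        index=pd.Index(range(max_tr + 1), name="tr"),
        columns=pd.Index(range(max_ta + 1), name="ta"),
    )


def matrix_long(matrix: pd.DataFrame, library_id: str, group_name: str) -> pd.DataFrame:
    """Long-form (library, group, tr, ta, proportion) export of a matrix."""
    long = matrix.stack().rename("proportion").reset_index()
    long.insert(0, "group_name", group_name)
    long.insert(0, "library_id", library_id)
    return long


def percent_table(counts: Sequence[float]) -> tuple[list[float], float]:
    """Category counts -> percentages at 1-decimal half-up rounding, plus total.

    Matches how printed phenotype-tally tables round: 25.65 -> 25.7.
    """
    total = sum(counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    if total <= 0:
        raise ValueError("sum of counts must be > 0")
    percents = [
        float(
            (Decimal(100) * Decimal(str(c)) / Decimal(str(total))).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for c in counts
    ]
    return percents, total


def u_fraction(calls: Iterable[IsoformCall]) -> float:
    """Fraction of tail nucleotides that are U, across all tailed calls."""
    u = n = 0.0
    for c in calls:
        if c.tail_seq:
            u += c.tail_seq.count("U") * c.count
            n += len(c.tail_seq) * c.count
    return u / n if n else float("nan")


def write_composition_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
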