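"""Cross-library procedures: control subtraction, replicate pooling,
two-group tests with significance stars, and library clustering.

The enzymatic-assay workflow subtracts isoform signal measured in a no-enzyme
(mock) or catalytically dead control reaction from the treatment reaction
before computing truncation ratios, because Argonaute-IP input already carries
a background of truncated species that the enzyme under test did not create.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .classify import IsoformCall

__all__ = [
    "ContrastResult",
    "mock_subtract",
    "tr_vs_fl_ratio",
    "pool_replicates",
    "two_group_test",
    "sum_truncation_test",
    "stars_for",
    "cluster_libraries",
    "bh_adjust",
]

_STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def stars_for(p: float | None) -> str:
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ContrastResult:
    group_name: str
    metric_name: str
    mean_A: float
    mean_B: float
    sd_A: float
    sd_B: float
    n_A: int
    n_B: int
    p_value: float  # NaN when either group has < 2 replicates
    stars: str
    direction: int  # sign of mean_B - mean_A


def mock_subtract(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    columns: Sequence[str] = ("n_FL", "n_TR", "n_TA", "n_TRTA"),
    key: str = "group_name",
) -> pd.DataFrame:
    """Entrywise treatment - control over ``columns``, floored at zero.

    Groups present only in the control contribute nothing (treatment 0 floored
    to 0); groups present only in the treatment keep their values.  Both
    frames must be on the same scale (counts, proportions or RPM).
    """
    t = treatment.set_index(key)
    c = control.set_index(key)
    out = t.copy()
    aligned = c.reindex(t.index).fillna(0.0)
    for col in columns:
        out[col] = np.maximum(t[col] - aligned[col], 0.0)
    return out.reset_index()


def tr_vs_fl_ratio(row) -> float:
    """Ratio of TR-only to FL species; NaN when no FL signal remains."""
    if row["n_FL"] <= 0:
        return float("nan")
    return row["n_TR"] / row["n_FL"]


def pool_replicates(replicates: Iterable[list[IsoformCall]]) -> list[IsoformCall]:
    """Sum call counts across replicates BEFORE any ratio computation.

    Pooling at count level, then forming ratios from the pooled counts, is not
    the same as averaging per-replicate ratios; the low-signal assay tables
    use pooled counts.
    """
    agg: dict[tuple[str, int, str, int], float] = {}
    for calls in replicates:
        for c in calls:
            k = (c.group_name, c.tr, c.tail_seq, c.templated_ext)
            agg[k] = agg.get(k, 0.0) + c.count
    return [
        IsoformCall(group_name=g, tr=tr, tail_seq=tail, count=n, templated_ext=ext)
        for (g, tr, tail, ext), n in sorted(agg.items())
    ]


def two_group_test(
    values_A: Sequence[float],
    values_B: Sequence[float],
    group_name: str = "",
    metric_name: str = "",
    variant: str = "welch",
) -> ContrastResult:
    """Two-sided t-test between per-replicate values of one metric.

    Welch's unequal-variance form by default (robust at n = 2-3 replicates);
    ``variant='student'`` selects the pooled-variance form.  With fewer than
    two replicates in either group the p-value is NaN and stars are empty.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sd_a = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    sd_b = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    if len(a) < 2 or len(b) < 2:
        p = float("nan")
    elif np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        p = 1.0  # all values identical: no evidence of difference
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        p = float(res.pvalue)
    diff = mean_b - mean_a
    return ContrastResult(
        group_name=group_name,
        metric_name=metric_name,
        mean_A=mean_a,
        mean_B=mean_b,
        sd_A=sd_a,
        sd_B=sd_b,
        n_A=len(a),
        n_B=len(b),
        p_value=p,
        stars=stars_for(p),
        direction=int(np.sign(diff)),
    )


def sum_truncation_test(
    tr_A: Sequence[float],
    trta_A: Sequence[float],
    tr_B: Sequence[float],
    trta_B: Sequence[float],
    group_name: str = "",
    variant: str = "welch",
) -> ContrastResult:
    """Test on the per-replicate sum p_TR + p_TRTA (total truncation).

    A genotype can reduce total 3' truncation significantly even when neither
    the TR-only nor the TR+TA component alone passes the threshold.
    """
    a = np.asarray(tr_A, dtype=float) + np.asarray(trta_A, dtype=float)
    b = np.asarray(tr_B, dtype=float) + np.asarray(trta_B, dtype=float)
    return two_group_test(
        a, b, group_name=group_name, metric_name="p_TR+p_TRTA", variant=variant
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional extra column)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))


def cluster_libraries(
    rpm_table: pd.DataFrame,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, str]:
    """Cluster libraries on log-transformed normalized counts.

    ``rpm_table`` is groups x libraries (RPM).  Values are log2(RPM + 1),
    distances Euclidean between library columns, agglomeration by the chosen
    linkage (average by default).  Returns the square distance matrix and the
    dendrogram as a Newick string.
    """
    if rpm_table.shape[1] < 2:
        raise ValueError("at least two libraries are required for clustering")
    if linkage_method not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    logged = np.log2(rpm_table.to_numpy(dtype=float).T + 1.0)
    dists = pdist(logged, metric="euclidean")
    z = hierarchy.linkage(dists, method=linkage_method)
    labels = list(rpm_table.columns)
    dist_df = pd.DataFrame(squareform(dists), index=labels, columns=labels)
    tree = TreeNode.from_linkage_matrix(z, labels)
    newick = str(tree).strip()
    return dist_df, newick
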