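"""Pairwise differential-expression counting and multi-group ANOVA.

Tests run on observed (never imputed) log2 values with a minimum per-group
observation count.  Significance requires both a fold change above the
threshold (|delta log2| > log2(threshold)) and a Benjamini-Hochberg
adjusted p-value below alpha; thresholding is always applied after
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = [
    "DEPResult",
    "DEPCountMatrix",
    "pairwise_dep",
    "dep_table",
    "dep_count_matrix",
    "anova_across_groups",
]


@dataclass(frozen=True)
class DEPResult:
    """One significant protein from a two-group comparison (A vs B)."""

    protein_id: str
    log2_fold_change: float  # mean(A) - mean(B) on the log2 scale
    p_value: float
    adjusted_p: float
    direction: str  # "up" or "down" in group A

    def __post_init__(self) -> None:
        if self.adjusted_p + 1e-15 < self.p_value:
            raise ValueError("adjusted p must be >= raw p")
        expected = "up" if self.log2_fold_change > 0 else "down"
        if self.direction != expected:
            raise ValueError("direction inconsistent with fold-change sign")


@dataclass
class DEPCountMatrix:
    """Up/down DEP counts for every ordered group pair."""

    groups: list[str]
    counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def count(self, a: str, b: str, direction: str = "up") -> int:
        up, down = self.counts[(a, b)]
        if direction == "up":
            return up
        if direction == "down":
            return down
        raise ValueError("direction must be 'up' or 'down'")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "up": up, "down": down}
            for (a, b), (up, down) in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def dep_table(
    matrix: AbundanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_obs: int = 3,
) -> pd.DataFrame:
    """Welch t-test per protein (A vs B) with BH adjustment across proteins.

    Returns the full table for proteins with >= ``min_obs`` observed values
    per group; proteins with fewer are excluded (listed in
    ``frame.attrs['excluded']``).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub_a = matrix.subset_samples(list(group_a)).values
    sub_b = matrix.subset_samples(list(group_b)).values
    rows, excluded = [], []
    for j, pid in enumerate(matrix.protein_ids):
        a = sub_a[:, j]
        a = a[~np.isnan(a)]
        b = sub_b[:, j]
        b = b[~np.isnan(b)]
        if len(a) < min_obs or len(b) < min_obs:
            excluded.append(pid)
            continue
        stat = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "protein_id": pid,
                "log2_fold_change": float(a.mean() - b.mean()),
                "p_value": float(stat.pvalue),
            }
        )
    frame = pd.DataFrame(rows, columns=["protein_id", "log2_fold_change", "p_value"])
    if len(frame):
        frame["adjusted_p"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["adjusted_p"] = pd.Series(dtype=float)
    frame.attrs["excluded"] = excluded
    return frame


def pairwise_dep(
    matrix: AbundanceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 4.0,
    alpha: float = 0.01,
    min_obs: int = 3,
) -> list[DEPResult]:
    """Proteins passing fold change > ``fc_threshold`` and adjusted p < ``alpha``.

    Fold change is evaluated on the log2 scale: |delta log2| > log2(threshold).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1 (linear-scale fold change)")
    table = dep_table(matrix, group_a, group_b, min_obs=min_obs)
    log2_cut = np.log2(fc_threshold)
    hits = table[(table["log2_fold_change"].abs() > log2_cut) & (table["adjusted_p"] < alpha)]
    return [
        DEPResult(
            protein_id=r.protein_id,
            log2_fold_change=r.log2_fold_change,
            p_value=r.p_value,
            adjusted_p=r.adjusted_p,
            direction="up" if r.log2_fold_change > 0 else "down",
        )
        for r in hits.itertuples(index=False)
    ]


def dep_count_matrix(
    matrix: AbundanceMatrix,
    groups: Mapping[str, Sequence[str]],
    fc_threshold: float = 4.0,
    alpha: float = 0.01,
    min_obs: int = 3,
) -> DEPCountMatrix:
    """All pairwise up/down DEP counts between the given groups.

    Each unordered pair is tested once; the mirrored entry swaps up and
    down, so ``count(A, B, "up") == count(B, A, "down")`` by construction
    (and by the symmetry of the underlying test).
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    out = DEPCountMatrix(groups=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            results = pairwise_dep(matrix, groups[a], groups[b], fc_threshold, alpha, min_obs)
            up = sum(1 for r in results if r.direction == "up")
            down = len(results) - up
            out.counts[(a, b)] = (up, down)
            out.counts[(b, a)] = (down, up)
    return out


def anova_across_groups(
    matrix: AbundanceMatrix,
    groups: Mapping[str, Sequence[str]],
    min_obs: int = 2,
) -> pd.Series:
    """Classical one-way ANOVA F-test p-value per protein on observed values.

    Proteins for which fewer than two groups reach ``min_obs`` observations
    are reported as NaN.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    subs = {g: matrix.subset_samples(list(groups[g])).values for g in names}
    pvals = np.full(matrix.n_proteins, np.nan)
    for j in range(matrix.n_proteins):
        arrays = []
        for g in names:
            col = subs[g][:, j]
            col = col[~np.isnan(col)]
            if len(col) >= min_obs:
                arrays.append(col)
        if len(arrays) < 2:
            continue
        if all(np.all(a == a[0]) for a in arrays):
            continue  # degenerate: no within-group variance anywhere
        pvals[j] = stats.f_oneway(*arrays).pvalue
    return pd.Series(pvals, index=matrix.protein_ids, name="anova_p")
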