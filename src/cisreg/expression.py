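"""Expression normalization, differential-expression thresholding and
element-to-gene linkage.

Cross-species comparisons run on one-to-one orthologous genes: TPM columns
are quantile normalized (every column gets the identical sorted value
vector, the per-rank across-column mean; ties within a column receive the
mean of the tied ranks' reference values), then genes pass the DE filter
when |log2 fold| >= 2 (inclusive), p < 0.001 and FDR < 0.01 (both strict).
Group-wise comparisons use the Wilcoxon rank-sum test, exact for small
groups, normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import Element, TSSRecord
from .qc import CoverageTrack

__all__ = [
    "DEThresholds",
    "quantile_normalize",
    "apply_de_thresholds",
    "tss_flank_intensity",
    "link_elements_to_genes",
    "compare_groups",
]

EXACT_WILCOXON_MAX_N = 8


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: every column is remapped onto the per-rank
    across-column mean of the sorted values.  Tied values within a column
    receive the mean of the reference values at the tied ranks, so the
    output of a column is a function of its value ranks only."""
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            out[order[i : k + 1], j] = reference[i : k + 1].mean()
            i = k + 1
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class DEThresholds:
    min_abs_log2_fold: float = 2.0  # inclusive
    max_pvalue: float = 0.001       # strict
    max_fdr: float = 0.01           # strict


def apply_de_thresholds(
    de_stats: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
    compute_fdr: bool = False,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Classify genes as up_in_A / down_in_A / ns.

    ``de_stats`` needs columns ``log2_fold`` and ``pvalue``; ``fdr`` must be
    present unless ``compute_fdr`` asks for Benjamini-Hochberg on the
    supplied p-values.  Direction is non-ns iff |log2_fold| >=
    ``min_abs_log2_fold`` AND p < ``max_pvalue`` AND FDR < ``max_fdr``.
    """
    df = de_stats.copy()
    for col in ("log2_fold", "pvalue"):
        if col not in df:
            raise ValueError(f"de_stats missing column {col!r}")
    if "fdr" not in df:
        if not compute_fdr:
            raise ValueError("no 'fdr' column and compute_fdr is disabled")
        df["fdr"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    significant = (
        (df["log2_fold"].abs() >= thresholds.min_abs_log2_fold)
        & (df["pvalue"] < thresholds.max_pvalue)
        & (df["fdr"] < thresholds.max_fdr)
    )
    df["direction"] = "ns"
    df.loc[significant & (df["log2_fold"] > 0), "direction"] = "up_in_A"
    df.loc[significant & (df["log2_fold"] < 0), "direction"] = "down_in_A"
    counts = {
        "up_in_A": int((df["direction"] == "up_in_A").sum()),
        "down_in_A": int((df["direction"] == "down_in_A").sum()),
        "ns": int((df["direction"] == "ns").sum()),
    }
    return df, counts


def tss_flank_intensity(
    tss_records: Sequence[TSSRecord],
    track: CoverageTrack,
    flank_bp: int = 1000,
) -> Dict[str, float]:
    """Histone RPM over [TSS - flank, TSS + flank), clipped at chromosome
    bounds, per gene."""
    out: Dict[str, float] = {}
    for t in tss_records:
        size = track.chrom_sizes[t.chrom]
        start = max(0, t.pos - flank_bp)
        end = min(size, t.pos + flank_bp)
        from .core import GenomicInterval

        out[t.gene_id] = track.rpm(GenomicInterval(t.chrom, start, end))
    return out


def link_elements_to_genes(
    elements: Sequence[Element],
    tss_records: Sequence[TSSRecord],
) -> Dict[str, str]:
    """Nearest-TSS linkage: element midpoint to TSS position on the same
    chromosome; distance ties break to the lexicographically first gene id."""
    by_chrom: Dict[str, list] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)
    out: Dict[str, str] = {}
    for el in elements:
        cands = by_chrom.get(el.interval.chrom)
        if not cands:
            continue
        mid = el.interval.midpoint
        nearest = min(cands, key=lambda t: (abs(t.pos - mid), t.gene_id))
        out[el.element_id] = nearest.gene_id
    return out


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two value groups.

    Exact null enumeration when the smaller group has <= 8 values and no
    ties span the pooled sample; otherwise the normal approximation with
    tie correction.  Returns (U statistic of group_a, p-value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        # no continuity correction so that a centered U gives p exactly 1
        res = mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic",
            use_continuity=False,
        )
    return float(res.statistic), float(res.pvalue)
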