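"""Cross-species conservation of 2 kb-standardized elements.

Coordinates are translated through UCSC chain alignments with liftOver-like
semantics: an interval maps when at least ``min_match`` of its bases fall in
the aligned blocks of a single chain (one target chromosome, colinear);
intervals whose qualifying bases would have to split across chains are
rejected unless ``allow_multiple`` is set, in which case the best chain
wins.  Reverse-strand chains yield reflected target coordinates.

A mapped element is *functionally conserved* when its target interval
overlaps (>= 1 bp) a target-species element of the same class, *sequence-only
conserved* when it maps without such an overlap, and *un-conserved* when it
does not map at all; the three statuses partition every element set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from .core import ChainAlignment, Element, GenomicInterval, StateSegment, TSSRecord

__all__ = [
    "LiftOverConfig",
    "MapResult",
    "ConservationCall",
    "map_interval",
    "classify_conservation",
    "conservation_fractions",
    "distance_to_nearest_gene",
    "ks_compare_with_random_control",
    "overlay_chromatin_states",
    "StateOverlay",
    "cluster_state_matrix",
]

REGULATORY_CATEGORIES = ("primary_DNase", "weak_enhancer", "active_enhancer")


@dataclass(frozen=True)
class LiftOverConfig:
    min_match: float = 0.2
    allow_multiple: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")


@dataclass
class MapResult:
    mapped: bool
    target: Optional[GenomicInterval] = None
    chain_id: Optional[int] = None
    mapped_bases: int = 0
    fraction: float = 0.0
    reason: str = ""


def _chain_overlap(interval: GenomicInterval, chain: ChainAlignment
                   ) -> Tuple[int, Optional[Tuple[int, int]]]:
    """Bases of ``interval`` aligned by ``chain`` and the forward-strand
    target span of those bases."""
    if chain.s_chrom != interval.chrom:
        return 0, None
    mapped = 0
    lo = hi = None
    cur_s, cur_q = chain.s_start, chain.t_start
    for size, dt, dq in chain.blocks:
        o_s = max(interval.start, cur_s)
        o_e = min(interval.end, cur_s + size)
        if o_e > o_s:
            mapped += o_e - o_s
            q_s = cur_q + (o_s - cur_s)
            q_e = cur_q + (o_e - cur_s)
            if chain.t_strand == "-":
                f_lo, f_hi = chain.t_size - q_e, chain.t_size - q_s
            else:
                f_lo, f_hi = q_s, q_e
            lo = f_lo if lo is None else min(lo, f_lo)
            hi = f_hi if hi is None else max(hi, f_hi)
        cur_s += size + dt
        cur_q += size + dq
        if cur_s >= interval.end:
            break
    return mapped, (None if lo is None else (lo, hi))


def map_interval(
    interval: GenomicInterval,
    chains: Sequence[ChainAlignment],
    config: LiftOverConfig = LiftOverConfig(),
) -> MapResult:
    """Translate an interval to target coordinates through chain blocks.

    The target interval is the forward-strand span of the mapped bases on
    the chosen chain.  The mapped-base count preserves per-base semantics:
    it equals what mapping each base independently through the chain would
    give.
    """
    width = interval.width
    per_chain = []
    for chain in chains:
        mapped, span = _chain_overlap(interval, chain)
        if mapped > 0:
            per_chain.append((mapped, chain, span))
    if not per_chain:
        return MapResult(False, reason="no_aligned_bases")
    qualifying = [
        entry for entry in per_chain if entry[0] / width >= config.min_match
    ]
    if not qualifying:
        best = max(per_chain, key=lambda e: (e[0], -e[1].chain_id))
        return MapResult(
            False,
            mapped_bases=best[0],
            fraction=best[0] / width,
            reason=f"below_min_match({best[0] / width:.3f}<{config.min_match})",
        )
    if len(qualifying) > 1 and not config.allow_multiple:
        return MapResult(False, reason="split_across_chains")
    mapped, chain, span = max(qualifying, key=lambda e: (e[0], -e[1].chain_id))
    return MapResult(
        True,
        target=GenomicInterval(chain.t_chrom, span[0], span[1]),
        chain_id=chain.chain_id,
        mapped_bases=mapped,
        fraction=mapped / width,
    )


@dataclass
class ConservationCall:
    element_id: str
    element_class: str
    status: str  # un_conserved | sequence_only | functional
    target: Optional[GenomicInterval] = None
    matched_target_ids: Tuple[str, ...] = ()
    reason: str = ""


def classify_conservation(
    elements: Sequence[Element],
    chains: Sequence[ChainAlignment],
    target_elements: Sequence[Element],
    config: LiftOverConfig = LiftOverConfig(),
) -> List[ConservationCall]:
    """Three-way conservation status for each (2 kb-standardized) element
    against a target-species element set classified by the same rules."""
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    classes_present = set()
    for i, tel in enumerate(target_elements):
        classes_present.add(tel.element_class)
        trees.setdefault(
            (tel.element_class, tel.interval.chrom), IntervalTree()
        ).addi(tel.interval.start, tel.interval.end, i)

    missing = {e.element_class for e in elements} - classes_present
    if missing:
        warnings.warn(
            f"element classes {sorted(missing)} absent from target set: "
            "all mapped elements of those classes become sequence_only"
        )

    calls: List[ConservationCall] = []
    for el in elements:
        res = map_interval(el.interval, chains, config)
        if not res.mapped:
            calls.append(
                ConservationCall(el.element_id, el.element_class,
                                 "un_conserved", reason=res.reason)
            )
            continue
        tree = trees.get((el.element_class, res.target.chrom))
        hits = sorted(
            target_elements[h.data].element_id
            for h in (tree.overlap(res.target.start, res.target.end) if tree else ())
        )
        status = "functional" if hits else "sequence_only"
        calls.append(
            ConservationCall(el.element_id, el.element_class, status,
                             target=res.target, matched_target_ids=tuple(hits))
        )
    return calls


def conservation_fractions(calls: Sequence[ConservationCall]) -> Dict[str, float]:
    n = len(calls)
    if n == 0:
        raise ValueError("no conservation calls")
    counts = {"un_conserved": 0, "sequence_only": 0, "functional": 0}
    for c in calls:
        counts[c.status] += 1
    return {k: v / n for k, v in counts.items()}


def distance_to_nearest_gene(
    elements: Sequence[Element],
    tss_records: Sequence[TSSRecord],
) -> np.ndarray:
    """Distance (bp) from each element's midpoint to the nearest TSS on the
    same chromosome; elements on TSS-free chromosomes get +inf."""
    pos_by_chrom: Dict[str, np.ndarray] = {}
    for t in tss_records:
        pos_by_chrom.setdefault(t.chrom, []).append(t.pos)
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        pos = pos_by_chrom.get(el.interval.chrom)
        if pos is None:
            out[i] = np.inf
            continue
        mid = el.interval.midpoint
        j = np.searchsorted(pos, mid)
        cand = []
        if j > 0:
            cand.append(mid - pos[j - 1])
        if j < pos.size:
            cand.append(pos[j] - mid)
        out[i] = min(cand)
    return out


def ks_compare_with_random_control(
    distances_a: np.ndarray,
    distances_b: np.ndarray,
    pool_distances: np.ndarray,
    n_draws: int = 100,
    draw_size: int = 4000,
    seed: int = 0,
) -> Dict[str, object]:
    """Two-sample KS comparison of distance distributions, plus a control
    band of ``n_draws`` random draws of ``draw_size`` elements from the pool
    (without replacement within a draw, independently across draws)."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    pool = np.asarray(pool_distances, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if draw_size > pool.size:
        raise ValueError(
            f"draw_size {draw_size} exceeds pool size {pool.size}"
        )
    stat, pvalue = ks_2samp(a, b)
    rng = np.random.default_rng(seed)
    controls = [
        rng.choice(pool, size=draw_size, replace=False) for _ in range(n_draws)
    ]
    return {
        "ks_statistic": float(stat),
        "pvalue": float(pvalue),
        "control_draws": controls,
        "control_medians": np.array([np.median(c) for c in controls]),
    }


@dataclass
class StateOverlay:
    matrix: pd.DataFrame  # rows: element ids, cols: tissues, cells: categories
    category_counts: Dict[str, int]
    tissue_counts: Dict[str, int]
    n_regulatory: int  # elements regulatory in >= 1 tissue

    @property
    def regulatory_fraction(self) -> float:
        return self.n_regulatory / len(self.matrix) if len(self.matrix) else 0.0


def overlay_chromatin_states(
    mapped_elements: Sequence[Tuple[str, GenomicInterval]],
    segments: Sequence[StateSegment],
    category_map: Dict[str, str],
) -> StateOverlay:
    """Per element per tissue, the category of the chromatin-state segment
    with the largest overlap ("other" when nothing covers the element).
    An element counts as regulatory when any tissue yields primary DNase,
    weak enhancer or active enhancer."""
    tissues = sorted({s.tissue for s in segments})
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for i, seg in enumerate(segments):
        trees.setdefault(
            (seg.tissue, seg.interval.chrom), IntervalTree()
        ).addi(seg.interval.start, seg.interval.end, i)

    rows = {}
    for element_id, iv in mapped_elements:
        row = {}
        for tissue in tissues:
            tree = trees.get((tissue, iv.chrom))
            best = None  # (overlap, -start, label, category)
            for hit in (tree.overlap(iv.start, iv.end) if tree else ()):
                seg = segments[hit.data]
                ov = iv.overlap_bp(seg.interval)
                key = (ov, -seg.interval.start, seg.state_label)
                if best is None or key > best[0]:
                    best = (key, category_map.get(seg.state_label, "other"))
            row[tissue] = "other" if best is None else best[1]
        rows[element_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)

    category_counts: Dict[str, int] = {}
    tissue_counts: Dict[str, int] = {t: 0 for t in tissues}
    n_regulatory = 0
    for element_id, row in matrix.iterrows():
        cats = set(row)
        for c in cats:
            category_counts[c] = category_counts.get(c, 0) + 1
        if any(c in REGULATORY_CATEGORIES for c in cats):
            n_regulatory += 1
        for t in tissues:
            if row[t] in REGULATORY_CATEGORIES:
                tissue_counts[t] += 1
    return StateOverlay(matrix, category_counts, tissue_counts, n_regulatory)


def cluster_state_matrix(
    matrix: pd.DataFrame, k: int = 100, seed: int = 0
) -> pd.Series:
    """k-means clustering of the one-hot-encoded element x tissue category
    matrix.  Cluster labels are renumbered by size, largest first, so label
    0 is always the biggest cluster; fixed seed gives identical assignments
    across runs."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of elements {len(matrix)}")
    encoded = pd.get_dummies(matrix).to_numpy(dtype=float)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300)
    raw = km.fit_predict(encoded)
    sizes = pd.Series(raw).value_counts()
    order = {old: new for new, old in enumerate(
        sorted(sizes.index, key=lambda c: (-sizes[c], c)))}
    return pd.Series([order[c] for c in raw], index=matrix.index, name="cluster")
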