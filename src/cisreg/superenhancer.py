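"""ROSE-style super-enhancer calling.

Enhancers within 12.5 kb of each other are stitched into regions
(transitive closure; the gap comparison is ``<= stitch_bp``), each region is
scored by the input-subtracted H3K27ac RPM summed over its constituent
enhancers (stitched gaps contribute nothing), and the super-enhancer cutoff
is the hockey-stick elbow: with ranks and signals min-max scaled to [0, 1],
the cutoff index maximizes x - y, i.e. the tangent point where the scaled
curve's slope reaches 1.  Regions with signal strictly above the cutoff
signal are super-enhancers.  Ties in the elbow search break to the highest
index (fewest super-enhancers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Element, GenomicInterval, TSSRecord
from .qc import CoverageTrack

__all__ = [
    "RoseConfig",
    "StitchedRegion",
    "ElbowResult",
    "stitch",
    "score_regions",
    "elbow_cutoff",
    "call_superenhancers",
    "assign_genes",
]


@dataclass(frozen=True)
class RoseConfig:
    stitch_bp: int = 12_500
    #: ROSE-style exclusion of TSS-proximal enhancers before stitching.
    #: Off by default: elements reaching this stage were already defined
    #: TSS-distal by the enhancer classification.
    exclude_tss_proximal: bool = False
    tss_upstream_bp: int = 2500
    tss_downstream_bp: int = 1500
    assign_mode: str = "overlap_then_nearest"  # or "nearest_tss"

    def __post_init__(self) -> None:
        if self.stitch_bp <= 0:
            raise ValueError("stitch_bp must be > 0")
        if self.assign_mode not in ("overlap_then_nearest", "nearest_tss"):
            raise ValueError(f"unknown assign_mode {self.assign_mode!r}")


@dataclass
class StitchedRegion:
    region_id: str
    interval: GenomicInterval
    constituents: List[Element]
    signal: Optional[float] = None
    rank: Optional[int] = None
    is_super: bool = False
    negative_signal: bool = False

    @property
    def constituent_ids(self) -> Tuple[str, ...]:
        return tuple(e.element_id for e in self.constituents)


def _tss_proximal(el: Element, tss_records: Sequence[TSSRecord],
                  config: RoseConfig) -> bool:
    for t in tss_records:
        if t.chrom != el.interval.chrom:
            continue
        if t.strand == "+":
            ws, we = t.pos - config.tss_upstream_bp, t.pos + config.tss_downstream_bp
        else:
            ws, we = t.pos - config.tss_downstream_bp, t.pos + config.tss_upstream_bp
        if el.interval.start < we and ws < el.interval.end:
            return True
    return False


def stitch(
    enhancers: Sequence[Element],
    config: RoseConfig = RoseConfig(),
    tss_records: Optional[Sequence[TSSRecord]] = None,
) -> List[StitchedRegion]:
    """Merge enhancers whose gap (end of one to start of the next on the
    same chromosome) is <= ``stitch_bp``; transitive, so a chain of nearby
    enhancers forms a single region.  Idempotent."""
    pool = list(enhancers)
    if config.exclude_tss_proximal:
        if tss_records is None:
            raise ValueError("exclude_tss_proximal requires tss_records")
        pool = [e for e in pool if not _tss_proximal(e, tss_records, config)]
    pool.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    regions: List[StitchedRegion] = []
    group: List[Element] = []

    def _flush():
        if not group:
            return
        iv = GenomicInterval(
            group[0].interval.chrom,
            min(e.interval.start for e in group),
            max(e.interval.end for e in group),
        )
        regions.append(
            StitchedRegion(f"stitched_{len(regions):05d}", iv, group.copy())
        )

    cur_chrom, cur_end = None, None
    for el in pool:
        if (
            cur_chrom != el.interval.chrom
            or el.interval.start - cur_end > config.stitch_bp
        ):
            _flush()
            group = []
            cur_chrom, cur_end = el.interval.chrom, el.interval.end
        else:
            cur_end = max(cur_end, el.interval.end)
        group.append(el)
    _flush()
    return regions


def score_regions(
    regions: Sequence[StitchedRegion],
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
) -> List[StitchedRegion]:
    """Signal = sum over constituent enhancers of RPM_IP - RPM_input,
    computed on the constituent intervals only (gaps excluded)."""
    for region in regions:
        signal = 0.0
        for el in region.constituents:
            signal += ip_track.rpm(el.interval) - input_track.rpm(el.interval)
        region.signal = signal
        region.negative_signal = signal < 0
    return list(regions)


@dataclass
class ElbowResult:
    cutoff_index: Optional[int]  # index into the ascending signal vector
    cutoff_signal: Optional[float]
    degenerate: bool = False


def elbow_cutoff(signals: Sequence[float]) -> ElbowResult:
    """Geometric elbow of the ranked-signal curve.

    ``signals`` must be sorted ascending with n >= 3.  Ranks are scaled to
    x in [0, 1] and signals to y in [0, 1]; the cutoff index is
    argmax(x - y), ties resolved to the highest index.  If all signals are
    equal there is no elbow: a warning is issued and no cutoff returned.
    """
    y_raw = np.asarray(signals, dtype=float)
    if y_raw.size < 3:
        raise ValueError("elbow_cutoff needs at least 3 signals")
    if np.any(np.diff(y_raw) < 0):
        raise ValueError("signals must be sorted ascending")
    span = y_raw[-1] - y_raw[0]
    if span == 0:
        warnings.warn("all signals equal: no elbow, zero super-enhancers")
        return ElbowResult(None, None, degenerate=True)
    x = np.arange(y_raw.size) / (y_raw.size - 1)
    y = (y_raw - y_raw[0]) / span
    diff = x - y
    best = int(np.flatnonzero(diff == diff.max())[-1])
    return ElbowResult(best, float(y_raw[best]))


def call_superenhancers(regions: Sequence[StitchedRegion]) -> Tuple[List[StitchedRegion], ElbowResult]:
    """Rank scored regions and flag those strictly above the elbow-cutoff
    signal as super-enhancers.  Returns regions sorted by descending signal
    (rank 1 = strongest) plus the elbow diagnostics."""
    if any(r.signal is None for r in regions):
        raise ValueError("regions must be scored before super-enhancer calling")
    ordered = sorted(regions, key=lambda r: (r.signal, r.region_id))
    elbow = elbow_cutoff([r.signal for r in ordered])
    for r in regions:
        r.is_super = (not elbow.degenerate) and r.signal > elbow.cutoff_signal
    by_rank = sorted(regions, key=lambda r: (-r.signal, r.region_id))
    for rank, r in enumerate(by_rank, 1):
        r.rank = rank
    return by_rank, elbow


def assign_genes(
    regions: Sequence[StitchedRegion],
    tss_records: Sequence[TSSRecord],
    mode: str = "overlap_then_nearest",
) -> Dict[str, List[str]]:
    """Map each region to target gene(s).

    ``overlap_then_nearest``: every gene whose TSS lies inside the stitched
    interval; if none, the single nearest TSS.  ``nearest_tss``: the single
    nearest TSS only.  Distance ties break to the lexicographically first
    gene id.
    """
    if not tss_records:
        raise ValueError("assign_genes requires a non-empty TSS set")
    if mode not in ("overlap_then_nearest", "nearest_tss"):
        raise ValueError(f"unknown mode {mode!r}")
    by_chrom: Dict[str, List[TSSRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)

    out: Dict[str, List[str]] = {}
    for region in regions:
        iv = region.interval
        cands = by_chrom.get(iv.chrom, [])
        inside = sorted(t.gene_id for t in cands if iv.start <= t.pos < iv.end)
        if mode == "overlap_then_nearest" and inside:
            out[region.region_id] = inside
            continue
        if not cands:
            out[region.region_id] = []
            continue
        mid = iv.midpoint
        nearest = min(cands, key=lambda t: (abs(t.pos - mid), t.gene_id))
        out[region.region_id] = [nearest.gene_id]
    return out
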