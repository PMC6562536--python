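"""Classify QC-passed peaks into cis-regulatory element classes.

Definitions (all overlaps are >= 1 bp on half-open intervals):

* promoter        — every H3K4me3 peak;
* active promoter — a promoter overlapping at least one H3K27ac peak;
* poised promoter — a promoter with no H3K27ac overlap;
* enhancer        — an H3K27ac peak with no H3K4me3 overlap and no overlap
                    with any TSS window (2.5 kb upstream / 1.5 kb downstream
                    of a TSS, strand-aware);
* broad H3K4me3 domain — an H3K4me3 peak overlapping a TSS window whose
                    original width exceeds 4 kb (width is measured on the
                    raw peak, never on the 2 kb standardized form).

H3K27ac peaks that fail the enhancer rules without being promoter-paired
are reported as unclassified rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core import Element, GenomicInterval, Peak, TSSRecord

__all__ = [
    "AnnotationConfig",
    "AnnotationResult",
    "tss_window",
    "classify_elements",
    "call_broad_domains",
    "rank_top_enhancers",
]


@dataclass(frozen=True)
class AnnotationConfig:
    upstream_bp: int = 2500
    downstream_bp: int = 1500
    broad_min_width_bp: int = 4000
    standard_width_bp: int = 2000
    #: optional stricter promoter rule: require TSS-window overlap
    restrict_promoters_to_tss: bool = False

    def __post_init__(self) -> None:
        for name in ("upstream_bp", "downstream_bp", "broad_min_width_bp",
                     "standard_width_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def tss_window(
    tss: TSSRecord,
    config: AnnotationConfig = AnnotationConfig(),
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> GenomicInterval:
    """The promoter-proximal window around a TSS: ``upstream_bp`` on the
    5' side and ``downstream_bp`` on the 3' side, reflected for - strand,
    clipped at chromosome bounds when sizes are supplied."""
    if tss.strand == "+":
        start, end = tss.pos - config.upstream_bp, tss.pos + config.downstream_bp
    else:
        start, end = tss.pos - config.downstream_bp, tss.pos + config.upstream_bp
    start = max(0, start)
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[tss.chrom])
    return GenomicInterval(tss.chrom, start, end)


def _tree_of(intervals: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def _overlaps_any(trees: Dict[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree and tree.overlap(iv.start, iv.end))


def _sorted_peaks(peaks: Sequence[Peak]) -> List[Peak]:
    return sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start,
                                        p.interval.end, p.name))


def _element_from_peak(peak: Peak, element_class: str, idx: int, prefix: str) -> Element:
    return Element(
        element_id=f"{prefix}{idx:06d}",
        interval=peak.interval,
        summit=peak.summit,
        element_class=element_class,
        source_ids=(peak.name,) if peak.name else (),
        rpm_ip=peak.rpm_ip,
        rpm_input=peak.rpm_input,
    )


@dataclass
class AnnotationResult:
    promoters: List[Element] = field(default_factory=list)
    active_promoters: List[Element] = field(default_factory=list)
    poised_promoters: List[Element] = field(default_factory=list)
    enhancers: List[Element] = field(default_factory=list)
    unclassified_h3k27ac: List[Peak] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        return {
            "promoter": len(self.promoters),
            "active_promoter": len(self.active_promoters),
            "poised_promoter": len(self.poised_promoters),
            "enhancer": len(self.enhancers),
            "unclassified_h3k27ac": len(self.unclassified_h3k27ac),
        }


def classify_elements(
    h3k4me3_peaks: Sequence[Peak],
    h3k27ac_peaks: Sequence[Peak],
    tss_records: Sequence[TSSRecord],
    config: AnnotationConfig = AnnotationConfig(),
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> AnnotationResult:
    """Partition peaks into promoter / active promoter / poised promoter /
    enhancer classes.  Inputs are sorted internally, so counts are invariant
    under input permutation."""
    if not tss_records:
        raise ValueError(
            "TSS records are required: the enhancer definition depends on "
            "TSS-window exclusion"
        )
    k4 = _sorted_peaks(h3k4me3_peaks)
    k27 = _sorted_peaks(h3k27ac_peaks)
    k4_trees = _tree_of([p.interval for p in k4])
    k27_trees = _tree_of([p.interval for p in k27])
    windows = [tss_window(t, config, chrom_sizes) for t in tss_records]
    window_trees = _tree_of(windows)

    result = AnnotationResult()
    for i, pk in enumerate(k4):
        if config.restrict_promoters_to_tss and not _overlaps_any(window_trees, pk.interval):
            continue
        el = _element_from_peak(pk, "promoter", i, "prom_")
        result.promoters.append(el)
        sub = "active_promoter" if _overlaps_any(k27_trees, pk.interval) else "poised_promoter"
        sub_el = _element_from_peak(pk, sub, i, "prom_")
        (result.active_promoters if sub == "active_promoter"
         else result.poised_promoters).append(sub_el)

    for i, pk in enumerate(k27):
        if _overlaps_any(k4_trees, pk.interval):
            continue  # promoter-paired H3K27ac signal
        if _overlaps_any(window_trees, pk.interval):
            result.unclassified_h3k27ac.append(pk)
            continue
        result.enhancers.append(_element_from_peak(pk, "enhancer", i, "enh_"))
    return result


def call_broad_domains(
    h3k4me3_peaks: Sequence[Peak],
    tss_records: Sequence[TSSRecord],
    config: AnnotationConfig = AnnotationConfig(),
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[Element]:
    """Broad H3K4me3 domains: TSS-window-overlapping peaks strictly wider
    than ``broad_min_width_bp`` (4 kb); width 4000 exactly is not broad."""
    windows = [tss_window(t, config, chrom_sizes) for t in tss_records]
    window_trees = _tree_of(windows)
    out: List[Element] = []
    for i, pk in enumerate(_sorted_peaks(h3k4me3_peaks)):
        if pk.interval.width > config.broad_min_width_bp and _overlaps_any(
            window_trees, pk.interval
        ):
            out.append(_element_from_peak(pk, "broad_domain", i, "broad_"))
    return out


def rank_top_enhancers(enhancers: Sequence[Element], n: int = 3000) -> List[Element]:
    """Top ``n`` enhancers by H3K27ac RPM, descending; ties broken by
    genome order (chrom, start) so the ranking is stable across runs."""
    for el in enhancers:
        if el.rpm_ip is None:
            raise ValueError(f"enhancer {el.element_id} has no rpm_ip")
    ranked = sorted(
        enhancers,
        key=lambda e: (-e.rpm_ip, e.interval.chrom, e.interval.start, e.element_id),
    )
    return ranked[: min(n, len(ranked))]
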