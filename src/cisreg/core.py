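"""Core coordinate types shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED-style).  Conversion from
1-based formats (GTF, chain display coordinates) happens in :mod:`cisreg.io`
and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "GenomicInterval",
    "Peak",
    "TSSRecord",
    "ChainAlignment",
    "StateSegment",
    "Element",
    "ELEMENT_CLASSES",
]

ELEMENT_CLASSES = (
    "promoter",
    "active_promoter",
    "poised_promoter",
    "enhancer",
    "broad_domain",
    "super_enhancer",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp shared, half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A called ChIP-seq peak with its summit and quality statistics.

    ``pvalue`` is the Poisson p-value of the peak caller (linear scale;
    narrowPeak/broadPeak files store -log10 of it).  ``rpm_ip`` and
    ``rpm_input`` are reads-per-million of the IP and input libraries over
    the peak region; they are ``None`` until computed from coverage tracks.
    """

    interval: GenomicInterval
    summit: int
    pvalue: float
    mark: str  # "H3K4me3" or "H3K27ac"
    name: str = ""
    rpm_ip: Optional[float] = None
    rpm_input: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} not in (0, 1]")
        for v in (self.rpm_ip, self.rpm_input):
            if v is not None and v < 0:
                raise ValueError("RPM values must be >= 0")


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site with its expression level (TPM)."""

    gene_id: str
    chrom: str
    pos: int
    strand: str
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"TSS for {self.gene_id} requires an explicit +/- strand"
            )
        if self.tpm < 0:
            raise ValueError("TPM must be >= 0")


@dataclass
class ChainAlignment:
    """One pairwise alignment chain in UCSC chain semantics.

    ``blocks`` is an ordered list of ``(size, dt, dq)`` triples: ``size``
    aligned bases, then ``dt``/``dq`` unaligned bases on the source/target
    side before the next block (both 0 for the final block).  When
    ``t_strand`` is ``-`` the target start/end are expressed in
    reverse-strand coordinates, exactly as in the chain file format; use
    :meth:`target_forward` to reflect a reverse coordinate onto the forward
    strand.
    """

    chain_id: int
    score: float
    s_chrom: str
    s_size: int
    s_start: int
    s_end: int
    t_chrom: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    blocks: list  # of (size, dt, dq)
    s_strand: str = "+"

    def validate(self) -> None:
        if self.s_strand != "+":
            raise ValueError(
                f"chain {self.chain_id}: source strand must be '+'"
            )
        if not self.blocks:
            raise ValueError(f"chain {self.chain_id}: no alignment blocks")
        s_span = sum(sz + dt for sz, dt, _ in self.blocks)
        t_span = sum(sz + dq for sz, _, dq in self.blocks)
        if s_span != self.s_end - self.s_start:
            raise ValueError(
                f"chain {self.chain_id}: source block sum {s_span} != "
                f"declared span {self.s_end - self.s_start}"
            )
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: target block sum {t_span} != "
                f"declared span {self.t_end - self.t_start}"
            )
        if any(sz < 1 for sz, _, _ in self.blocks):
            raise ValueError(f"chain {self.chain_id}: block size < 1")
        if any(dt < 0 or dq < 0 for _, dt, dq in self.blocks):
            raise ValueError(f"chain {self.chain_id}: negative gap")
        last = self.blocks[-1]
        if last[1] != 0 or last[2] != 0:
            raise ValueError(
                f"chain {self.chain_id}: trailing gaps on final block"
            )

    def target_forward(self, pos: int) -> int:
        """Reflect a target-strand coordinate onto the forward strand."""
        if self.t_strand == "+":
            return pos
        return self.t_size - 1 - pos


@dataclass(frozen=True)
class StateSegment:
    """A chromatin-state segment (ChromHMM-like) in one tissue."""

    interval: GenomicInterval
    state_label: str
    tissue: str


@dataclass
class Element:
    """A classified cis-regulatory element.

    ``clipped`` records whether 2 kb summit-standardization ran into a
    chromosome boundary.  ``source_ids`` names the peaks (or constituent
    enhancers, for super-enhancers) the element was derived from.
    """

    element_id: str
    interval: GenomicInterval
    summit: int
    element_class: str
    source_ids: tuple = ()
    rpm_ip: Optional[float] = None
    rpm_input: Optional[float] = None
    linked_gene: Optional[str] = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")

    def with_interval(self, interval: GenomicInterval, clipped: bool = False) -> "Element":
        new = replace(self, interval=interval)
        new.clipped = clipped
        return new
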