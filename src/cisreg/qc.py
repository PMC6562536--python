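"""Signal-level quality control.

Implements the peak-quality rules applied before any element is classified:
Poisson p-value cutoffs (narrow <= 0.01, broad <= 0.1; boundary values are
kept because only strictly larger values are removed), the two-fold RPM
enrichment rule (RPM_IP >= 2 x RPM_input and RPM_IP - RPM_input > 1),
10 kb-binned replicate correlation, and the 2 kb summit-centered
standardization applied to every element before cross-species comparison.

Coverage is consumed as bedGraph where the value column is per-base read
density; the total mapped read count used for RPM normalization comes from
the track's ``# total_reads=`` header rather than being recomputed, so RPM
stays well-defined for partial tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as gio
from .core import Element, GenomicInterval, Peak

__all__ = [
    "CoverageTrack",
    "BinnedTrack",
    "bin_track",
    "replicate_correlation",
    "filter_peaks_by_pvalue",
    "enrichment_filter",
    "standardize_2kb",
    "standardize_elements",
    "peak_qc",
]

NARROW_P_CUTOFF = 0.01
BROAD_P_CUTOFF = 0.1
STANDARD_WIDTH = 2000


@dataclass
class CoverageTrack:
    """Binned per-base read density with a declared library size.

    ``density[chrom][i]`` is the per-base read depth over bin ``i`` of width
    ``bin_size``; the number of reads in an interval is the integral of the
    density, and RPM divides by ``total_reads`` (from the bedGraph header).
    """

    bin_size: int
    total_reads: float
    chrom_sizes: Dict[str, int]
    density: Dict[str, np.ndarray]

    @classmethod
    def zeros(cls, chrom_sizes: Dict[str, int], bin_size: int = 10,
              total_reads: float = 1.0) -> "CoverageTrack":
        density = {
            c: np.zeros(-(-size // bin_size), dtype=float)
            for c, size in chrom_sizes.items()
        }
        return cls(bin_size, total_reads, dict(chrom_sizes), density)

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: Dict[str, int],
                      bin_size: int = 10) -> "CoverageTrack":
        runs, total = gio.read_bedgraph(path)
        track = cls.zeros(chrom_sizes, bin_size, total)
        for chrom, chrom_runs in runs.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom.sizes")
            arr = track.density[chrom]
            for start, end, value in chrom_runs:
                if start % bin_size or (end % bin_size and end != chrom_sizes[chrom]):
                    raise ValueError(
                        f"bedGraph run {chrom}:{start}-{end} not aligned to "
                        f"{bin_size} bp bins"
                    )
                arr[start // bin_size : -(-end // bin_size)] = value
        return track

    def to_bedgraph(self, path) -> None:
        # merge consecutive equal-valued bins into single runs
        runs: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, arr in self.density.items():
            size = self.chrom_sizes[chrom]
            chrom_runs = []
            if arr.size:
                breaks = np.flatnonzero(np.diff(arr) != 0) + 1
                starts = np.concatenate([[0], breaks])
                ends = np.concatenate([breaks, [arr.size]])
                for s, e in zip(starts, ends):
                    v = float(arr[s])
                    if v != 0.0:
                        chrom_runs.append(
                            (int(s) * self.bin_size,
                             min(int(e) * self.bin_size, size), v)
                        )
            runs[chrom] = chrom_runs
        gio.write_bedgraph(runs, self.total_reads, path)

    def reads_in(self, interval: GenomicInterval) -> float:
        """Integral of read density over the interval; partial bins are
        pro-rated by overlap fraction."""
        if interval.chrom not in self.density:
            raise ValueError(f"interval chromosome {interval.chrom!r} not in track")
        size = self.chrom_sizes[interval.chrom]
        if interval.end > size:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {size}"
            )
        arr = self.density[interval.chrom]
        bs = self.bin_size
        i0, i1 = interval.start // bs, (interval.end - 1) // bs
        if i0 == i1:
            return float(arr[i0]) * interval.width
        total = float(arr[i0]) * ((i0 + 1) * bs - interval.start)
        total += float(arr[i1]) * (interval.end - i1 * bs)
        if i1 > i0 + 1:
            total += float(arr[i0 + 1 : i1].sum()) * bs
        return total

    def rpm(self, interval: GenomicInterval) -> float:
        return 1e6 * self.reads_in(interval) / self.total_reads


@dataclass
class BinnedTrack:
    """Genome-wide read counts on a fixed tiling (default 10 kb), used for
    replicate-correlation QC."""

    bin_size: int
    counts: Dict[str, np.ndarray]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])


def bin_track(cov: CoverageTrack, bin_size: int = 10_000) -> BinnedTrack:
    """Aggregate a coverage track into read counts per ``bin_size`` window."""
    counts: Dict[str, np.ndarray] = {}
    for chrom, size in cov.chrom_sizes.items():
        n = -(-size // bin_size)
        out = np.zeros(n, dtype=float)
        for i in range(n):
            s, e = i * bin_size, min((i + 1) * bin_size, size)
            out[i] = cov.reads_in(GenomicInterval(chrom, s, e))
        counts[chrom] = out
    return BinnedTrack(bin_size, counts)


def replicate_correlation(track_a: BinnedTrack, track_b: BinnedTrack) -> float:
    """Pearson r between two replicates on the same binning grid.  Bins that
    are zero in both replicates are retained."""
    if track_a.bin_size != track_b.bin_size or set(track_a.counts) != set(track_b.counts):
        raise ValueError("replicate tracks are on different bin grids")
    a, b = track_a.flatten(), track_b.flatten()
    if a.shape != b.shape:
        raise ValueError("replicate tracks are on different bin grids")
    return float(np.corrcoef(a, b)[0, 1])


def filter_peaks_by_pvalue(peaks: Sequence[Peak], mode: str) -> List[Peak]:
    """Drop peaks whose Poisson p-value is strictly greater than the cutoff
    (0.01 narrow, 0.1 broad); boundary values survive."""
    if mode == "narrow":
        cutoff = NARROW_P_CUTOFF
    elif mode == "broad":
        cutoff = BROAD_P_CUTOFF
    else:
        raise ValueError(f"mode must be 'narrow' or 'broad', got {mode!r}")
    return [p for p in peaks if p.pvalue <= cutoff]


def _passes_enrichment(rpm_ip: float, rpm_input: float) -> bool:
    return rpm_ip >= 2.0 * rpm_input and (rpm_ip - rpm_input) > 1.0


def enrichment_filter(
    peaks: Sequence[Peak],
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
) -> List[Peak]:
    """Keep peaks with RPM_IP >= 2 x RPM_input and RPM_IP - RPM_input > 1,
    recomputing both RPM values from the tracks.  Order is preserved and the
    output is a subset of the input."""
    kept: List[Peak] = []
    for pk in peaks:
        rpm_ip = ip_track.rpm(pk.interval)
        rpm_input = input_track.rpm(pk.interval)
        pk = replace(pk, rpm_ip=rpm_ip, rpm_input=rpm_input)
        if _passes_enrichment(rpm_ip, rpm_input):
            kept.append(pk)
    return kept


def standardize_2kb(
    summit: int,
    chrom: str,
    chrom_sizes: Dict[str, int],
    width: int = STANDARD_WIDTH,
) -> Tuple[GenomicInterval, bool]:
    """The 2 kb window centered on a summit, ``[summit - w/2, summit + w/2)``,
    clipped (not dropped) at chromosome boundaries.  Returns the interval and
    whether clipping occurred."""
    size = chrom_sizes[chrom]
    if not (0 <= summit < size):
        raise ValueError(f"summit {summit} outside chromosome {chrom} (len {size})")
    half = width // 2
    start, end = summit - half, summit + half
    clipped = start < 0 or end > size
    return GenomicInterval(chrom, max(0, start), min(size, end)), clipped


def standardize_elements(
    elements: Sequence[Element], chrom_sizes: Dict[str, int],
    width: int = STANDARD_WIDTH,
) -> List[Element]:
    out = []
    for el in elements:
        iv, clipped = standardize_2kb(el.summit, el.interval.chrom, chrom_sizes, width)
        out.append(el.with_interval(iv, clipped=clipped))
    return out


def peak_qc(
    peaks: Sequence[Peak],
    mode: str,
    ip_track: Optional[CoverageTrack] = None,
    input_track: Optional[CoverageTrack] = None,
) -> Tuple[List[Peak], pd.DataFrame]:
    """Full peak QC: p-value cutoff then (if tracks given) the enrichment
    rule.  Returns survivors plus a per-peak report with pass/fail reasons."""
    rows = []
    survivors: List[Peak] = []
    cutoff = NARROW_P_CUTOFF if mode == "narrow" else BROAD_P_CUTOFF
    for pk in peaks:
        reason = ""
        ok = pk.pvalue <= cutoff
        if not ok:
            reason = f"pvalue>{cutoff}"
        rpm_ip = rpm_input = np.nan
        if ok and ip_track is not None and input_track is not None:
            rpm_ip = ip_track.rpm(pk.interval)
            rpm_input = input_track.rpm(pk.interval)
            pk = replace(pk, rpm_ip=rpm_ip, rpm_input=rpm_input)
            if not _passes_enrichment(rpm_ip, rpm_input):
                ok, reason = False, "enrichment"
        if ok:
            survivors.append(pk)
        rows.append(
            dict(
                name=pk.name,
                chrom=pk.interval.chrom,
                start=pk.interval.start,
                end=pk.interval.end,
                pvalue=pk.pvalue,
                rpm_ip=rpm_ip,
                rpm_input=rpm_input,
                passed=ok,
                reason=reason,
            )
        )
    return survivors, pd.DataFrame(rows)
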