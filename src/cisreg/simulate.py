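"""Synthetic study generator.

Produces every input the pipeline consumes — genome, gene annotation,
peak calls, coverage tracks, replicate tracks, cross-species chains,
target-species element sets, chromatin-state segmentations, expression
tables, orthology and PWMs — with planted ground truth so each downstream
stage is testable without external data:

* enhancer signal is heavy-tailed (Pareto, tail exponent ``se_tail_exponent``)
  and a handful of gene loci carry dense clusters of very strong enhancers,
  so the ranked-signal curve has a real hockey-stick elbow;
* conservation statuses (functional / sequence-only / un-conserved) are
  planted per element at the configured fractions, with un-conserved
  elements placed in chain gaps and functional elements given a same-class
  target element at their (generator-computed) orthologous position;
* super-enhancer target genes and active-promoter genes get multiplicative
  expression boosts, giving the group comparisons a known direction;
* motif occurrences are exact planted k-mers, so PWM scanning has a known
  answer.

Determinism: every generator draws from ``numpy`` Generators seeded from
``(seed, stream)`` pairs, so identical configs give byte-identical output
files and sub-generators stay decoupled.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as gio
from .core import ChainAlignment, Element, GenomicInterval, Peak, StateSegment, TSSRecord
from .crc import PWM
from .qc import CoverageTrack

__all__ = [
    "SyntheticConfig",
    "SizingError",
    "ReferenceBundle",
    "PeaksBundle",
    "ChainPairBundle",
    "generate_reference",
    "generate_peaks_and_coverage",
    "generate_chain_pair",
    "generate_state_segments",
    "generate_de_stats",
    "generate_pwm_set",
    "plant_motif",
    "DEFAULT_CATEGORY_MAP",
]

# rng stream offsets: one per sub-generator, so changing one stage's draws
# never perturbs another stage
_STREAM_REFERENCE = 1
_STREAM_PEAKS = 2
_STREAM_CHAIN = 3
_STREAM_PWM = 4
_STREAM_DE = 5
_STREAM_STATES = 6

#: per-base read density of the uniform input (control) library
_INPUT_DENSITY = 2e-4
#: per-base background density of IP libraries
_IP_BACKGROUND = 5e-5
#: declared library size; with 1e6 total reads, RPM equals reads-in-region
_TOTAL_READS = 1_000_000.0

DEFAULT_CATEGORY_MAP = {
    "EnhA": "active_enhancer",
    "EnhWk": "weak_enhancer",
    "DNase": "primary_DNase",
    "Quies": "other",
    "Tx": "other",
    "ReprPC": "other",
}


class SizingError(ValueError):
    """Requested feature counts do not fit on the configured genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 3_000_000
    n_genes: int = 200
    n_h3k4me3_peaks: int = 200
    n_h3k27ac_peaks: int = 300
    frac_functional: float = 0.30
    frac_sequence_only: float = 0.55
    se_tail_exponent: float = 1.5
    de_effect_log2: float = 2.0
    noise_sd: float = 0.05
    # placement structure
    frac_k4_at_tss: float = 0.9
    frac_k27_distal: float = 0.85
    n_se_loci: int = 26
    active_promoter_effect_log2: float = 1.5
    broad_domain_effect_log2: float = 1.0
    # chain geometry
    chain_coverage: float = 0.9
    chain_with_indels: bool = True
    conservation_proximity_bias: bool = True
    # chromatin-state overlay
    frac_seqonly_regulatory: float = 0.78
    # coverage resolution
    bin_size: int = 10

    def __post_init__(self) -> None:
        if self.frac_functional < 0 or self.frac_sequence_only < 0:
            raise ValueError("conservation fractions must be >= 0")
        if self.frac_functional + self.frac_sequence_only > 1 + 1e-12:
            raise ValueError("frac_functional + frac_sequence_only must be <= 1")
        if self.se_tail_exponent <= 0:
            raise ValueError("se_tail_exponent must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_chroms < 1 or self.chrom_len < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 0 or self.n_h3k4me3_peaks < 0 or self.n_h3k27ac_peaks < 0:
            raise ValueError("feature counts must be >= 0")
        if not (0 < self.chain_coverage <= 1):
            raise ValueError("chain_coverage must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# reference bundle

@dataclass
class ReferenceBundle:
    chrom_sizes: Dict[str, int]
    sequences: Optional[Dict[str, str]]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    expression: pd.DataFrame  # index gene_id; columns liver_rep1, liver_rep2
    se_target_genes: List[str] = field(default_factory=list)
    active_promoter_genes: List[str] = field(default_factory=list)
    broad_domain_genes: List[str] = field(default_factory=list)

    def tss_records(self) -> List[TSSRecord]:
        mean_tpm = self.expression.mean(axis=1) if len(self.expression) else {}
        out = []
        for row in self.genes.itertuples():
            pos = row.start if row.strand == "+" else row.end - 1
            out.append(
                TSSRecord(row.gene_id, row.chrom, pos, row.strand,
                          float(mean_tpm.get(row.gene_id, 0.0)))
            )
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_chrom_sizes(self.chrom_sizes, outdir / "genome.chrom.sizes")
        if self.sequences is not None:
            gio.write_fasta(self.sequences, outdir / "genome.fa")
        gio.write_gtf(
            [
                (r.gene_id, r.chrom, r.start, r.end, r.strand)
                for r in self.genes.itertuples()
            ],
            outdir / "genes.gtf",
        )
        gio.write_expression(self.expression, outdir / "expression.tsv")


def generate_reference(config: SyntheticConfig, with_sequence: bool = True) -> ReferenceBundle:
    """Genome, non-overlapping stranded genes, and a baseline expression
    table (two replicate liver samples; log-normal TPM)."""
    rng = config.rng(_STREAM_REFERENCE)
    chrom_sizes = {f"chr{i + 1}": config.chrom_len for i in range(config.n_chroms)}

    sequences = None
    if with_sequence:
        bases = np.array(list("ACGT"))
        sequences = {
            c: "".join(bases[rng.integers(0, 4, size=size)])
            for c, size in chrom_sizes.items()
        }

    rows = []
    if config.n_genes > 0:
        chroms = list(chrom_sizes)
        per_chrom = [
            config.n_genes // config.n_chroms
            + (1 if i < config.n_genes % config.n_chroms else 0)
            for i in range(config.n_chroms)
        ]
        gene_idx = 0
        for chrom, n_on_chrom in zip(chroms, per_chrom):
            if n_on_chrom == 0:
                continue
            slot_w = config.chrom_len // n_on_chrom
            if slot_w < 20_000:
                raise SizingError(
                    f"{chrom}: {n_on_chrom} genes need {n_on_chrom * 20_000} bp, "
                    f"chromosome is {config.chrom_len} bp"
                )
            for j in range(n_on_chrom):
                length = int(rng.integers(2_000, 8_000))
                offset = int(rng.integers(6_000, slot_w - length - 6_000))
                start = j * slot_w + offset
                rows.append(
                    dict(
                        gene_id=f"G{gene_idx:04d}",
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                gene_idx += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    base_tpm = rng.lognormal(mean=1.5, sigma=1.2, size=len(genes))
    noise = config.noise_sd
    expr = pd.DataFrame(
        {
            "liver_rep1": base_tpm * 2 ** rng.normal(0, noise, size=len(genes)),
            "liver_rep2": base_tpm * 2 ** rng.normal(0, noise, size=len(genes)),
        },
        index=pd.Index(genes["gene_id"], name="gene_id"),
    )
    return ReferenceBundle(chrom_sizes, sequences, genes, expr)


# ---------------------------------------------------------------------------
# peaks + coverage

@dataclass
class PeaksBundle:
    h3k4me3: List[Peak]
    h3k27ac: List[Peak]
    tracks: Dict[str, CoverageTrack]  # k4_ip, k4_input, k27_ip, k27_input
    replicates: Dict[str, Tuple[CoverageTrack, CoverageTrack]]
    se_truth: pd.DataFrame  # gene_id, chrom, cluster_start, cluster_end

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_peaks(self.h3k4me3, outdir / "h3k4me3.narrowPeak")
        gio.write_peaks(self.h3k27ac, outdir / "h3k27ac.narrowPeak")
        for name, track in self.tracks.items():
            track.to_bedgraph(outdir / f"{name}.bedGraph")
        for mark, (a, b) in self.replicates.items():
            a.to_bedgraph(outdir / f"{mark}_rep1.bedGraph")
            b.to_bedgraph(outdir / f"{mark}_rep2.bedGraph")


class _Occupancy:
    """Per-chromosome interval bookkeeping for rejection-sampled placement."""

    def __init__(self, margin: int = 20):
        self.trees: Dict[str, IntervalTree] = {}
        self.margin = margin

    def blocked(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree and tree.overlap(start - self.margin, end + self.margin))

    def add(self, chrom: str, start: int, end: int) -> None:
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end)


def _deposit(track: CoverageTrack, interval: GenomicInterval, reads: float,
             rng: np.random.Generator, noise_sd: float) -> None:
    """Add a uniform-density pulse carrying ``reads`` reads over the
    interval (per-bin multiplicative noise when noise_sd > 0)."""
    bs = track.bin_size
    arr = track.density[interval.chrom]
    dens = reads / interval.width
    i0, i1 = interval.start // bs, -(-interval.end // bs)
    if noise_sd > 0:
        factors = np.maximum(0.0, 1.0 + rng.normal(0, noise_sd, size=i1 - i0))
        arr[i0:i1] += dens * factors
    else:
        arr[i0:i1] += dens


def generate_peaks_and_coverage(
    config: SyntheticConfig, ref: ReferenceBundle
) -> PeaksBundle:
    """H3K4me3 and H3K27ac peak sets with consistent coverage tracks.

    Plants: ``frac_k4_at_tss`` of H3K4me3 peaks inside TSS windows (a few
    of them wider than 4 kb, the broad-domain pool); active-promoter
    H3K27ac peaks overlapping TSS-proximal H3K4me3 peaks; Pareto-tailed
    distal enhancers; and ``n_se_loci`` dense clusters of very strong
    enhancers placed just outside the TSS window of a target gene (those
    genes get an expression boost of ``de_effect_log2`` log2 units).
    A small fraction of peaks is planted with failing p-values or poor
    enrichment to exercise the QC filters.
    """
    rng = config.rng(_STREAM_PEAKS)
    tss = ref.tss_records()
    chrom_sizes = ref.chrom_sizes
    chroms = list(chrom_sizes)
    occ_k4, occ_k27 = _Occupancy(), _Occupancy()
    # stitch-distance guard around planted clusters: nothing else may land
    # close enough to bridge a cluster toward a neighbouring gene
    occ_guard = _Occupancy(margin=0)
    _GUARD = 12_600

    tracks = {
        name: CoverageTrack.zeros(chrom_sizes, config.bin_size, _TOTAL_READS)
        for name in ("k4_ip", "k4_input", "k27_ip", "k27_input")
    }
    for name in ("k4_input", "k27_input"):
        for arr in tracks[name].density.values():
            arr[:] = _INPUT_DENSITY
    for name in ("k4_ip", "k27_ip"):
        for arr in tracks[name].density.values():
            arr[:] = _IP_BACKGROUND

    def good_p():
        return 10.0 ** (-rng.uniform(2.5, 8.0))

    def place_random(occ: _Occupancy, width: int, avoid_tss: bool,
                     max_tries: int = 200) -> Optional[Tuple[str, int]]:
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            if occ.blocked(chrom, start, start + width):
                continue
            if avoid_tss and any(
                t.chrom == chrom and start < t.pos + 2500 and t.pos - 2500 < start + width
                for t in tss
            ):
                continue
            return chrom, start
        return None

    k4_peaks: List[Peak] = []
    k27_peaks: List[Peak] = []

    # --- H3K4me3 at TSS (promoters); some wide (broad-domain pool) -------
    n_k4 = config.n_h3k4me3_peaks
    n_at_tss = int(round(config.frac_k4_at_tss * n_k4)) if tss else 0
    n_broad = min(max(1, n_k4 // 20), n_at_tss) if n_at_tss else 0
    tss_order = list(rng.permutation(len(tss))) if tss else []
    broad_genes: List[str] = []
    k4_tss_genes: List[str] = []
    for i in range(n_at_tss):
        t = tss[tss_order[i % len(tss_order)]]
        wide = i < n_broad
        width = int(rng.integers(4_500, 7_000)) if wide else int(rng.integers(900, 3_200))
        center = t.pos + int(rng.integers(-300, 301))
        start = max(0, min(center - width // 2, chrom_sizes[t.chrom] - width))
        if occ_k4.blocked(t.chrom, start, start + width):
            continue
        occ_k4.add(t.chrom, start, start + width)
        summit = start + width // 2 + int(rng.integers(-width // 6, width // 6 + 1))
        rpm_ip = 3.0 + rng.gamma(2.0, 2.0)
        k4_peaks.append(
            Peak(GenomicInterval(t.chrom, start, start + width), summit,
                 good_p(), "H3K4me3", name=f"k4_{len(k4_peaks):05d}",
                 rpm_ip=rpm_ip, rpm_input=_INPUT_DENSITY * width)
        )
        k4_tss_genes.append(t.gene_id)
        if wide:
            broad_genes.append(t.gene_id)

    # --- distal H3K4me3 ---------------------------------------------------
    while len(k4_peaks) < n_k4:
        width = int(rng.integers(900, 3_200))
        spot = place_random(occ_k4, width, avoid_tss=True)
        if spot is None:
            break
        chrom, start = spot
        occ_k4.add(chrom, start, start + width)
        bad = rng.random() < 0.05
        pvalue = rng.uniform(0.011, 0.2) if bad else good_p()
        rpm_ip = 3.0 + rng.gamma(2.0, 2.0)
        k4_peaks.append(
            Peak(GenomicInterval(chrom, start, start + width),
                 start + width // 2, pvalue, "H3K4me3",
                 name=f"k4_{len(k4_peaks):05d}",
                 rpm_ip=rpm_ip, rpm_input=_INPUT_DENSITY * width)
        )

    # --- H3K27ac at active promoters -------------------------------------
    n_k27 = config.n_h3k27ac_peaks
    n_k27_tss = int(round((1 - config.frac_k27_distal) * n_k27))
    active_genes: List[str] = []
    for i in range(min(n_k27_tss, len(k4_tss_genes))):
        gene = k4_tss_genes[i]
        src = k4_peaks[i]  # the TSS H3K4me3 peak placed for this gene
        width = int(rng.integers(800, 2_000))
        start = max(0, src.summit - width // 2 + int(rng.integers(-200, 201)))
        start = min(start, chrom_sizes[src.interval.chrom] - width)
        if occ_k27.blocked(src.interval.chrom, start, start + width):
            continue
        occ_k27.add(src.interval.chrom, start, start + width)
        rpm_ip = 2.5 + rng.gamma(2.0, 1.5)
        k27_peaks.append(
            Peak(GenomicInterval(src.interval.chrom, start, start + width),
                 start + width // 2, good_p(), "H3K27ac",
                 name=f"k27_{len(k27_peaks):05d}",
                 rpm_ip=rpm_ip, rpm_input=_INPUT_DENSITY * width)
        )
        active_genes.append(gene)

    # --- super-enhancer clusters ------------------------------------------
    se_rows = []
    se_genes: List[str] = []
    unused_genes = [g for g in ref.genes["gene_id"] if g not in set(active_genes)]
    rng.shuffle(unused_genes)
    tss_by_gene = {t.gene_id: t for t in tss}
    gene_rank = {g: i for i, g in enumerate(ref.genes["gene_id"])}
    se_ranks: set = set()
    for gene in unused_genes:
        if len(se_genes) >= config.n_se_loci:
            break
        # keep SE loci non-adjacent so clusters never stitch together
        if {gene_rank[gene] - 1, gene_rank[gene] + 1} & se_ranks:
            continue
        t = tss_by_gene[gene]
        k = int(rng.integers(3, 5))
        widths = rng.integers(800, 1_200, size=k)
        gaps = rng.integers(200, 400, size=k - 1) if k > 1 else np.array([], dtype=int)
        span = int(widths.sum() + gaps.sum())
        start0 = t.pos + 3_000
        if start0 + span > chrom_sizes[t.chrom] - 1_000:
            start0 = t.pos - 3_500 - span
        if start0 < 0:
            continue
        coords, cur = [], start0
        for j in range(k):
            coords.append((cur, cur + int(widths[j])))
            cur += int(widths[j]) + (int(gaps[j]) if j < k - 1 else 0)
        if any(occ_k27.blocked(t.chrom, s, e) or occ_k4.blocked(t.chrom, s, e)
               for s, e in coords):
            continue
        if occ_guard.blocked(t.chrom, coords[0][0] - _GUARD, coords[-1][1] + _GUARD):
            continue
        # cluster strengths kept well above the typical-enhancer tail so
        # every planted locus sits on the steep arm of the hockey stick
        base = float(rng.uniform(18.0, 40.0))
        for s, e in coords:
            occ_k27.add(t.chrom, s, e)
            rpm_ip = base * rng.uniform(0.7, 1.3)
            k27_peaks.append(
                Peak(GenomicInterval(t.chrom, s, e), (s + e) // 2, good_p(),
                     "H3K27ac", name=f"k27_{len(k27_peaks):05d}",
                     rpm_ip=rpm_ip, rpm_input=_INPUT_DENSITY * (e - s))
            )
        occ_guard.add(t.chrom, coords[0][0] - _GUARD, coords[-1][1] + _GUARD)
        se_genes.append(gene)
        se_ranks.add(gene_rank[gene])
        se_rows.append(dict(gene_id=gene, chrom=t.chrom,
                            cluster_start=coords[0][0], cluster_end=coords[-1][1]))

    # --- typical distal enhancers (heavy-tailed signal) -------------------
    tries = 0
    while len(k27_peaks) < n_k27 and tries < 50 * n_k27:
        tries += 1
        width = int(rng.integers(700, 2_000))
        spot = place_random(occ_k27, width, avoid_tss=True)
        if spot is None:
            break
        chrom, start = spot
        if occ_k4.blocked(chrom, start, start + width):
            continue
        if occ_guard.blocked(chrom, start, start + width):
            continue
        occ_k27.add(chrom, start, start + width)
        bad = rng.random() < 0.05
        pvalue = rng.uniform(0.011, 0.2) if bad else good_p()
        rpm_ip = 2.5 + (rng.pareto(config.se_tail_exponent) + 1.0) * 0.8
        k27_peaks.append(
            Peak(GenomicInterval(chrom, start, start + width),
                 start + width // 2, pvalue, "H3K27ac",
                 name=f"k27_{len(k27_peaks):05d}",
                 rpm_ip=rpm_ip, rpm_input=_INPUT_DENSITY * width)
        )

    # --- coverage consistent with the recorded RPM values ------------------
    for pk in k4_peaks:
        extra = max(0.0, pk.rpm_ip - _IP_BACKGROUND * pk.interval.width)
        _deposit(tracks["k4_ip"], pk.interval, extra, rng, config.noise_sd)
    for pk in k27_peaks:
        extra = max(0.0, pk.rpm_ip - _IP_BACKGROUND * pk.interval.width)
        _deposit(tracks["k27_ip"], pk.interval, extra, rng, config.noise_sd)

    # --- replicate tracks (10 kb bins, shared signal + Poisson noise) ------
    replicates: Dict[str, Tuple[CoverageTrack, CoverageTrack]] = {}
    for mark, src_name in (("h3k4me3", "k4_ip"), ("h3k27ac", "k27_ip")):
        src = tracks[src_name]
        reps = []
        for _ in range(2):
            rep = CoverageTrack.zeros(chrom_sizes, 10_000, _TOTAL_READS)
            for chrom, size in chrom_sizes.items():
                n_bins = -(-size // 10_000)
                lam = np.zeros(n_bins)
                fine = src.density[chrom]
                per_fine = config.bin_size
                for i in range(n_bins):
                    s, e = i * 10_000, min((i + 1) * 10_000, size)
                    lam[i] = fine[s // per_fine : -(-e // per_fine)].sum() * per_fine
                counts = rng.poisson(lam * 5.0 + 1.0)
                rep.density[chrom] = counts / 10_000.0
            reps.append(rep)
        replicates[mark] = (reps[0], reps[1])

    # --- planted expression structure --------------------------------------
    expr = ref.expression
    if len(expr):
        # SE target genes: floor the baseline (an SE-driven TF is expressed)
        # then apply the planted shift
        se_mask = expr.index.isin(se_genes)
        expr.loc[se_mask] = expr.loc[se_mask].clip(lower=2.0)
        expr.loc[se_mask] *= 2.0 ** config.de_effect_log2
        expr.loc[expr.index.isin(active_genes)] *= 2.0 ** config.active_promoter_effect_log2
        expr.loc[expr.index.isin(broad_genes)] *= 2.0 ** config.broad_domain_effect_log2
    ref.se_target_genes = se_genes
    ref.active_promoter_genes = active_genes
    ref.broad_domain_genes = broad_genes

    return PeaksBundle(
        h3k4me3=k4_peaks,
        h3k27ac=k27_peaks,
        tracks=tracks,
        replicates=replicates,
        se_truth=pd.DataFrame(
            se_rows, columns=["gene_id", "chrom", "cluster_start", "cluster_end"]
        ),
    )


# ---------------------------------------------------------------------------
# chain pair + planted conservation

@dataclass
class ChainPairBundle:
    target_chrom_sizes: Dict[str, int]
    chains: List[ChainAlignment]
    source_elements: List[Element]
    target_elements: List[Element]
    truth: pd.DataFrame  # element_id, status
    orthology: List[Tuple[str, str]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_chain(self.chains, outdir / "source_to_target.chain")
        gio.write_chrom_sizes(self.target_chrom_sizes, outdir / "target.chrom.sizes")
        gio.write_elements(self.source_elements, outdir / "source_elements.bed")
        gio.write_elements(self.target_elements, outdir / "target_elements.bed")
        gio.write_orthology(self.orthology, outdir / "orthology.tsv")
        self.truth.to_csv(outdir / "conservation_truth.tsv", sep="\t", index=False)


_BLOCK, _GAP, _UNIT = 6_000, 4_000, 10_000


def _controlled_chain_pair(config: SyntheticConfig, ref: ReferenceBundle,
                           rng: np.random.Generator) -> ChainPairBundle:
    """Slot-based construction: one 6 kb aligned block + 4 kb gap per
    element, so each planted status is exact by construction."""
    n = config.n_h3k27ac_peaks
    chroms = list(ref.chrom_sizes)
    capacity = {c: (size - 1_000) // _UNIT for c, size in ref.chrom_sizes.items()}
    if sum(capacity.values()) < n:
        raise SizingError(
            f"{n} elements need {n * _UNIT} bp of genome; have "
            f"{sum(ref.chrom_sizes.values())}"
        )
    statuses = rng.choice(
        ["functional", "sequence_only", "un_conserved"],
        size=n,
        p=[
            config.frac_functional,
            config.frac_sequence_only,
            1 - config.frac_functional - config.frac_sequence_only,
        ],
    )

    # distribute units evenly so every chromosome carries a chain
    per_chrom: Dict[str, int] = {}
    left = n
    for i, c in enumerate(chroms):
        share = -(-left // (len(chroms) - i))
        take = min(capacity[c], share)
        per_chrom[c] = take
        left -= take
    if left > 0:  # spill remainder into whatever capacity is free
        for c in chroms:
            extra = min(capacity[c] - per_chrom[c], left)
            per_chrom[c] += extra
            left -= extra

    chains: List[ChainAlignment] = []
    source_elements: List[Element] = []
    target_elements: List[Element] = []
    truth_rows = []
    target_chrom_sizes: Dict[str, int] = {}
    idx = 0
    for ci, chrom in enumerate(chroms):
        n_units = per_chrom[chrom]
        if n_units == 0:
            continue
        t_chrom = f"t_{chrom}"
        reverse = ci == len(chroms) - 1 and len(chroms) > 1
        dqs = [
            int(rng.integers(2_500, 6_000)) if config.chain_with_indels else _GAP
            for _ in range(n_units - 1)
        ] + [0]
        blocks = [
            (_BLOCK, _GAP if j < n_units - 1 else 0, dqs[j]) for j in range(n_units)
        ]
        s_end = n_units * _UNIT - _GAP
        t_span = sum(sz + dq for sz, _, dq in blocks)
        t_size = t_span + 1_000
        chains.append(
            ChainAlignment(
                chain_id=ci + 1, score=1e6, s_chrom=chrom,
                s_size=ref.chrom_sizes[chrom], s_start=0, s_end=s_end,
                t_chrom=t_chrom, t_size=t_size,
                t_strand="-" if reverse else "+", t_start=0, t_end=t_span,
                blocks=blocks,
            )
        )
        target_chrom_sizes[t_chrom] = t_size

        cum_q = 0
        for j in range(n_units):
            block_s = j * _UNIT
            status = statuses[idx]
            if status == "un_conserved":
                start = block_s + _BLOCK + 1_000  # fully inside the gap
            else:
                start = block_s + int(rng.integers(500, _BLOCK - 2_000 - 500))
            el = Element(
                element_id=f"src_{idx:05d}",
                interval=GenomicInterval(chrom, start, start + 2_000),
                summit=start + 1_000,
                element_class="enhancer",
                rpm_ip=3.0,
            )
            source_elements.append(el)
            if status == "functional":
                q_s = cum_q + (start - block_s)
                if reverse:
                    f_lo, f_hi = t_size - (q_s + 2_000), t_size - q_s
                else:
                    f_lo, f_hi = q_s, q_s + 2_000
                target_elements.append(
                    Element(
                        element_id=f"tgt_{idx:05d}",
                        interval=GenomicInterval(t_chrom, f_lo, f_hi),
                        summit=(f_lo + f_hi) // 2,
                        element_class="enhancer",
                        rpm_ip=3.0,
                    )
                )
            truth_rows.append(dict(element_id=el.element_id, status=status))
            cum_q += _BLOCK + dqs[j]
            idx += 1

    orthology = [(g, f"t_{g}") for g in ref.genes["gene_id"]]
    return ChainPairBundle(
        target_chrom_sizes, chains, source_elements, target_elements,
        pd.DataFrame(truth_rows), orthology,
    )


def _random_chain_pair(config: SyntheticConfig, ref: ReferenceBundle,
                       source_elements: Sequence[Element],
                       rng: np.random.Generator) -> ChainPairBundle:
    """Chains with coverage ``chain_coverage`` laid independently of the
    elements; statuses planted after generator-side mapping (functional
    with probability ``frac_functional`` among mapped elements)."""
    from .conservation import LiftOverConfig, map_interval

    cov = config.chain_coverage
    chains: List[ChainAlignment] = []
    target_chrom_sizes: Dict[str, int] = {}
    chroms = list(ref.chrom_sizes)
    for ci, chrom in enumerate(chroms):
        size = ref.chrom_sizes[chrom]
        reverse = ci == len(chroms) - 1 and len(chroms) > 1
        blocks: List[Tuple[int, int, int]] = []
        pos = 0
        while True:
            block = int(rng.integers(8_000, 16_000))
            if pos + block > size - 1_000:
                break
            gap = int(round(block * (1 - cov) / cov)) if cov < 1 else 0
            if config.chain_with_indels and gap > 0:
                dq = int(rng.integers(max(0, gap - 2_000), gap + 2_000))
            else:
                dq = gap
            blocks.append((block, gap, dq))
            pos += block + gap
        if not blocks:
            raise SizingError(f"{chrom} too short for chain construction")
        blocks[-1] = (blocks[-1][0], 0, 0)
        s_end = sum(sz + dt for sz, dt, _ in blocks)
        t_span = sum(sz + dq for sz, _, dq in blocks)
        t_chrom, t_size = f"t_{chrom}", t_span + 1_000
        chains.append(
            ChainAlignment(
                chain_id=ci + 1, score=1e6, s_chrom=chrom, s_size=size,
                s_start=0, s_end=s_end, t_chrom=t_chrom, t_size=t_size,
                t_strand="-" if reverse else "+", t_start=0, t_end=t_span,
                blocks=blocks,
            )
        )
        target_chrom_sizes[t_chrom] = t_size

    lift = LiftOverConfig()
    mapped: List[Tuple[Element, GenomicInterval]] = []
    unmapped: List[Element] = []
    for el in source_elements:
        res = map_interval(el.interval, chains, lift)
        if res.mapped:
            mapped.append((el, res.target))
        else:
            unmapped.append(el)

    # plant functional status per element class (fractions hold within
    # every class, not just pooled)
    n_mapped = len(mapped)
    functional_flags = np.zeros(n_mapped, dtype=bool)
    tss = ref.tss_records()
    pos_by_chrom: Dict[str, np.ndarray] = {}
    for t in tss:
        pos_by_chrom.setdefault(t.chrom, []).append(t.pos)
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}

    def _dist(el: Element) -> float:
        pos = pos_by_chrom.get(el.interval.chrom)
        if pos is None or pos.size == 0:
            return np.inf
        mid = el.interval.midpoint
        j = np.searchsorted(pos, mid)
        cands = []
        if j > 0:
            cands.append(mid - pos[j - 1])
        if j < pos.size:
            cands.append(pos[j] - mid)
        return float(min(cands))

    # statuses are planted per connected component of overlapping source
    # elements (overlapping elements map to overlapping targets, so a
    # planted target for one would make its neighbours functional too)
    by_class: Dict[str, List[int]] = {}
    for i, (el, _) in enumerate(mapped):
        by_class.setdefault(el.element_class, []).append(i)
    for cls_indices in by_class.values():
        ordered = sorted(
            cls_indices,
            key=lambda i: (mapped[i][0].interval.chrom, mapped[i][0].interval.start),
        )
        groups: List[List[int]] = []
        cur_chrom, cur_end = None, None
        for i in ordered:
            iv = mapped[i][0].interval
            if cur_chrom == iv.chrom and iv.start < cur_end:
                groups[-1].append(i)
                cur_end = max(cur_end, iv.end)
            else:
                groups.append([i])
                cur_chrom, cur_end = iv.chrom, iv.end
        n_cls = len(cls_indices)
        n_funct = int(round(config.frac_functional * n_cls))
        if config.conservation_proximity_bias:
            # gene-proximal groups become functional first
            groups.sort(key=lambda g: min(_dist(mapped[i][0]) for i in g))
        else:
            rng.shuffle(groups)
        taken = 0
        for group in groups:
            if taken >= n_funct:
                break
            functional_flags[group] = True
            taken += len(group)

    target_elements: List[Element] = []
    truth_rows = []
    for (el, tgt), is_funct in zip(mapped, functional_flags):
        status = "functional" if is_funct else "sequence_only"
        if is_funct:
            target_elements.append(
                Element(
                    element_id=f"tgt_{el.element_id}",
                    interval=tgt,
                    summit=tgt.midpoint,
                    element_class=el.element_class,
                    rpm_ip=3.0,
                )
            )
        truth_rows.append(dict(element_id=el.element_id, status=status))
    for el in unmapped:
        truth_rows.append(dict(element_id=el.element_id, status="un_conserved"))

    orthology = [(g, f"t_{g}") for g in ref.genes["gene_id"]]
    return ChainPairBundle(
        target_chrom_sizes, chains, list(source_elements), target_elements,
        pd.DataFrame(truth_rows), orthology,
    )


def generate_chain_pair(
    config: SyntheticConfig,
    ref: ReferenceBundle,
    source_elements: Optional[Sequence[Element]] = None,
) -> ChainPairBundle:
    """Second-species coordinate system, chain file, one-to-one orthology
    and target element sets with planted conservation statuses.

    Without ``source_elements`` the construction is slot-based and exact:
    each element gets its own aligned block (mappable) or chain gap
    (un-mappable) and statuses are drawn at the configured fractions.
    With ``source_elements`` (e.g. the pipeline's own standardized
    enhancers) chains are laid independently at ``chain_coverage`` and
    statuses are planted after generator-side mapping.
    """
    rng = config.rng(_STREAM_CHAIN)
    if source_elements is None:
        return _controlled_chain_pair(config, ref, rng)
    return _random_chain_pair(config, ref, source_elements, rng)


# ---------------------------------------------------------------------------
# chromatin-state segmentation for the overlay stage

_TISSUES = ("kidney", "heart", "lung", "muscle", "brain", "spleen")
#: kidney contributes most of the regulatory states
_TISSUE_WEIGHTS = (0.45, 0.13, 0.12, 0.11, 0.10, 0.09)


def generate_state_segments(
    config: SyntheticConfig,
    mapped_elements: Sequence[Tuple[str, GenomicInterval]],
) -> Tuple[List[StateSegment], Dict[str, str], pd.DataFrame]:
    """Target-species chromatin-state segments over the mapped coordinates
    of sequence-only conserved elements.  A fraction
    ``frac_seqonly_regulatory`` of elements is planted with a regulatory
    state (active enhancer / weak enhancer / primary DNase) in at least one
    tissue; the rest see only quiescent states."""
    rng = config.rng(_STREAM_STATES)
    segments: List[StateSegment] = []
    truth_rows = []
    reg_states = ("EnhA", "EnhWk", "DNase")
    for element_id, iv in mapped_elements:
        regulatory = rng.random() < config.frac_seqonly_regulatory
        chosen: List[str] = []
        if regulatory:
            n_t = 1 + int(rng.binomial(2, 0.4))
            chosen = list(
                rng.choice(_TISSUES, size=n_t, replace=False, p=_TISSUE_WEIGHTS)
            )
        for tissue in _TISSUES:
            # small padding keeps segments from bleeding onto neighbours
            pad_s, pad_e = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            seg_iv = GenomicInterval(iv.chrom, max(0, iv.start - pad_s), iv.end + pad_e)
            if tissue in chosen:
                label = reg_states[int(rng.choice(3, p=[0.4, 0.35, 0.25]))]
                segments.append(StateSegment(seg_iv, label, tissue))
            elif rng.random() < 0.6:
                segments.append(StateSegment(seg_iv, "Quies", tissue))
        truth_rows.append(dict(element_id=element_id, regulatory=regulatory,
                               n_tissues=len(chosen)))
    return segments, dict(DEFAULT_CATEGORY_MAP), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# differential-expression statistics

def generate_de_stats(
    config: SyntheticConfig, gene_ids: Sequence[str]
) -> Tuple[pd.DataFrame, Dict[str, set]]:
    """Per-gene cross-species DE statistics (log2 fold, p-value) with a
    planted DE set: ~8% of genes at |log2FC| >= de_effect_log2 and tiny
    p-values, half up and half down; the rest null."""
    rng = config.rng(_STREAM_DE)
    n = len(gene_ids)
    n_de = max(4, int(round(0.08 * n))) if n >= 8 else 0
    idx = rng.permutation(n)
    up = set(np.asarray(gene_ids)[idx[: n_de // 2]])
    down = set(np.asarray(gene_ids)[idx[n_de // 2 : n_de]])
    rows = []
    for g in gene_ids:
        if g in up or g in down:
            lfc = config.de_effect_log2 + rng.exponential(0.5)
            if g in down:
                lfc = -lfc
            p = 10.0 ** (-rng.uniform(4, 10))
        else:
            lfc = rng.normal(0, 0.5)
            p = rng.uniform(0.002, 1.0)
        rows.append(dict(gene_id=g, log2_fold=lfc, pvalue=p))
    df = pd.DataFrame(rows).set_index("gene_id")
    return df, {"up": up, "down": down}


# ---------------------------------------------------------------------------
# PWMs with planted motif occurrences

def generate_pwm_set(
    config: SyntheticConfig,
    tf_names: Sequence[str],
    motif_len: int = 10,
) -> Tuple[Dict[str, PWM], Dict[str, str]]:
    """One near-deterministic PWM per TF built from a random k-mer
    (probability 0.97 on the consensus base).  Returns the PWMs and the
    consensus k-mers used for planting occurrences."""
    if not tf_names:
        raise ValueError("tf_names must be non-empty")
    rng = config.rng(_STREAM_PWM)
    bases = "ACGT"
    pwms: Dict[str, PWM] = {}
    kmers: Dict[str, str] = {}
    seen = set()
    for tf in tf_names:
        while True:
            kmer = "".join(bases[i] for i in rng.integers(0, 4, size=motif_len))
            if kmer not in seen:
                seen.add(kmer)
                break
        mat = np.full((motif_len, 4), 0.01)
        for i, b in enumerate(kmer):
            mat[i, bases.index(b)] = 0.97
        pwms[tf] = PWM(tf, mat)
        kmers[tf] = kmer
    return pwms, kmers


def plant_motif(sequence: str, kmer: str, positions: Sequence[int]) -> str:
    """Overwrite ``sequence`` with ``kmer`` at each position (exact match
    retrievable by string search)."""
    seq = list(sequence)
    for pos in positions:
        if pos < 0 or pos + len(kmer) > len(seq):
            raise ValueError(f"planted position {pos} outside sequence")
        seq[pos : pos + len(kmer)] = kmer
    return "".join(seq)
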