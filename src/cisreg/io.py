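"""Readers and writers for the text formats the pipeline exchanges.

Strict about coordinate conventions: everything in memory is 0-based
half-open; GTF (1-based inclusive) is converted on read and write, and
chain-file reverse-strand coordinates keep the UCSC convention inside
:class:`~cisreg.core.ChainAlignment` (reflection happens in the mapper).

narrowPeak / broadPeak / BED6 / bedGraph / UCSC chain / TSV / FASTA /
MEME-minimal PWM text are the only formats touched; nothing here parses
binary formats.
"""

from __future__ import annotations

import math
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ChainAlignment, Element, GenomicInterval, Peak, StateSegment, TSSRecord

__all__ = [
    "FormatError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_fasta",
    "read_fasta",
    "write_gtf",
    "read_tss",
    "read_peaks",
    "write_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_chain",
    "write_chain",
    "read_elements",
    "write_elements",
    "read_expression",
    "write_expression",
    "read_orthology",
    "write_orthology",
    "read_meme_pwms",
    "write_meme_pwms",
    "read_state_bed",
    "write_state_bed",
    "read_category_map",
    "write_category_map",
]


class FormatError(ValueError):
    """A file violated its declared dialect; names the offending line."""

    def __init__(self, path, lineno: Optional[int], message: str):
        loc = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{loc}: {message}")


# ---------------------------------------------------------------------------
# chrom.sizes and FASTA

def read_chrom_sizes(path) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(path, lineno, "expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sizes:
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Whole-file read; for random access use pyfaidx directly."""
    seqs: Dict[str, str] = {}
    name = None
    parts: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


# ---------------------------------------------------------------------------
# gene annotation

def write_gtf(genes: Iterable[Tuple[str, str, int, int, str]], path) -> None:
    """Write gene features. ``genes`` yields (gene_id, chrom, start, end,
    strand) in 0-based half-open coordinates; the file is 1-based inclusive."""
    with open(path, "w") as fh:
        for gene_id, chrom, start, end, strand in genes:
            fh.write(
                f"{chrom}\tcisreg\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}";\n'
            )


def read_tss(
    path,
    expression: Optional[Dict[str, float]] = None,
) -> List[TSSRecord]:
    """Extract one TSS per gene from a GTF (gene features) or BED6 file.

    TSS convention (0-based): ``start`` for + strand, ``end - 1`` for -
    strand.  A missing strand is an error — a TSS is undefined without it.
    ``expression`` optionally supplies TPM per gene id (default 0).
    """
    expression = expression or {}
    records: List[TSSRecord] = []
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        import gffutils

        with open(path) as fh:
            if not any(line.strip() and not line.startswith("#") for line in fh):
                return []  # empty annotation: no genes, no TSS
        try:
            db = gffutils.create_db(
                path, dbfn=":memory:", force=True, keep_order=True,
                merge_strategy="create_unique",
                disable_infer_genes=True, disable_infer_transcripts=True,
            )
        except Exception as exc:  # gffutils raises its own error classes
            raise FormatError(path, None, f"unreadable GTF: {exc}") from exc
        for feat in db.all_features():
            if feat.featuretype not in ("gene", "transcript"):
                continue
            if feat.strand not in ("+", "-"):
                raise FormatError(
                    path, None,
                    f"feature {feat.id}: strand {feat.strand!r} invalid; "
                    "TSS requires +/-",
                )
            gene_id = feat.attributes.get("gene_id", [feat.id])[0]
            # gffutils keeps GTF 1-based inclusive coordinates
            start0, end0 = feat.start - 1, feat.end
            pos = start0 if feat.strand == "+" else end0 - 1
            records.append(
                TSSRecord(gene_id, feat.seqid, pos, feat.strand,
                          float(expression.get(gene_id, 0.0)))
            )
        return records
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(path, lineno, "BED6 needs 6 columns")
            chrom, gene_id, strand = fields[0], fields[3], fields[5]
            start, end = int(fields[1]), int(fields[2])
            if strand not in ("+", "-"):
                raise FormatError(
                    path, lineno, f"strand {strand!r} invalid; TSS requires +/-"
                )
            pos = start if strand == "+" else end - 1
            records.append(
                TSSRecord(gene_id, chrom, pos, strand, float(expression.get(gene_id, 0.0)))
            )
    return records


# ---------------------------------------------------------------------------
# peaks (MACS2 narrowPeak / broadPeak dialects)

def _decode_log10(x: float) -> float:
    return min(1.0, 10.0 ** (-x))


def read_peaks(path, mark: str) -> List[Peak]:
    """Read narrowPeak (10 columns, summit offset in column 10) or
    broadPeak (9 columns; summit := interval midpoint).  The p-value column
    carries -log10(p), MACS2 convention."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 10:
                offset = int(fields[9])
                summit_from = "offset"
            elif len(fields) == 9:
                offset = None
                summit_from = "midpoint"
            else:
                raise FormatError(
                    path, lineno,
                    f"expected 9 (broadPeak) or 10 (narrowPeak) columns, got {len(fields)}",
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            interval = GenomicInterval(chrom, start, end)
            if summit_from == "offset":
                summit = start + offset
                if not (start <= summit < end):
                    raise FormatError(
                        path, lineno, f"summit {summit} outside [{start},{end})"
                    )
            else:
                summit = interval.midpoint
            signal = float(fields[6])
            peaks.append(
                Peak(
                    interval=interval,
                    summit=summit,
                    pvalue=_decode_log10(float(fields[7])),
                    mark=mark,
                    name=fields[3],
                    rpm_ip=signal if signal >= 0 else None,
                )
            )
    return peaks


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "narrowPeak") -> None:
    if dialect not in ("narrowPeak", "broadPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            mlog10 = -math.log10(pk.pvalue)
            signal = -1.0 if pk.rpm_ip is None else pk.rpm_ip
            score = int(min(1000, max(0, round(10 * mlog10))))
            base = (
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pk.name}\t{score}\t.\t"
                f"{signal:.6g}\t{mlog10:.6g}\t-1"
            )
            if dialect == "narrowPeak":
                fh.write(base + f"\t{pk.summit - iv.start}\n")
            else:
                fh.write(base + "\n")


# ---------------------------------------------------------------------------
# bedGraph (with a total-reads comment for RPM normalization)

def read_bedgraph(path) -> Tuple[Dict[str, List[Tuple[int, int, float]]], float]:
    """Return per-chromosome (start, end, value) runs plus the declared
    total mapped reads (``# total_reads=N`` comment, required for RPM)."""
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                if "total_reads=" in line:
                    total = float(line.split("total_reads=")[1])
                continue
            if not line.strip() or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(path, lineno, "bedGraph needs 4 columns")
            runs.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    if total is None:
        raise FormatError(path, None, "missing '# total_reads=' header")
    return runs, total


def write_bedgraph(
    runs: Dict[str, Iterable[Tuple[int, int, float]]], total_reads: float, path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_reads={total_reads:.6f}\n")
        for chrom, chrom_runs in runs.items():
            for start, end, value in chrom_runs:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# UCSC chain

def read_chain(path) -> List[ChainAlignment]:
    chains: List[ChainAlignment] = []
    header = None
    blocks: List[Tuple[int, int, int]] = []

    def _finish(lineno):
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise FormatError(path, lineno, f"chain {header.chain_id} truncated")
        header.blocks = blocks.copy()
        try:
            header.validate()
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
        chains.append(header)

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if fields[0] == "chain":
                _finish(lineno)
                if len(fields) != 13:
                    raise FormatError(path, lineno, "chain header needs 13 fields")
                (_, score, s_chrom, s_size, s_strand, s_start, s_end,
                 t_chrom, t_size, t_strand, t_start, t_end, chain_id) = fields
                header = ChainAlignment(
                    chain_id=int(chain_id),
                    score=float(score),
                    s_chrom=s_chrom,
                    s_size=int(s_size),
                    s_start=int(s_start),
                    s_end=int(s_end),
                    t_chrom=t_chrom,
                    t_size=int(t_size),
                    t_strand=t_strand,
                    t_start=int(t_start),
                    t_end=int(t_end),
                    blocks=[],
                    s_strand=s_strand,
                )
                blocks = []
            elif len(fields) == 3:
                blocks.append((int(fields[0]), int(fields[1]), int(fields[2])))
            elif len(fields) == 1:
                blocks.append((int(fields[0]), 0, 0))
            else:
                raise FormatError(path, lineno, f"unparseable chain line {line!r}")
        if header is None:
            raise FormatError(path, None, "no chain records found")
        _finish(lineno)
    return chains


def write_chain(chains: Sequence[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            ch.validate()
            fh.write(
                f"chain {ch.score:.0f} {ch.s_chrom} {ch.s_size} {ch.s_strand} "
                f"{ch.s_start} {ch.s_end} {ch.t_chrom} {ch.t_size} "
                f"{ch.t_strand} {ch.t_start} {ch.t_end} {ch.chain_id}\n"
            )
            for size, dt, dq in ch.blocks[:-1]:
                fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write(f"{ch.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# classified elements (BED6 + class/signal columns)

_ELEMENT_COLUMNS = (
    "chrom start end element_id score strand element_class summit "
    "rpm_ip rpm_input linked_gene clipped source_ids"
).split()


def write_elements(elements: Sequence[Element], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ELEMENT_COLUMNS) + "\n")
        for el in elements:
            iv = el.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        el.element_id,
                        "0",
                        iv.strand,
                        el.element_class,
                        str(el.summit),
                        "." if el.rpm_ip is None else f"{el.rpm_ip:.6f}",
                        "." if el.rpm_input is None else f"{el.rpm_input:.6f}",
                        el.linked_gene or ".",
                        "1" if el.clipped else "0",
                        ",".join(el.source_ids) or ".",
                    ]
                )
                + "\n"
            )


def read_elements(path) -> List[Element]:
    elements: List[Element] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_ELEMENT_COLUMNS):
                raise FormatError(
                    path, lineno, f"expected {len(_ELEMENT_COLUMNS)} columns"
                )
            elements.append(
                Element(
                    element_id=f[3],
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    summit=int(f[7]),
                    element_class=f[6],
                    source_ids=tuple(f[12].split(",")) if f[12] != "." else (),
                    rpm_ip=None if f[8] == "." else float(f[8]),
                    rpm_input=None if f[9] == "." else float(f[9]),
                    linked_gene=None if f[10] == "." else f[10],
                    clipped=f[11] == "1",
                )
            )
    return elements


# ---------------------------------------------------------------------------
# expression / orthology tables

def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_orthology(pairs: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\thomology_type\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\tone2one\n")


def read_orthology(path) -> Dict[str, str]:
    """Return a one-to-one gene_a -> gene_b map; other homology types are
    skipped."""
    df = pd.read_csv(path, sep="\t")
    df = df[df["homology_type"] == "one2one"]
    return dict(zip(df["gene_a"], df["gene_b"]))


# ---------------------------------------------------------------------------
# MEME-minimal PWM text

def write_meme_pwms(
    pwms: Dict[str, np.ndarray],
    path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    nsites: int = 1_000_000,
) -> None:
    """Write probability matrices (w x 4, ACGT order) in MEME minimal text."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*background)
        )
        for name, mat in pwms.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != 4:
                raise ValueError(f"PWM {name}: expected w x 4 matrix")
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_pwms(path) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Parse MEME minimal motif text via Biopython; returns probability
    matrices (w x 4, ACGT order) and the background frequencies."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out: Dict[str, np.ndarray] = {}
    background = np.array([0.25, 0.25, 0.25, 0.25])
    for m in parsed:
        counts = np.array(
            [[m.counts[base][i] for base in "ACGT"] for i in range(m.length)],
            dtype=float,
        )
        out[m.name] = counts / counts.sum(axis=1, keepdims=True)
        if m.background:
            background = np.array([m.background[b] for b in "ACGT"], dtype=float)
    return out, background


# ---------------------------------------------------------------------------
# chromatin-state segmentation and category map

def write_state_bed(segments: Sequence[StateSegment], path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            iv = seg.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state_label}\t{seg.tissue}\n"
            )


def read_state_bed(path) -> List[StateSegment]:
    segments: List[StateSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise FormatError(path, lineno, "state BED needs 5 columns")
            segments.append(
                StateSegment(GenomicInterval(f[0], int(f[1]), int(f[2])), f[3], f[4])
            )
    return segments


def write_category_map(mapping: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("state_label\tcategory\n")
        for state, cat in mapping.items():
            fh.write(f"{state}\t{cat}\n")


def read_category_map(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["state_label"], df["category"]))
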