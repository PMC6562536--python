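"""Core transcriptional regulatory circuitry (CRC).

A CRC is the fully interconnected, auto-regulatory core of super-enhancer
driven transcription factors: a TF is a node when its own motif occurs in
its own super-enhancer constituent sequences, a directed edge A -> B means
A's motif occurs in B's constituents, and circuitries are the maximal sets
of mutually (bidirectionally) connected nodes.

Motif occurrence uses a log-odds bit-score scan of position weight
matrices over both strands (default threshold 6 bits) rather than FIMO's
p-value machinery; the threshold is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "PWM",
    "Hit",
    "scan_pwm",
    "candidate_tfs",
    "CRCGraph",
    "build_crc",
    "compare_crcs",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DEFAULT_SCAN_THRESHOLD = 6.0  # bits
MAX_CRC_NODES = 64


@dataclass
class PWM:
    """A position weight matrix: ``matrix`` is positions x 4 (ACGT order)
    base probabilities; rows are renormalized to sum to 1 after adding
    ``pseudocount``.  A position with zero total probability is degenerate
    and rejected."""

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError(f"PWM {self.tf_name}: matrix must be w x 4")
        if np.any(mat < 0):
            raise ValueError(f"PWM {self.tf_name}: negative probabilities")
        row_sums = mat.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError(f"PWM {self.tf_name}: degenerate all-zero position")
        mat = mat + self.pseudocount
        self.matrix = mat / mat.sum(axis=1, keepdims=True)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: Sequence[float]) -> np.ndarray:
        q = np.asarray(background, dtype=float)
        return np.log2(self.matrix / q)

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.matrix[::-1, ::-1].copy(), pseudocount=0.0)


@dataclass(frozen=True)
class Hit:
    position: int  # forward-strand start of the motif window
    strand: str
    score: float


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window; N bases contribute 0 (background odds)."""
    w = log_odds.shape[0]
    n_windows = codes.size - w + 1
    if n_windows <= 0:
        return np.empty(0)
    lo_ext = np.vstack([log_odds.T, np.zeros(w)]).T  # row for N -> 0
    scores = np.zeros(n_windows)
    for j in range(w):
        scores += lo_ext[j, codes[j : j + n_windows]]
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    threshold: float = DEFAULT_SCAN_THRESHOLD,
) -> List[Hit]:
    """Both-strand log-odds scan.  A hit is any window whose summed
    log2(p/q) score reaches ``threshold`` bits; reverse-strand hits are
    reported at the forward coordinate of the window start.  Sequences
    shorter than the motif yield no hits."""
    seq = sequence.upper()
    if any(c not in _BASE_INDEX for c in seq):
        bad = sorted({c for c in seq if c not in _BASE_INDEX})
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    codes = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    hits: List[Hit] = []
    for strand, lo in (
        ("+", pwm.log_odds(background)),
        ("-", pwm.reverse_complement().log_odds(background)),
    ):
        scores = _window_scores(codes, lo)
        for pos in np.flatnonzero(scores >= threshold):
            hits.append(Hit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def candidate_tfs(
    se_gene_map: Dict[str, Sequence[str]],
    tf_list: Sequence[str],
    expression: Dict[str, float],
    min_tpm: float = 1.0,
) -> List[str]:
    """TFs that are assigned a super-enhancer and expressed at >= min_tpm."""
    if not tf_list:
        raise ValueError("empty TF list")
    se_genes = {g for genes in se_gene_map.values() for g in genes}
    return sorted(
        tf
        for tf in tf_list
        if tf in se_genes and expression.get(tf, 0.0) >= min_tpm
    )


@dataclass
class CRCGraph:
    nodes: List[str]                       # auto-regulated TFs
    edges: Set[Tuple[str, str]]            # directed, A -> B
    cliques: List[Tuple[str, ...]]         # maximal mutually connected sets

    def clique_members(self) -> Set[str]:
        return {tf for clique in self.cliques for tf in clique}


def build_crc(
    candidates: Sequence[str],
    constituent_sequences: Dict[str, Sequence[str]],
    pwms: Dict[str, PWM],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    threshold: float = DEFAULT_SCAN_THRESHOLD,
) -> CRCGraph:
    """Build the auto-regulatory TF graph and enumerate its circuitries.

    A candidate without a PWM is excluded with a warning; a node survives
    only if its own motif hits its own super-enhancer constituents.  Maximal
    cliques of the mutual (bidirectional) graph are enumerated exactly
    (Bron-Kerbosch); graphs above 64 nodes are refused.
    """
    usable = []
    for tf in candidates:
        if tf not in pwms:
            warnings.warn(f"candidate TF {tf} has no PWM; excluded")
            continue
        if tf not in constituent_sequences or not constituent_sequences[tf]:
            raise ValueError(f"candidate TF {tf} has no constituent sequences")
        usable.append(tf)
    if len(usable) > MAX_CRC_NODES:
        raise ValueError(
            f"{len(usable)} candidate TFs exceeds the {MAX_CRC_NODES}-node cap"
        )

    def _hits(tf_motif: str, tf_target: str) -> bool:
        pwm = pwms[tf_motif]
        return any(
            scan_pwm(seq, pwm, background, threshold)
            for seq in constituent_sequences[tf_target]
        )

    nodes = [tf for tf in usable if _hits(tf, tf)]
    edges: Set[Tuple[str, str]] = {(tf, tf) for tf in nodes}
    for a in nodes:
        for b in nodes:
            if a != b and _hits(a, b):
                edges.add((a, b))

    mutual = nx.Graph()
    mutual.add_nodes_from(nodes)
    for a, b in edges:
        if a < b and (b, a) in edges:
            mutual.add_edge(a, b)
    cliques = sorted(
        (tuple(sorted(c)) for c in nx.find_cliques(mutual)),
        key=lambda c: (-len(c), c),
    )
    return CRCGraph(nodes=sorted(nodes), edges=edges, cliques=cliques)


def compare_crcs(crc_by_species: Dict[str, Iterable[str]]) -> Dict[str, object]:
    """Shared and species-specific circuitry TFs, matched case-insensitively
    on (orthologous) TF names.

    Reports the intersection across all species, per-species specific sets,
    and — because "consistency" can be read as all-species or any-two-species
    sharing — both the fraction of each species' TFs shared by all and the
    fraction shared by at least two species.
    """
    if len(crc_by_species) < 2:
        raise ValueError("need CRCs from at least two species")
    sets = {
        sp: {tf.upper() for tf in tfs} for sp, tfs in crc_by_species.items()
    }
    shared_all = set.intersection(*sets.values())
    specific = {
        sp: s - set.union(*(o for k, o in sets.items() if k != sp))
        for sp, s in sets.items()
    }
    shared_two = {
        tf
        for sp, s in sets.items()
        for tf in s
        if any(tf in o for k, o in sets.items() if k != sp)
    }
    return {
        "shared_all": sorted(shared_all),
        "specific": {sp: sorted(v) for sp, v in specific.items()},
        "shared_at_least_two": sorted(shared_two),
        "fraction_shared_all": {
            sp: len(shared_all) / len(s) if s else 0.0 for sp, s in sets.items()
        },
        "fraction_shared_at_least_two": {
            sp: len(s & shared_two) / len(s) if s else 0.0
            for sp, s in sets.items()
        },
    }
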