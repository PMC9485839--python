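"""Core regulatory circuitry inference.

Candidate circuitry factors are transcription factors that (a) are the
assigned target of at least one super-enhancer and (b) are expressed above a
cutoff (default 33, in the units of the supplied normalized matrix).  Each
factor's motif (JASPAR PFM converted to a log-odds PWM) is scanned over every
factor's super-enhancer constituents extended by 500 bp on each side; an edge
A -> B means A's motif occurs in B's extended constituents.  Core circuits
are the maximal cliques of the bidirectional subgraph restricted to
autoregulating factors (self-edge required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .consensus import ConsensusSE
from .intervals import GenomicInterval
from .io import MotifPFM
from .linking import SEGeneLink
from .rose import StitchedRegion

__all__ = [
    "PWM",
    "MotifHit",
    "TFNode",
    "CRCNetwork",
    "pwm_from_pfm",
    "scan",
    "reverse_complement",
    "candidate_crc_tfs",
    "build_network",
    "find_crcs",
]

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """4 x L log2-odds matrix with its maximum achievable score."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        if not np.isfinite(m).all():
            raise ValueError("PWM entries must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    position: int      # 0-based start on the forward strand
    strand: str        # "+" or "-"
    score: float


@dataclass(frozen=True)
class TFNode:
    tf_id: str
    se_id: str
    expression: float


@dataclass
class CRCNetwork:
    """Directed motif-occurrence graph over TFs, with its circuitry cliques."""

    nodes: list[TFNode]
    edges: set[tuple[str, str]]                 # (A, B): A's motif in B's SE
    cliques: list[tuple[str, ...]] = field(default_factory=list)
    tf_frequency: dict[str, float] = field(default_factory=dict)


def pwm_from_pfm(
    pfm: MotifPFM,
    pseudocount: float = 0.5,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """log2((count + pc) / (colsum + 4*pc) / background) per cell."""
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
    matrix = np.log2(probs / np.asarray(background)[:, None])
    return PWM(pfm.motif_id, matrix)


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int64)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _scan_strand(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Window scores at each start position; NaN where the window has an N."""
    L = matrix.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = matrix[safe, np.arange(L)].sum(axis=1)
    scores[has_n] = np.nan
    return scores


def scan(sequence: str, pwm: PWM, score_fraction: float = 0.8) -> list[MotifHit]:
    """Scan both strands; hit iff score >= score_fraction * max achievable.

    Windows containing N are skipped.  A minus-strand hit is reported at the
    forward-strand start of the window it occupies.
    """
    threshold = score_fraction * pwm.max_score
    hits: list[MotifHit] = []
    fwd = _scan_strand(_encode(sequence), pwm.matrix)
    for pos in np.nonzero(~np.isnan(fwd) & (fwd >= threshold))[0]:
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    rev = _scan_strand(_encode(reverse_complement(sequence)), pwm.matrix)
    n = len(sequence)
    L = pwm.length
    for pos in np.nonzero(~np.isnan(rev) & (rev >= threshold))[0]:
        hits.append(MotifHit(int(n - L - pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def candidate_crc_tfs(
    links: list[SEGeneLink],
    tf_catalog: dict[str, str],
    expression: "dict[str, float] | object",
    cutoff: float = 33.0,
) -> list[TFNode]:
    """TFs that target >= 1 SE and are expressed at or above the cutoff.

    ``tf_catalog`` maps gene id -> motif id; ``expression`` maps gene id ->
    normalized expression in the analyzed condition.
    """
    nodes = []
    seen: set[str] = set()
    for link in links:
        gid = link.gene_id
        if gid in seen or gid not in tf_catalog:
            continue
        expr = float(expression[gid]) if gid in expression else 0.0
        if expr >= cutoff:
            nodes.append(TFNode(tf_id=gid, se_id=link.se_id, expression=expr))
            seen.add(gid)
    nodes.sort(key=lambda n: n.tf_id)
    return nodes


def build_network(
    tf_nodes: list[TFNode],
    se_constituents: dict[str, list[GenomicInterval]],
    genome: dict[str, str],
    pwms: dict[str, PWM],
    tf_catalog: dict[str, str],
    extension: int = 500,
    score_fraction: float = 0.8,
) -> CRCNetwork:
    """Directed edges A -> B where A's motif hits B's extended constituents.

    Constituent peaks (not the stitched hull) are extended by ``extension``
    bp on each side, clipped to the chromosome, and scanned on both strands.
    """
    sequences: dict[str, list[str]] = {}
    for node in tf_nodes:
        consts = se_constituents.get(node.se_id)
        if not consts:
            raise ValueError(f"no constituents recorded for {node.se_id}")
        seqs = []
        for c in consts:
            if c.chrom not in genome:
                raise KeyError(f"no sequence for region {c.chrom}:{c.start}-{c.end}")
            chrom_seq = genome[c.chrom]
            lo = max(0, c.start - extension)
            hi = min(len(chrom_seq), c.end + extension)
            seqs.append(chrom_seq[lo:hi])
        sequences[node.tf_id] = seqs

    edges: set[tuple[str, str]] = set()
    for a in tf_nodes:
        pwm = pwms[tf_catalog[a.tf_id]]
        for b in tf_nodes:
            if any(scan(seq, pwm, score_fraction) for seq in sequences[b.tf_id]):
                edges.add((a.tf_id, b.tf_id))
    return CRCNetwork(nodes=list(tf_nodes), edges=edges)


def find_crcs(network: CRCNetwork) -> CRCNetwork:
    """Enumerate autoregulatory fully interconnected circuits.

    Nodes without a self-edge are excluded; the undirected support graph
    keeps pair (A, B) iff both A->B and B->A exist; maximal cliques are
    enumerated (Bron-Kerbosch) and sorted by size (descending) then
    lexicographically.  ``tf_frequency`` is the fraction of cliques
    containing each TF.
    """
    auto = sorted(n.tf_id for n in network.nodes if (n.tf_id, n.tf_id) in network.edges)
    g = nx.Graph()
    g.add_nodes_from(auto)
    for a in auto:
        for b in auto:
            if a < b and (a, b) in network.edges and (b, a) in network.edges:
                g.add_edge(a, b)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    freq: dict[str, float] = {}
    if cliques:
        for tf in auto:
            freq[tf] = sum(tf in c for c in cliques) / len(cliques)
    return CRCNetwork(
        nodes=list(network.nodes),
        edges=set(network.edges),
        cliques=cliques,
        tf_frequency=freq,
    )
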