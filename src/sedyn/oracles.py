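"""Naive reference implementations used to validate the fast code paths.

Each function here recomputes a quantity by direct enumeration (per-bp sets,
exhaustive scans, subset enumeration) and deliberately shares no code with
the implementation it checks.  They are quadratic-to-exponential and only
meant for small inputs.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "stitch_by_dilation",
    "elbow_by_tangent_scan",
    "coverage_area_per_bp",
    "scan_per_window",
    "maximal_cliques_bruteforce",
]


def stitch_by_dilation(
    peaks: list[GenomicInterval], stitch_distance: int
) -> list[frozenset[tuple[str, int, int]]]:
    """Group peaks by dilate-merge-contract.

    Every peak is widened by ``stitch_distance / 2`` on each side (kept exact
    with halves); groups are the connected components of strictly-overlapping
    dilated peaks.  Returns the set of member peaks per group, order-free.
    """
    half = Fraction(stitch_distance, 2)
    items = [(pk.chrom, Fraction(pk.start) - half, Fraction(pk.end) + half, i)
             for i, pk in enumerate(peaks)]
    n = len(items)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a in range(n):
        for b in range(a + 1, n):
            ca, sa, ea, _ = items[a]
            cb, sb, eb, _ = items[b]
            if ca == cb and sa < eb and sb < ea:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[int] = set()
    groups = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp.add(j)
            stack.extend(adj[j] - comp)
        seen |= comp
        groups.append(
            frozenset((peaks[j].chrom, peaks[j].start, peaks[j].end) for j in comp)
        )
    return groups


def elbow_by_tangent_scan(signals: list[float]) -> int | None:
    """Exhaustive tangent-point scan for the rank-curve elbow, with exact
    rational arithmetic.

    Sorts ascending, rescales both axes to [0, 1], computes every discrete
    segment slope as a Fraction, and returns the left index of the first
    segment (from the low end) whose slope reaches 1.  None when undefined.
    """
    s = sorted(Fraction(x).limit_denominator(10**12) if not isinstance(x, int) else Fraction(x)
               for x in signals)
    n = len(s)
    if n < 3 or s[0] == s[-1]:
        return None
    span = s[-1] - s[0]
    candidates = []
    for i in range(n - 1):
        dy = Fraction(s[i + 1] - s[i], 1) / span
        dx = Fraction(1, n - 1)
        if dy / dx >= 1:
            candidates.append(i)
    return candidates[0] if candidates else None


def coverage_area_per_bp(
    runs: list[tuple[str, int, int, float]], chrom: str, start: int, end: int
) -> float:
    """Coverage area over [start, end) by per-basepair accumulation."""
    total = 0.0
    for pos in range(start, end):
        for c, s, e, d in runs:
            if c == chrom and s <= pos < e:
                total += d
    return total


def scan_per_window(sequence: str, matrix: np.ndarray, threshold: float):
    """Per-window motif scan of both strands by direct indexing.

    Returns (position, strand, score) tuples; windows containing non-ACGT
    characters are skipped.  Minus-strand windows are scored on the reverse
    complement read right-to-left, reported at their forward start.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = matrix.shape[1]
    order = "ACGT"
    hits = []
    seq = sequence.upper()
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        if any(b not in order for b in window):
            continue
        fwd = sum(matrix[order.index(b), j] for j, b in enumerate(window))
        if fwd >= threshold:
            hits.append((pos, "+", fwd))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(matrix[order.index(b), j] for j, b in enumerate(rc))
        if rev >= threshold:
            hits.append((pos, "-", rev))
    return hits


def maximal_cliques_bruteforce(
    nodes: list[str], directed_edges: set[tuple[str, str]]
) -> list[tuple[str, ...]]:
    """Autoregulatory fully interconnected sets by subset enumeration.

    Keeps nodes with self-edges, then enumerates every subset of them and
    retains subsets in which every ordered pair has both directed edges;
    returns the maximal such subsets, sorted by size descending then
    lexicographically.  Exponential — fine up to ~15 nodes.
    """
    auto = sorted(v for v in nodes if (v, v) in directed_edges)
    valid = []
    for r in range(1, len(auto) + 1):
        for combo in combinations(auto, r):
            ok = all(
                (a, b) in directed_edges and (b, a) in directed_edges
                for a in combo for b in combo if a != b
            )
            if ok:
                valid.append(frozenset(combo))
    maximal = [
        s for s in valid if not any(s < t for t in valid)
    ]
    out = sorted((tuple(sorted(s)) for s in maximal), key=lambda c: (-len(c), c))
    return out
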