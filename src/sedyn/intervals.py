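"""Genomic interval and coverage-track primitives.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Chromosome names are matched by exact string comparison — no ``chr`` aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["GenomicInterval", "CoverageTrack", "merge_intervals", "sort_intervals"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional signal and name.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty, exact matching).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    signal : float, optional
        Non-negative signal value (e.g. narrowPeak ``signalValue``).
    name : str, optional
        Feature label.
    """

    chrom: str
    start: int
    end: int
    signal: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.signal is not None and self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosome or disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start, end)."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Union-merge intervals; two intervals join when ``next.start - prev.end < min_gap``
    or they overlap.  ``min_gap=0`` merges only strictly overlapping intervals
    (touching intervals stay separate); ``min_gap=1`` also joins book-ended ones.
    """
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and iv.chrom == merged[-1].chrom and iv.start < merged[-1].end + min_gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class CoverageTrack:
    """Per-chromosome run-length coverage (sorted, disjoint, depth >= 0).

    Stored as three parallel arrays per chromosome: starts, ends, depths.
    Zero-depth gaps are implicit; queries over uncovered bases return depth 0.
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]], merge_equal: bool = True
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, depth) runs; runs may be unsorted.

        Raises
        ------
        ValueError
            on negative depth or overlapping runs.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in runs:
            if depth < 0:
                raise ValueError(f"negative depth {depth} at {chrom}:{start}-{end}")
            if end <= start:
                raise ValueError(f"empty/inverted run {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(depth)))
        track = cls()
        for chrom, items in by_chrom.items():
            items.sort()
            prev_end = -1
            out: list[tuple[int, int, float]] = []
            for start, end, depth in items:
                if start < prev_end:
                    raise ValueError(f"overlapping runs on {chrom} at {start}")
                if merge_equal and out and out[-1][1] == start and out[-1][2] == depth:
                    out[-1] = (out[-1][0], end, depth)
                else:
                    out.append((start, end, depth))
                prev_end = end
            starts = np.array([r[0] for r in out], dtype=np.int64)
            ends = np.array([r[1] for r in out], dtype=np.int64)
            depths = np.array([r[2] for r in out], dtype=np.float64)
            track._runs[chrom] = (starts, ends, depths)
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        if chrom not in self._runs:
            return
        starts, ends, depths = self._runs[chrom]
        for s, e, d in zip(starts.tolist(), ends.tolist(), depths.tolist()):
            yield s, e, d

    def iter_all_runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for s, e, d in self.runs(chrom):
                yield chrom, s, e, d

    def n_runs(self) -> int:
        return sum(len(v[0]) for v in self._runs.values())

    def area(self, chrom: str, start: int, end: int) -> float:
        """Sum of depth x covered-bp over ``[start, end)`` (missing bases count 0)."""
        if chrom not in self._runs or end <= start:
            return 0.0
        starts, ends, depths = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(np.maximum(ov, 0) * depths[lo:hi]))

    def interval_area(self, interval: GenomicInterval) -> float:
        return self.area(interval.chrom, interval.start, interval.end)

    def total_area(self) -> float:
        total = 0.0
        for starts, ends, depths in self._runs.values():
            total += float(np.sum((ends - starts) * depths))
        return total

    def bin_areas(self, chrom: str, bin_width: int, chrom_length: int) -> np.ndarray:
        """Per-bin coverage area for fixed-width bins tiling ``[0, chrom_length)``.

        The final partial bin (if any) is included.
        """
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = int(np.ceil(chrom_length / bin_width))
        out = np.zeros(n_bins, dtype=np.float64)
        if chrom not in self._runs:
            return out
        starts, ends, depths = self._runs[chrom]
        for s, e, d in zip(starts.tolist(), ends.tolist(), depths.tolist()):
            e = min(e, chrom_length)
            if e <= s:
                continue
            b0, b1 = s // bin_width, (e - 1) // bin_width
            if b0 == b1:
                out[b0] += d * (e - s)
            else:
                out[b0] += d * ((b0 + 1) * bin_width - s)
                out[b1] += d * (e - b1 * bin_width)
                if b1 > b0 + 1:
                    out[b0 + 1 : b1] += d * bin_width
        return out

    @staticmethod
    def pool(tracks: Iterable["CoverageTrack"]) -> "CoverageTrack":
        """Sum several tracks into one (depths add; breakpoints are unioned)."""
        tracks = list(tracks)
        pooled = CoverageTrack()
        chroms = sorted({c for t in tracks for c in t.chroms})
        for chrom in chroms:
            cuts: set[int] = set()
            for t in tracks:
                for s, e, _ in t.runs(chrom):
                    cuts.add(s)
                    cuts.add(e)
            edges = np.array(sorted(cuts), dtype=np.int64)
            seg_starts, seg_ends = edges[:-1], edges[1:]
            depth = np.zeros(len(seg_starts), dtype=np.float64)
            for t in tracks:
                for s, e, d in t.runs(chrom):
                    i0 = int(np.searchsorted(seg_starts, s))
                    i1 = int(np.searchsorted(seg_starts, e))
                    depth[i0:i1] += d
            keep = depth != 0
            pooled._runs[chrom] = (
                seg_starts[keep].copy(),
                seg_ends[keep].copy(),
                depth[keep].copy(),
            )
        return pooled
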