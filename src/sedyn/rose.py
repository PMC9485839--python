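"""ROSE-style super-enhancer calling.

Constituent H3K27ac peaks closer than a stitching distance (default 12.5 kb)
are merged into stitched regions; each region is scored by input-subtracted
H3K27ac area over its constituents only (valleys between constituents would
dilute the signal and are excluded); regions are ranked by signal and the
super-enhancer cutoff is the elbow of the rank curve — the point where the
slope of the [0,1]x[0,1]-rescaled ascending signal curve reaches 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import CoverageTrack, GenomicInterval, sort_intervals

__all__ = ["RoseConfig", "StitchedRegion", "stitch", "score_region",
           "call_superenhancers", "elbow_cutoff_index"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoseConfig:
    """Stitching parameters.

    stitch_distance : bp; peaks whose gap (next.start - prev.end) is strictly
        below this are joined (default 12500).
    tss_exclusion : if True, peaks overlapping a TSS +/- ``tss_window`` are
        dropped before stitching.  Off by default: the analysis this package
        implements stitches without TSS removal.
    """

    stitch_distance: int = 12500
    tss_exclusion: bool = False
    tss_window: int = 2500
    signal_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")


@dataclass
class StitchedRegion:
    """A stitched region and its constituent peaks.

    ``signal`` is the input-subtracted H3K27ac area (>= 0); ``rank`` is
    1 for the highest-signal region; ``is_super`` marks regions above the
    rank-curve elbow.
    """

    interval: GenomicInterval
    constituents: list[GenomicInterval]
    signal: float = 0.0
    rank: int | None = None
    is_super: bool = False

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


def stitch(
    peaks: list[GenomicInterval],
    config: RoseConfig = RoseConfig(),
    tss_positions: list[tuple[str, int]] | None = None,
) -> list[StitchedRegion]:
    """Merge peaks into stitched regions.

    Two peaks belong to the same region iff a chain of peaks connects them in
    which every consecutive gap (``next.start - prev.end``) is strictly less
    than ``config.stitch_distance``.  Output is sorted by (chrom, start).
    """
    if config.tss_exclusion and tss_positions:
        keep = []
        for pk in peaks:
            near_tss = any(
                chrom == pk.chrom and pk.start - config.tss_window < pos < pk.end + config.tss_window
                for chrom, pos in tss_positions
            )
            if not near_tss:
                keep.append(pk)
        peaks = keep

    regions: list[StitchedRegion] = []
    current: list[GenomicInterval] = []
    for pk in sort_intervals(peaks):
        if current and pk.chrom == current[-1].chrom and pk.start - _chain_end(current) < config.stitch_distance:
            current.append(pk)
        else:
            if current:
                regions.append(_make_region(current))
            current = [pk]
    if current:
        regions.append(_make_region(current))
    return regions


def _chain_end(chain: list[GenomicInterval]) -> int:
    return max(iv.end for iv in chain)


def _make_region(chain: list[GenomicInterval]) -> StitchedRegion:
    start = min(iv.start for iv in chain)
    end = max(iv.end for iv in chain)
    return StitchedRegion(
        interval=GenomicInterval(chain[0].chrom, start, end),
        constituents=list(chain),
    )


def score_region(
    region: StitchedRegion, treatment: CoverageTrack, input_track: CoverageTrack | None
) -> float:
    """Input-subtracted H3K27ac area over the region's constituents.

    ``max(0, sum area(treatment) - sum area(input))`` — never negative;
    bases absent from a track contribute depth 0.
    """
    t = sum(treatment.interval_area(c) for c in region.constituents)
    i = 0.0
    if input_track is not None:
        i = sum(input_track.interval_area(c) for c in region.constituents)
    return max(0.0, t - i)


def elbow_cutoff_index(signals: np.ndarray) -> int | None:
    """Index (into the ascending-sorted signal vector) of the elbow cutoff.

    The ascending signals are rescaled so rank index and signal both span
    [0, 1]; scanning from the low end, the cutoff is the left endpoint of the
    first segment whose discrete slope reaches 1.  Regions with raw signal
    strictly above the cutoff signal are super-enhancers.  Returns None when
    the elbow is undefined (fewer than 3 regions, or all signals equal).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3 or s[0] == s[-1]:
        return None
    y = (s - s[0]) / (s[-1] - s[0])
    # x spacing is uniform 1/(n-1), so slope_i = (y[i+1]-y[i]) * (n-1);
    # the tolerance keeps exact slope-1 ties qualifying despite float rounding
    slopes = np.diff(y) * (n - 1)
    hits = np.nonzero(slopes >= 1.0 - 1e-9)[0]
    # slopes sum to n-1 over n-1 segments, so at least one reaches 1
    return int(hits[0])


def call_superenhancers(regions: list[StitchedRegion]) -> list[StitchedRegion]:
    """Assign ranks (1 = highest signal) and the super-enhancer flag.

    Degenerate inputs (under 3 regions, or all-equal signals) yield no
    super-enhancers and a logged warning.  Returns new region objects sorted
    by descending signal; the input list is not modified.
    """
    if not regions:
        return []
    signals = np.array([r.signal for r in regions], dtype=float)
    cut_idx = elbow_cutoff_index(signals)
    if cut_idx is None:
        logger.warning(
            "super-enhancer elbow undefined (%d regions, %s distinct signals); "
            "calling none",
            len(regions),
            len(np.unique(signals)),
        )
        cutoff = np.inf
    else:
        cutoff = float(np.sort(signals)[cut_idx])

    order = sorted(
        range(len(regions)),
        key=lambda i: (-signals[i], regions[i].interval.chrom, regions[i].interval.start),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        r = regions[i]
        out.append(
            StitchedRegion(
                interval=r.interval,
                constituents=list(r.constituents),
                signal=r.signal,
                rank=rank,
                is_super=bool(signals[i] > cutoff),
            )
        )
    return out
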