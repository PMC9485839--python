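"""Replicate-consensus super-enhancers and the normalized signal matrix.

A super-enhancer is high-confidence within a condition when super-enhancer
calls from at least ``min_support`` distinct replicates overlap each other by
at least ``min_overlap_bp`` (defaults 2 and 1, per the replicate-consensus
rule the pipeline implements).  High-confidence sets from all conditions are
then union-merged into one consensus list, quantified per sample over the
full consensus interval, and normalized by library size DiffBind-style:
``x_ij * mean(library sizes) / library_size_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomicInterval, sort_intervals

__all__ = [
    "ConsensusSE",
    "SignalMatrix",
    "replicate_filter",
    "build_consensus",
    "quantify_matrix",
    "normalize_library",
    "row_zscore",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSE:
    """A consensus super-enhancer region with per-condition provenance."""

    se_id: str
    interval: GenomicInterval
    support: dict[str, int]            # condition -> contributing region count
    source_conditions: tuple[str, ...]  # conditions with support >= 1


@dataclass
class SignalMatrix:
    """Consensus-SE x sample H3K27ac signal with per-sample library sizes."""

    values: pd.DataFrame          # index: se_id, columns: sample ids
    library_sizes: pd.Series
    samples: pd.DataFrame         # sample metadata (condition, replicate, ...)
    normalized: bool = False

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("signal matrix must be non-negative")


def _overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    return a.overlap_bp(b)


def _components(
    intervals: list[tuple[GenomicInterval, int]], min_overlap_bp: int
) -> list[list[tuple[GenomicInterval, int]]]:
    """Connected components under 'overlap >= min_overlap_bp' (union-find)."""
    tagged = sorted(intervals, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    n = len(tagged)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        iv_i = tagged[i][0]
        for j in range(i + 1, n):
            iv_j = tagged[j][0]
            if iv_j.chrom != iv_i.chrom:
                break
            if iv_j.start >= iv_i.end:  # sorted: no later start can overlap i
                break
            if _overlap_bp(iv_i, iv_j) >= min_overlap_bp:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[tuple[GenomicInterval, int]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(tagged[i])
    return list(groups.values())


def replicate_filter(
    replicate_se_sets: list[list[GenomicInterval]],
    min_support: int = 2,
    min_overlap_bp: int = 1,
) -> list[GenomicInterval]:
    """Keep super-enhancers supported by >= ``min_support`` distinct replicates.

    An interval is *supported* when, counting its own replicate, intervals
    from at least ``min_support`` distinct replicates each overlap it by at
    least ``min_overlap_bp``.  Retained regions are the unions of connected
    groups of supported intervals; with ``min_support=1`` this reduces to a
    plain overlap-merge of all replicate calls.
    """
    if min_support > len(replicate_se_sets):
        raise ValueError(
            f"min_support={min_support} exceeds number of replicate sets "
            f"({len(replicate_se_sets)})"
        )
    tagged = [
        (iv, rep_idx)
        for rep_idx, ses in enumerate(replicate_se_sets)
        for iv in ses
    ]
    supported: list[tuple[GenomicInterval, int]] = []
    for iv, rep in tagged:
        reps = {rep}
        for other, other_rep in tagged:
            if other_rep != rep and _overlap_bp(iv, other) >= min_overlap_bp:
                reps.add(other_rep)
        if len(reps) >= min_support:
            supported.append((iv, rep))

    out: list[GenomicInterval] = []
    for comp in _components(supported, min_overlap_bp):
        chrom = comp[0][0].chrom
        start = min(iv.start for iv, _ in comp)
        end = max(iv.end for iv, _ in comp)
        out.append(GenomicInterval(chrom, start, end))
    return sort_intervals(out)


def build_consensus(
    per_condition_sets: dict[str, list[GenomicInterval]]
) -> list[ConsensusSE]:
    """Union-merge high-confidence sets across conditions (transitively).

    Every input region ends up inside exactly one consensus region; output is
    sorted and pairwise disjoint, with per-condition provenance counts.
    """
    tagged = [
        (iv, cond)
        for cond, ses in per_condition_sets.items()
        for iv in ses
    ]
    indexed = [(iv, i) for i, (iv, _) in enumerate(tagged)]
    out: list[ConsensusSE] = []
    comps = _components(indexed, min_overlap_bp=1)
    comps.sort(key=lambda comp: (comp[0][0].chrom, min(iv.start for iv, _ in comp)))
    for k, comp in enumerate(comps, start=1):
        chrom = comp[0][0].chrom
        start = min(iv.start for iv, _ in comp)
        end = max(iv.end for iv, _ in comp)
        support = {cond: 0 for cond in per_condition_sets}
        for _, idx in comp:
            support[tagged[idx][1]] += 1
        out.append(
            ConsensusSE(
                se_id=f"SE{k:04d}",
                interval=GenomicInterval(chrom, start, end),
                support=support,
                source_conditions=tuple(c for c in per_condition_sets if support[c] > 0),
            )
        )
    return out


def quantify_matrix(
    consensus: list[ConsensusSE],
    coverage: dict[str, CoverageTrack],
    samples: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> SignalMatrix:
    """Raw signal matrix: coverage area over each full consensus interval.

    ``coverage`` maps sample id -> track; every sample in ``samples`` must be
    present.  Library sizes default to each track's total area (a stand-in
    for mapped-read counts when only coverage is available).
    """
    missing = [s for s in samples.index if s not in coverage]
    if missing:
        raise KeyError(f"missing coverage for sample(s): {missing}")
    sample_ids = list(samples.index)
    mat = np.zeros((len(consensus), len(sample_ids)))
    for i, se in enumerate(consensus):
        for j, sid in enumerate(sample_ids):
            mat[i, j] = coverage[sid].interval_area(se.interval)
    if library_sizes is None:
        library_sizes = pd.Series(
            {sid: coverage[sid].total_area() for sid in sample_ids}, name="library_size"
        )
    values = pd.DataFrame(mat, index=[se.se_id for se in consensus], columns=sample_ids)
    return SignalMatrix(values=values, library_sizes=library_sizes.loc[sample_ids],
                        samples=samples, normalized=False)


def normalize_library(matrix: SignalMatrix) -> SignalMatrix:
    """Scale each sample column to the mean library size.

    ``x_ij_norm = x_ij * mean(lib) / lib_j`` — invariant under a global
    rescaling of all library sizes.
    """
    lib = matrix.library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    factors = lib.mean() / lib
    values = matrix.values * factors
    return SignalMatrix(values=values, library_sizes=matrix.library_sizes,
                        samples=matrix.samples, normalized=True)


def row_zscore(
    values: pd.DataFrame, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Z-scale each row within sample groups (sample sd, n-1 denominator).

    ``grouping`` maps sample id -> group (e.g. cell line); None treats all
    samples as one group.  Constant rows become all zeros (with a warning).
    """
    if grouping is None:
        grouping = pd.Series("all", index=values.columns)
    out = values.copy().astype(float)
    n_constant = 0
    for group in grouping.unique():
        cols = [c for c in values.columns if grouping[c] == group]
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        sub = out[cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        constant = sd == 0
        n_constant += int(constant.sum())
        sd = sd.replace(0, 1.0)
        out[cols] = sub.sub(mean, axis=0).div(sd, axis=0)
    if n_constant:
        logger.warning("%d constant row/group blocks z-scored to zeros", n_constant)
    return out
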