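"""Compare pipeline output against planted truth from the generator."""

from __future__ import annotations

import numpy as np

from .consensus import ConsensusSE
from .dynamics import PatternCall
from .linking import SEGeneLink
from .simulate import TruthRegion

__all__ = [
    "expected_call",
    "match_to_truth",
    "pattern_recovery",
    "link_precision_recall",
]

#: planted pattern -> label the classifier should emit
_EXPECTED = {
    "gained_maintained": "gained_maintained",
    "gained_reverted": "gained_reverted",
    "lost_maintained": "lost_maintained",
    "lost_reverted": "lost_reverted",
    "unchanged_present": "unchanged",
    "unchanged_absent": None,            # produces no super-enhancer
    "other_late_gain": "other",
    "other_late_loss": "other",
}


def expected_call(pattern: str) -> str | None:
    return _EXPECTED[pattern]


def match_to_truth(
    consensus: list[ConsensusSE], truth: list[TruthRegion]
) -> dict[int, str | None]:
    """Truth index -> se_id of the overlapping consensus SE (None if missed).

    Planted regions are far apart, so overlap is unambiguous; the consensus
    SE with the largest overlap wins if several touch.
    """
    out: dict[int, str | None] = {}
    for i, region in enumerate(truth):
        best, best_ov = None, 0
        for se in consensus:
            ov = se.interval.overlap_bp(region.interval)
            if ov > best_ov:
                best, best_ov = se.se_id, ov
        out[i] = best
    return out


def pattern_recovery(
    truth: list[TruthRegion],
    consensus: list[ConsensusSE],
    calls: list[PatternCall],
) -> tuple[float, int, int]:
    """(fraction correct, n correct, n recoverable planted regions).

    A recoverable region (any pattern except the always-absent one) counts as
    correct when a consensus SE overlaps it and that SE's call matches the
    planted pattern's expected label; a missing SE counts as an error.
    """
    call_by_id = {c.se_id: c for c in calls}
    matches = match_to_truth(consensus, truth)
    n_recoverable = n_correct = 0
    for i, region in enumerate(truth):
        want = expected_call(region.pattern)
        if want is None:
            continue
        n_recoverable += 1
        se_id = matches[i]
        if se_id is not None and se_id in call_by_id and call_by_id[se_id].pattern == want:
            n_correct += 1
    frac = n_correct / n_recoverable if n_recoverable else float("nan")
    return frac, n_correct, n_recoverable


def link_precision_recall(
    truth: list[TruthRegion],
    consensus: list[ConsensusSE],
    links: list[SEGeneLink],
) -> tuple[float, float]:
    """Precision and recall of SE -> target-gene assignment on planted links.

    Recall: fraction of recoverable planted (SE, gene) pairs recovered.
    Precision: fraction of links assigned to truth-matched SEs that name the
    planted gene.
    """
    link_by_id = {l.se_id: l for l in links}
    matches = match_to_truth(consensus, truth)
    tp = fn = fp = 0
    for i, region in enumerate(truth):
        if expected_call(region.pattern) is None or region.target_gene is None:
            continue
        se_id = matches[i]
        if se_id is None or se_id not in link_by_id:
            fn += 1
            continue
        if link_by_id[se_id].gene_id == region.target_gene:
            tp += 1
        else:
            fn += 1
            fp += 1
    n_pred = tp + fp
    precision = tp / n_pred if n_pred else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, recall
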