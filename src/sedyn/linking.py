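"""Super-enhancer -> target-gene assignment.

Each consensus super-enhancer is linked to the gene whose expression is most
strongly positively correlated with the enhancer's normalized H3K27ac signal
across samples, among genes whose TSS lies within 50 kb of the enhancer.
When no in-window gene shows a significant positive correlation, the closest
gene genome-wide is assigned instead (nearest-fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .consensus import ConsensusSE
from .io import Gene, GeneAnnotation

__all__ = ["SEGeneLink", "candidate_genes", "correlate", "assign_target", "link_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SEGeneLink:
    """One SE -> gene assignment with its correlation evidence."""

    se_id: str
    gene_id: str
    distance: int                 # bp from TSS to the SE (0 if inside)
    r: float | None
    p: float | None
    method: str                   # "correlation" or "nearest-fallback"

    def __post_init__(self) -> None:
        if self.method not in ("correlation", "nearest-fallback"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def _tss_distance(se: ConsensusSE, gene: Gene) -> int | None:
    """bp distance from the gene's TSS to the SE; None on other chromosomes."""
    iv = se.interval
    if gene.chrom != iv.chrom:
        return None
    if iv.start <= gene.tss < iv.end:
        return 0
    if gene.tss < iv.start:
        return iv.start - gene.tss
    return gene.tss - iv.end


def candidate_genes(
    se: ConsensusSE, annotation: GeneAnnotation, window: int = 50_000
) -> list[tuple[Gene, int]]:
    """Genes whose TSS lies within ``[se.start - window, se.end + window)``.

    Returned with their TSS distance (0 when the TSS falls inside the SE),
    sorted by (distance, gene id).
    """
    out = []
    for gene in annotation.genes:
        d = _tss_distance(se, gene)
        if d is None:
            continue
        if se.interval.start - window <= gene.tss < se.interval.end + window:
            out.append((gene, d))
    out.sort(key=lambda t: (t[1], t[0].gene_id))
    return out


def correlate(se_signal: np.ndarray, gene_expr: np.ndarray) -> tuple[float, float]:
    """Pearson r with one-sided p (H1: r > 0, t-distribution, n-2 df).

    Requires >= 3 matched samples and two non-constant vectors.
    """
    x = np.asarray(se_signal, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signal and expression vectors must be 1-D and matched")
    if len(x) < 3:
        raise ValueError("need >= 3 matched samples for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def assign_target(
    se: ConsensusSE,
    candidates: list[tuple[Gene, int, float | None, float | None]],
    annotation: GeneAnnotation,
    alpha: float = 0.05,
) -> SEGeneLink:
    """Pick the target among scored candidates (gene, distance, r, p).

    Significant positive correlations (r > 0, p < alpha) win; the highest r
    is chosen, ties broken by smaller distance then gene id.  With no
    significant candidate the genome-wide closest gene is assigned
    (method ``nearest-fallback``).
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation: cannot assign a target")
    significant = [
        (g, d, r, p)
        for g, d, r, p in candidates
        if r is not None and p is not None and r > 0 and p < alpha
    ]
    if significant:
        g, d, r, p = min(significant, key=lambda t: (-t[2], t[1], t[0].gene_id))
        return SEGeneLink(se.se_id, g.gene_id, d, r, p, "correlation")
    scored = [(g, _tss_distance(se, g)) for g in annotation.genes]
    in_chrom = [(g, d) for g, d in scored if d is not None]
    pool = in_chrom if in_chrom else [
        (g, 10**12) for g in annotation.genes  # no same-chromosome gene at all
    ]
    g, d = min(pool, key=lambda t: (t[1], t[0].gene_id))
    known = {gid: (r, p) for gid, _, r, p in
             ((gg.gene_id, dd, rr, pp) for gg, dd, rr, pp in candidates)}
    r, p = known.get(g.gene_id, (None, None))
    return SEGeneLink(se.se_id, g.gene_id, d if d < 10**12 else 0, r, p,
                      "nearest-fallback")


def link_all(
    consensus: list[ConsensusSE],
    annotation: GeneAnnotation,
    se_signal: "np.ndarray | object",
    expression_logfpm: "object",
    window: int = 50_000,
    alpha: float = 0.05,
) -> list[SEGeneLink]:
    """Link every consensus SE to exactly one target gene.

    ``se_signal`` is a DataFrame (se_id x sample) of normalized H3K27ac;
    ``expression_logfpm`` a DataFrame (gene x sample) on matching samples.
    Candidates with a constant signal or expression vector are skipped for
    correlation (warning) but remain eligible for the nearest fallback.
    """
    common = [s for s in se_signal.columns if s in expression_logfpm.columns]
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples between signal and expression")
    links = []
    for se in consensus:
        sig = se_signal.loc[se.se_id, common].to_numpy(dtype=float)
        scored: list[tuple[Gene, int, float | None, float | None]] = []
        for gene, dist in candidate_genes(se, annotation, window=window):
            if gene.gene_id not in expression_logfpm.index:
                continue
            expr = expression_logfpm.loc[gene.gene_id, common].to_numpy(dtype=float)
            try:
                r, p = correlate(sig, expr)
            except ValueError:
                logger.warning(
                    "constant vector for %s / %s; excluded from correlation",
                    se.se_id, gene.gene_id,
                )
                r, p = None, None
            scored.append((gene, dist, r, p))
        links.append(assign_target(se, scored, annotation, alpha=alpha))
    return links
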