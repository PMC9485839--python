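"""Expression-side computations: log2-FPM, module scores, a stand-in
differential-expression test, and hypergeometric over-representation.

The differential test is Welch's t on log2-FPM with Benjamini-Hochberg
adjustment — a deliberately simple stand-in whose thresholds (padj < 0.05,
|log2FC| > 2) match the analysis this package reimplements; a DE table
produced by an external negative-binomial tool can be supplied instead via
the defined TSV schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetRecord as GeneSet

__all__ = [
    "GeneSet",
    "DEResult",
    "log_fpm",
    "module_score",
    "differential_expression",
    "ora_hypergeometric",
]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast.

    ``table`` has columns log2fc, p, padj indexed by gene id; positive
    log2fc means higher in the second-named (treatment) group of the
    contrast label "treatment_vs_reference".
    """

    table: pd.DataFrame
    contrast: str

    def significant(self, padj: float = 0.05, min_abs_log2fc: float = 2.0) -> pd.DataFrame:
        t = self.table
        return t[(t["padj"] < padj) & (t["log2fc"].abs() > min_abs_log2fc)]


def log_fpm(
    counts: pd.DataFrame, library_sizes: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(counts / library size * 1e6 + pseudocount), column-wise."""
    lib = library_sizes.loc[list(counts.columns)].astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2(counts.div(lib, axis=1) * 1e6 + pseudocount)


def module_score(expr_logfpm: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample unweighted mean log2-FPM over the set's member genes.

    Members absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in gene_set.members if g in expr_logfpm.index]
    missing = len(gene_set.members) - len(present)
    if not present:
        raise ValueError(f"gene set {gene_set.set_id!r}: no members in matrix")
    if missing:
        logger.warning(
            "gene set %s: %d of %d members absent from matrix",
            gene_set.set_id, missing, len(gene_set.members),
        )
    return expr_logfpm.loc[present].mean(axis=0).rename(gene_set.set_id)


def differential_expression(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    group_a: list[str],
    group_b: list[str],
    contrast: str = "B_vs_A",
    pseudocount: float = 1.0,
) -> DEResult:
    """Welch-t stand-in DE test on log2-FPM; log2FC = mean(B) - mean(A).

    Group A is the reference; positive fold changes mean higher in group B.
    BH adjustment is applied across all genes.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    lf = log_fpm(counts, library_sizes, pseudocount=pseudocount)
    a = lf[group_a].to_numpy(dtype=float)
    b = lf[group_b].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    tstat, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj}, index=counts.index
    )
    return DEResult(table=table, contrast=contrast)


def ora_hypergeometric(
    hit_list: list[str],
    gene_sets: dict[str, GeneSet],
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation, BH-adjusted across sets.

    For each set: p = P(X >= k) with N = |universe|, K = |set in universe|,
    n = |hit list|, k = |hits in set|.  Hits must be drawn from the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hits = set(hit_list)
    if not hits <= uni:
        raise ValueError("hit list must be a subset of the universe")
    rows = []
    for set_id, gs in gene_sets.items():
        members = set(gs.members) & uni
        k = len(hits & members)
        # P(X >= k) = sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(hits)))
        rows.append((set_id, gs.label, k, len(members), p))
    df = pd.DataFrame(rows, columns=["set_id", "label", "overlap", "set_size", "p"])
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df.set_index("set_id")
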