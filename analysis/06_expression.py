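#!/usr/bin/env python
"""Expression-side analysis: differential expression, module scores, ORA.

Runs the stand-in Welch-on-log2-FPM differential test for the three
contrasts (treated vs control, withdrawn vs treated, withdrawn vs control),
scores the two planted gene modules per sample, and tests the
treated-vs-control hit list for over-representation of the planted modules
with the hypergeometric tail.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS

from sedyn import io as sio
from sedyn.expression import (
    differential_expression,
    log_fpm,
    module_score,
    ora_hypergeometric,
)

CONTRASTS = [("treated", "control"), ("withdrawn", "treated"),
             ("withdrawn", "control")]


def main() -> None:
    expr = sio.parse_expression_file(DATA / "expression.tsv")
    sets = sio.parse_gene_sets(DATA / "gene_sets.tsv")
    by_cond = expr.samples.groupby("condition").groups

    de_tables = {}
    for b, a in CONTRASTS:
        label = f"{b}_vs_{a}"
        de = differential_expression(expr.values, expr.library_sizes,
                                     list(by_cond[a]), list(by_cond[b]),
                                     contrast=label)
        de.table.to_csv(RESULTS / f"de_{label}.tsv", sep="\t",
                        index_label="gene_id")
        de_tables[label] = de
        sig = de.significant(padj=0.05, min_abs_log2fc=2.0)
        print(f"{label}: {len(sig)} genes at padj<0.05, |log2FC|>2")

    logfpm = log_fpm(expr.values, expr.library_sizes)
    scores = pd.DataFrame({sid: module_score(logfpm, gs)
                           for sid, gs in sets.items()}).T
    scores.to_csv(RESULTS / "module_scores.tsv", sep="\t", index_label="set_id")
    cond = expr.samples["condition"]
    for sid in scores.index:
        by = scores.loc[sid].groupby(cond).mean()
        print(f"module {sid}: control={by['control']:.2f} "
              f"treated={by['treated']:.2f} withdrawn={by['withdrawn']:.2f}")

    de = de_tables["treated_vs_control"]
    hits = list(de.significant(padj=0.05, min_abs_log2fc=2.0).index)
    universe = list(expr.values.index)
    ora = ora_hypergeometric(hits, sets, universe)
    ora.to_csv(RESULTS / "ora_treated_vs_control.tsv", sep="\t")
    print("over-representation of planted modules in the "
          "treated-vs-control hit list:")
    print(ora[["overlap", "set_size", "p", "padj"]].to_string())


if __name__ == "__main__":
    main()
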