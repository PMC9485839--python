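#!/usr/bin/env python
"""Assign each consensus super-enhancer a regulatory target gene.

Correlates normalized H3K27ac with log2-FPM expression across the 9 samples
for every gene whose TSS lies within 50 kb, picks the strongest significant
positive correlation, and falls back to the closest gene otherwise.  Scores
the assignments against the planted truth table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, RESULTS

from sedyn import io as sio
from sedyn.consensus import ConsensusSE
from sedyn.expression import log_fpm
from sedyn.linking import link_all


def main() -> None:
    consensus = [ConsensusSE(iv.name, iv, {}, ())
                 for iv in sio.parse_interval_file(RESULTS / "consensus_se.bed")]
    signal = pd.read_csv(RESULTS / "signal_matrix.tsv", sep="\t", index_col=0)
    annotation = sio.parse_annotation_file(DATA / "annotation.tsv")
    expr = sio.parse_expression_file(DATA / "expression.tsv")
    logfpm = log_fpm(expr.values, expr.library_sizes)

    links = link_all(consensus, annotation, signal, logfpm,
                     window=50_000, alpha=0.05)
    df = pd.DataFrame(
        [(l.se_id, l.gene_id, l.distance,
          "" if l.r is None else round(l.r, 6),
          "" if l.p is None else f"{l.p:.3g}", l.method) for l in links],
        columns=["se_id", "gene_id", "distance", "r", "p", "method"])
    df.to_csv(RESULTS / "se_gene_links.tsv", sep="\t", index=False)

    methods = df.method.value_counts().to_dict()
    print(f"linked {len(links)} super-enhancers to targets; methods: {methods}")

    # score against the planted truth
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
    se_by_id = {se.se_id: se for se in consensus}
    link_by_id = {l.se_id: l for l in links}
    tp = total = 0
    for row in truth.itertuples():
        if row.target_gene == "." or row.pattern == "unchanged_absent":
            continue
        total += 1
        hit = [se for se in consensus
               if se.interval.chrom == row.chrom
               and se.interval.start < row.end and row.start < se.interval.end]
        if hit and link_by_id[hit[0].se_id].gene_id == row.target_gene:
            tp += 1
    print(f"planted target recovered for {tp}/{total} recoverable "
          f"super-enhancers")


if __name__ == "__main__":
    main()
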