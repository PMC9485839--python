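#!/usr/bin/env python
"""Consensus super-enhancers: replicate filtering, cross-condition merge,
library-size-normalized signal matrix.

Keeps per-condition regions supported by >= 2 of 3 replicates (>= 1 bp
mutual overlap), union-merges the three condition sets into one consensus
list, quantifies H3K27ac over each consensus interval in every sample, and
normalizes columns to the mean library size.  Also writes the consensus
constituents (merged called peaks inside each consensus span) for the
motif-scanning stage.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import CONDITIONS, DATA, RESULTS, SE_CALLS, read_sample_sheet

from sedyn import io as sio
from sedyn.consensus import build_consensus, normalize_library, quantify_matrix, replicate_filter
from sedyn.intervals import merge_intervals


def main() -> None:
    sheet = read_sample_sheet()
    highconf = {}
    for cond in CONDITIONS:
        rep_sets = []
        for sid in sheet.index[sheet.condition == cond]:
            path = SE_CALLS / f"{sid}.super.bed"
            rep_sets.append(sio.parse_interval_file(path) if path.stat().st_size
                            else [])
        highconf[cond] = replicate_filter(rep_sets, min_support=2,
                                          min_overlap_bp=1)
    consensus = build_consensus(highconf)

    coverage = {sid: sio.parse_coverage_file(DATA / meta.coverage_path)
                for sid, meta in sheet.iterrows()}
    raw = quantify_matrix(consensus, coverage, sheet)
    norm = normalize_library(raw)

    with open(RESULTS / "consensus_se.bed", "w") as fh:
        for se in consensus:
            iv = se.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{se.se_id}\n")
    norm.values.to_csv(RESULTS / "signal_matrix.tsv", sep="\t",
                       index_label="se_id")
    raw.library_sizes.to_csv(RESULTS / "library_sizes.tsv", sep="\t",
                             header=["library_size"])

    # constituents: merged called peaks (all samples) inside each consensus span
    peaks_all = []
    for sid, meta in sheet.iterrows():
        peaks_all.extend(sio.parse_interval_file(DATA / meta.peak_path,
                                                 dialect="narrowPeak"))
    with open(RESULTS / "consensus_constituents.bed", "w") as fh:
        for se in consensus:
            inside = [p for p in peaks_all if p.overlap_bp(se.interval) > 0]
            for c in merge_intervals(inside, min_gap=1):
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{se.se_id}\n")

    per_cond = {c: len(v) for c, v in highconf.items()}
    print(f"high-confidence super-enhancers per condition: {per_cond}")
    print(f"consensus list: {len(consensus)} regions "
          f"(union-merged across conditions)")
    print("wrote consensus_se.bed, signal_matrix.tsv, "
          "consensus_constituents.bed")


if __name__ == "__main__":
    main()
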