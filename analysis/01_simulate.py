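#!/usr/bin/env python
"""Generate the synthetic three-condition H3K27ac + expression dataset.

Plants 5 super-enhancers per dynamics class (gained/lost x maintained/
reverted, unchanged present/absent, late gain/loss) across two chromosomes,
each with a target gene within 50 kb, plus decoy and background genes,
low-signal background enhancers, two expression modules that move in
opposite directions under treatment, and a four-factor autoregulatory
circuit spliced into the genome sequence.  Writes every input the rest of
the analysis consumes (narrowPeak, bedGraph, TSV, FASTA, JASPAR) plus the
truth table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA, N_PER_PATTERN, NOISE_SD, SEED

from sedyn import io as sio
from sedyn.pipeline import stage_seed
from sedyn.simulate import SimulationConfig, simulate_all


def main() -> None:
    cfg = SimulationConfig(
        seed=stage_seed(SEED, "simulate"),
        n_per_pattern=N_PER_PATTERN,
        replicate_noise_sd=NOISE_SD,
    )
    genome, truth, chip, expr = simulate_all(cfg)
    DATA.mkdir(parents=True, exist_ok=True)

    sio.write_annotation_file(DATA / "annotation.tsv", genome.annotation)
    sio.write_expression_file(DATA / "expression.tsv", expr)
    sio.write_motif_file(DATA / "motifs.jaspar", genome.motifs)
    sio.write_fasta(DATA / "genome.fa", genome.sequences)
    sio.write_gene_sets(DATA / "gene_sets.tsv", genome.module_sets)
    sio.write_coverage_file(DATA / "input.bedGraph", chip.input_track)
    with open(DATA / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with open(DATA / "tf_catalog.tsv", "w") as fh:
        for gene_id, motif_id in sorted(genome.tf_catalog.items()):
            fh.write(f"{gene_id}\t{motif_id}\n")
    rows = ["sample_id\tcell_line\tcondition\treplicate\tpeak_path\tcoverage_path"]
    for sid, meta in chip.samples.iterrows():
        sio.write_interval_file(DATA / f"{sid}.narrowPeak", chip.peaks[sid],
                                dialect="narrowPeak")
        sio.write_coverage_file(DATA / f"{sid}.bedGraph", chip.tracks[sid])
        rows.append(f"{sid}\tSIM1\t{meta.condition}\t{meta.replicate}"
                    f"\t{sid}.narrowPeak\t{sid}.bedGraph")
    (DATA / "sample_sheet.tsv").write_text("\n".join(rows) + "\n")
    with open(DATA / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tpattern\tn_constituents\ttarget_gene\n")
        for r in truth:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                     f"\t{r.pattern}\t{r.n_constituents}\t{r.target_gene or '.'}\n")

    n_peaks = sum(len(p) for p in chip.peaks.values())
    print(f"planted {len(truth)} super-enhancer regions "
          f"({N_PER_PATTERN} per pattern class) on "
          f"{len(genome.chrom_sizes)} chromosomes")
    print(f"simulated {len(chip.samples)} ChIP samples "
          f"(3 conditions x 3 replicates), {n_peaks} called peaks total")
    print(f"expression matrix: {len(expr.gene_ids)} genes x "
          f"{len(expr.sample_ids)} samples")
    print(f"wrote dataset to {DATA}")


if __name__ == "__main__":
    main()
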