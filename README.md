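# sedyn — super-enhancer dynamics across treatment conditions

Neuroblastoma and similar tumor cells can be pushed toward differentiation
by agents such as all-trans-retinoic acid (ATRA), and whether the induced
state *persists after the drug is withdrawn* is visible in the chromatin:
super-enhancers (SEs) — large clusters of H3K27ac-marked enhancers — are
gained and lost with treatment, and either maintain or revert their new
state after withdrawal. `sedyn` is a tested, reusable implementation of that
analysis for anyone with per-condition H3K27ac peaks and coverage plus
matched RNA expression:

1. **SE calling** — ROSE-style: stitch peaks within 12.5 kb, score stitched
   regions by input-subtracted H3K27ac over constituent peaks, rank, and cut
   at the rank-curve elbow (the point where the slope of the [0,1]-rescaled
   signal curve reaches 1).
2. **Consensus** — keep SEs present in ≥ 2 of 3 replicates (≥ 1 bp overlap),
   union-merge across conditions, quantify, and normalize by library size
   (`x·mean(lib)/lib_j`).
3. **Dynamics** — binarize 200-bp bins per condition (Poisson upper tail vs
   genome background), fit an 8-state hidden Markov model with independent
   Bernoulli emissions per condition (one state per presence/absence
   combination over control/treated/withdrawn), Viterbi-decode, and label
   each SE from its predominant state as `gained_maintained`,
   `gained_reverted`, `lost_maintained`, `lost_reverted`, `unchanged`, or
   `other`.
4. **Target linking** — each SE is assigned the gene (TSS within 50 kb)
   whose expression correlates best (one-sided Pearson, p < 0.05, r > 0)
   with its normalized H3K27ac; otherwise the closest gene.
5. **Core regulatory circuitry (CRC)** — SE-driven transcription factors
   expressed above a cutoff are scanned (log-odds PWMs, both strands,
   ±500 bp around constituents) for each other's motifs; the maximal fully
   interconnected autoregulatory cliques are the circuits.

A first-class synthetic-data generator plants all eight dynamics patterns,
target genes, expression modules and a four-factor circuit with known truth,
so every stage is testable end to end. See `docs/methods.md` for the model
details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
dataset (`python analysis/01_simulate.py`, then `02_…` through `08_…`;
outputs land under `results/`). The same thing in one call:

```bash
sedyn run-all --seed 1 --out results/run
```

or from Python:

```python
from sedyn.pipeline import PipelineConfig, run
result = run(PipelineConfig(out_dir="results/run", seed=1))
print(result.report["pattern_counts"])
```

With the default configuration (5 planted SEs per pattern, replicate noise
σ = 0.3) the report stage prints:

```
consensus super-enhancers: 35
pattern counts: {'other': 10, 'gained_maintained': 5, 'gained_reverted': 5,
                 'lost_maintained': 5, 'lost_reverted': 5, 'unchanged': 5}
5 of the 10 gained super-enhancers maintained treatment-induced H3K27ac after withdrawal
5 of the 10 lost super-enhancers reverted after withdrawal
planted patterns recovered: 35/35
```

Reading: 40 regions were planted, the 5 always-absent ones correctly produce
no SE, and every recovered SE is labelled with its true dynamics class —
the "N of M gained SEs maintained" phrasing is exactly the headline statistic
this style of analysis produces on real data. `results/se_gene_links.tsv`
lists each SE's target with its correlation (32 of 35 by correlation, 3 by
nearest-fallback on this run), and `results/crc_cliques.json` contains the
planted circuit recovered as the unique maximal clique in every condition:
`["G020T", "G021T", "G022T", "G023T"]`.

The CLI also exposes each stage separately (`sedyn simulate`, `call-se`,
`consensus`, `dynamics`, `link-targets`, `expression`, `crc`, `report`);
run `sedyn --help`.

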