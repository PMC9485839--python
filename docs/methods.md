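# Methods

`sedyn` reimplements, as one tested pipeline, the analysis used to ask how a
cell's super-enhancer landscape responds to a differentiation treatment and
whether the response outlasts the treatment: super-enhancers are called from
H3K27ac ChIP signal in three conditions (control, treated, withdrawn;
three replicates each), their dynamics across the conditions are classified
with a multivariate Bernoulli hidden Markov model, each super-enhancer is
assigned a target gene by signal–expression correlation, and the
autoregulatory core regulatory circuitry (CRC) of super-enhancer-driven
transcription factors is enumerated.

## Super-enhancer calling (ROSE-style)

Peaks on the same chromosome are stitched into one region whenever a chain of
peaks connects them with inter-peak gaps (`next.start − prev.end`) strictly
below the stitching distance (default **12,500 bp**; TSS exclusion is
implemented but off by default). Each stitched region is scored by
input-subtracted H3K27ac area summed **over its constituent peaks only** —
valleys between constituents would dilute the signal and are excluded — and
floored at zero.

The super-enhancer cutoff is the geometric elbow of the rank curve: signals
are sorted ascending, both axes are rescaled to [0, 1], and the cutoff is the
left endpoint of the first segment (scanning from the low end) whose discrete
slope reaches 1. Regions with signal strictly above the cutoff signal are
super-enhancers, so ties at the cutoff resolve toward fewer calls. Because
the mean rescaled slope is exactly 1, a qualifying segment always exists when
the elbow is defined; with fewer than 3 regions or all-equal signals the
elbow is undefined and nothing is called (logged warning). The slope
comparison uses `slope ≥ 1 − 1e−9` so that exact rational slope-1 ties are
not flipped by floating-point rounding; integer-valued signal vectors cannot
otherwise land inside that tolerance gap. Both the stitching rule and the
elbow are verified against brute-force references (`sedyn.oracles`):
per-peak dilation by half the stitch distance with connected-component
merging, and an exhaustive tangent scan in exact rational arithmetic.

No read-count normalization is applied inside scoring (raw area); per-sample
comparability is handled by the consensus stage below. Whether rpm scaling
should precede input subtraction is genuinely open; raw area is the
documented choice.

## Replicate consensus and the signal matrix

Within each condition a super-enhancer is high-confidence when calls from at
least **2** distinct replicates mutually overlap by at least **1 bp**; the
retained region is the union of the supporting calls (union rather than
intersection, matching DiffBind-style merging and preserving constituent
coverage). High-confidence sets from all conditions are then union-merged
(transitively) into a consensus list in which every input region lies in
exactly one consensus region.

H3K27ac signal is quantified as coverage area over the full consensus
interval per sample and normalized DiffBind-style by library size:
`x[i,j] · mean(lib) / lib[j]`, which is invariant under global rescaling of
all library sizes. Library size defaults to each sample's total coverage
area — the only size measure available from coverage tracks alone — and can
be overridden. Heatmap-style row z-scores use the sample (n−1) standard
deviation; constant rows become zeros with a warning.

## Dynamics classification (Bernoulli HMM)

The genome is tiled into **200-bp** bins. Per condition, replicate coverage
is pooled and a bin is called *present* when the upper-tail Poisson p-value
of its (rounded) coverage area, under the genome-wide mean per-bin area as
background rate, is below **1e−4** (configurable; per-replicate binarization
is available behind a flag). An HMM with **8 states** — one per
presence/absence combination over (control, treated, withdrawn) — and
independent per-condition Bernoulli emissions is fitted by Baum–Welch EM.
Chromosome boundaries reset the chain: no transition is counted or scored
across a break.

Initialization: emission rows at the 8 binary corners smoothed to
{0.1, 0.9}, uniform initial distribution, and a **sticky transition matrix
(0.9 on the diagonal)**. The sticky start matters: presence calls come in
genomic runs, and with a uniform transition matrix the overwhelming
all-absent background mass leaks a small responsibility into every rare
corner state each E-step and drags its emission row to (0, 0, 0), collapsing
the rare patterns (observed directly on planted data). With the sticky
start, planted corner runs are recovered exactly in under ten iterations.
EM stops when the log-likelihood gain drops below 1e−4 (default cap 200
iterations; hitting the cap returns a flagged, non-converged result). The
log-likelihood sequence is non-decreasing (EM guarantee, asserted in tests),
and decoding uses the Viterbi path — hard labels are needed for window
counting and are deterministic.

Each consensus super-enhancer is assigned its **predominant state**: the
state covering the largest fraction of the 200-bp windows it overlaps (ties
to the lower state index; a super-enhancer overlapping no bin is an error).
Density is the window-count fraction — i.e. the predominant state maximizes
the number of windows of that state within the super-enhancer. The state's
emission row, thresholded at 0.5 per condition, maps to the pattern label:

| presence (c, t, w) | label |
|---|---|
| (0,1,1) | gained_maintained |
| (0,1,0) | gained_reverted |
| (1,0,0) | lost_maintained |
| (1,0,1) | lost_reverted |
| (0,0,0), (1,1,1) | unchanged |
| (0,0,1), (1,1,0) | other |

Maintained-vs-reverted is decided from the HMM presence pattern alone; a
one-way ANOVA on normalized signal can be overlaid for reporting but never
changes labels. The vocabulary is closed: exactly four responsive classes
plus `unchanged` and `other`.

## Target-gene assignment

Candidates are genes whose TSS lies within `[SE.start − 50 kb, SE.end +
50 kb)` (TSS anchor; distance 0 when the TSS falls inside the
super-enhancer). For each candidate, Pearson correlation between the
library-size-normalized H3K27ac row and the gene's log2-FPM expression
across the matched samples, with a one-sided p-value for r > 0 from the
t-distribution with n−2 degrees of freedom. Among candidates with r > 0 and
p < **0.05** (no multiple-testing correction across the few candidates per
enhancer; a BH mode is available), the highest r wins, ties broken by
smaller distance then gene id. With no significant candidate the genome-wide
closest gene is assigned (`nearest-fallback`). Every consensus
super-enhancer receives exactly one link.

## Expression side

log2-FPM is `log2(count / library size × 1e6 + 1)` — FPM, not FPKM: no
gene-length normalization. Module scores are unweighted means of member-gene
log2-FPM per sample. The differential test is **Welch's t on log2-FPM** with
Benjamini–Hochberg adjustment and significance thresholds padj < 0.05,
|log2FC| > 2 — a deliberately simple stand-in whose null calibration is
checked (empirical type-I ≈ 5% on negative-binomial null data); an external
negative-binomial DE table can be supplied in the defined TSV schema
instead. Over-representation uses the exact upper-tail hypergeometric
probability, BH-adjusted across sets.

## Core regulatory circuitry

Candidate factors are transcription factors (per a gene↔motif catalog) that
are the assigned target of at least one super-enhancer and whose normalized
expression in the analyzed condition is at least **33** — the cutoff's units
are those of the supplied matrix (mean FPM here) and it is fully
configurable, since no principled unit is fixed by the procedure. JASPAR
PFMs are converted to log2-odds PWMs with pseudocount 0.5 against a uniform
background. Each factor's PWM is scanned over every factor's constituent
peaks extended by **±500 bp** (constituents, not the stitched hull), both
strands, windows containing N skipped; a hit requires a score of at least
**80% of the maximum achievable** — a simple deterministic threshold that
needs no background model at this scale. Edge A→B means A's motif occurs in
B's extended constituents. Circuits are the maximal cliques
(Bron–Kerbosch, via networkx) of the bidirectional subgraph restricted to
autoregulating nodes (self-edge required), sorted by size then
lexicographically; per-TF frequency is the fraction of cliques containing
the factor. Enumeration is validated against exhaustive subset enumeration.

## Synthetic data: what it emulates and what it does not

The generator plants, per pattern class, `n_per_pattern` super-enhancers of
3–5 constituents (2 kb wide, 1 kb valleys — well under the stitch distance)
in 150-kb slots across 2 chromosomes. Presence per condition follows the
pattern table above (8 classes, including always-present, always-absent, and
the two "other" late-change classes). Present constituents emit per-bp depth
`30 × lognormal(0, σ)` with σ = 0.3 by default (multiplicative, right-skewed
noise, drawn per condition × replicate × constituent); everything else sits
on a depth-1.0 floor, the shared ChIP input is flat at the floor, and peaks
are emitted wherever depth reaches 5.0 (a thresholded-truth stand-in for the
upstream peak caller, which is out of scope). Sixty low-signal background
enhancers give the rank curve its low-signal body.

Each super-enhancer has a designated target gene (TSS 20 kb beyond its
edge), an in-window decoy with constant expression at 45 kb, and an
out-of-window decoy at 70 kb. Expression counts are negative-binomial
(dispersion 0.1; dispersion 0 is the deterministic rounded-mean degenerate
case) with the target's mean proportional to its enhancer's per-sample
constituent H3K27ac area, scaled by per-sample library factors; background
genes have constant means, and two 30-gene modules move 4-fold in opposite
directions under treatment. Four target genes of always-present
super-enhancers form the planted circuit: their distinct 10-bp motif
consensus sites are spliced into the first constituent of every member's
super-enhancer, and two decoy catalog entries (no enhancer) check the
candidate filter. Truth geometry is a deterministic function of the
configuration; the seed drives only sequence, noise and counts.

Not emulated: read-level data (FASTQ/fragment models), GC bias, copy-number
aberration, multiple cell lines with divergent responses, biological
correlation structure among background genes, and motif occurrences arising
from evolved sequence. Passing recovery tests therefore demonstrates the
pipeline's correctness and its behavior under calibrated multiplicative
noise, not performance on real ChIP-seq artifacts.

## Problem sizes and numerics

Default validation runs use 5 regions per pattern (40 planted
super-enhancers, ~47k bins × 3 conditions), chosen to exercise every stage
while a full pipeline run stays under ~10 s; HMM parameter recovery is
measured on 10⁵ bins sampled from a known sticky 8-state model, with fitted
states matched to planted ones by minimum-cost assignment on emission rows.
Emission probabilities are clipped to [1e−10, 1 − 1e−10] inside likelihoods;
forward–backward uses per-step scaling. All interval arithmetic is 0-based
half-open; chromosome names match exactly (no "chr" aliasing). Degenerate
inputs (empty peak lists, all-equal signals, constant expression rows,
all-zero bins) are defined behaviors with tests rather than errors, except
where a result would be meaningless (no bins overlapping a super-enhancer,
empty annotation).

## Known limitations

- The Welch-on-log-FPM test underestimates nothing on calibrated nulls but
  is not a shrinkage-based NB test; very low counts with few replicates will
  be noisier than a dedicated DE tool.
- The motif-hit threshold (fraction of max score) has no p-value semantics;
  thresholds are comparable within a motif, not across motifs.
- One target gene per super-enhancer, TSS-anchored; no contact-map-aware
  assignment.
- The CRC expression cutoff is unit-dependent by construction.
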