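"""Synthetic genomes, H3K27ac data and expression matrices with planted truth.

The generator emulates the three-condition design (control, ATRA-treated,
withdrawn; three replicates each): super-enhancers composed of several
constituent peaks separated by sub-stitch-distance valleys are planted with
known presence/absence dynamics across the conditions, each with a designated
target gene whose expression tracks the enhancer's per-sample H3K27ac, plus
decoy genes, background genes, low-signal background enhancers, and a planted
four-factor autoregulatory circuit whose motif consensus sites are spliced
into each member's constituents.

Truth coordinates are a deterministic function of the configuration alone;
the seed drives only sequence content, signal noise and counts, so two seeds
give different depths over identical planted geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomicInterval
from .io import (
    ExpressionMatrix,
    Gene,
    GeneAnnotation,
    GeneSetRecord,
    MotifPFM,
)

__all__ = [
    "PATTERNS",
    "PATTERN_PRESENCE",
    "SimulationConfig",
    "TruthRegion",
    "ToyGenome",
    "ChIPSim",
    "build_toy_genome",
    "plant_truth",
    "simulate_h3k27ac",
    "simulate_expression",
    "simulate_all",
]

#: planted pattern classes, in fixed order
PATTERNS = (
    "gained_maintained",
    "gained_reverted",
    "lost_maintained",
    "lost_reverted",
    "unchanged_present",
    "unchanged_absent",
    "other_late_gain",
    "other_late_loss",
)

#: presence vector over (control, treated, withdrawn) per pattern
PATTERN_PRESENCE = {
    "gained_maintained": (0, 1, 1),
    "gained_reverted": (0, 1, 0),
    "lost_maintained": (1, 0, 0),
    "lost_reverted": (1, 0, 1),
    "unchanged_present": (1, 1, 1),
    "unchanged_absent": (0, 0, 0),
    "other_late_gain": (0, 0, 1),
    "other_late_loss": (1, 1, 0),
}

#: planted circuit motif consensus sites (distinct, no shared 10-mers)
_CRC_MOTIF_CONSENSUS = ("ACGGTCAAGC", "TGCATCGGAT", "GGATACCTGC", "CTTGAGCGTA")
_DECOY_MOTIF_CONSENSUS = ("AATTCCGGAA", "GCGCATATGC")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    Depths are per-bp coverage; ``replicate_noise_sd`` is the sigma of the
    multiplicative lognormal noise on constituent depth per condition,
    replicate and constituent.  ``library_size_range`` scales per-sample
    sequencing depth for the expression counts.
    """

    seed: int = 0
    n_per_pattern: int = 5
    n_chroms: int = 2
    chrom_length: int | None = None
    conditions: tuple[str, str, str] = ("control", "treated", "withdrawn")
    n_replicates: int = 3
    present_depth_mean: float = 30.0
    absent_depth_mean: float = 1.0
    replicate_noise_sd: float = 0.3
    peak_call_threshold: float = 5.0
    nb_dispersion: float = 0.1
    n_background_genes: int = 200
    library_size_range: tuple[float, float] = (800_000.0, 1_200_000.0)
    # geometry of planted super-enhancers
    constituent_width: int = 2000
    valley_width: int = 1000
    min_constituents: int = 3
    max_constituents: int = 5
    se_slot: int = 150_000
    target_tss_offset: int = 20_000      # inside the 50 kb window
    near_decoy_offset: int = 45_000      # inside the window, constant expression
    far_decoy_offset: int = 70_000       # outside the window
    gene_span: int = 1500
    # background enhancers (low-signal peaks present in every condition)
    n_background_peaks: int = 60
    background_peak_width: int = 1000
    background_peak_depth: float = 8.0
    # expression
    base_target_expression: float = 500.0
    background_expression: float = 50.0
    n_module_genes: int = 30
    module_fold: float = 4.0
    # planted core regulatory circuit
    plant_crc: bool = True

    def __post_init__(self) -> None:
        if not self.present_depth_mean > self.absent_depth_mean >= 0:
            raise ValueError("need present_depth_mean > absent_depth_mean >= 0")
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2")
        if self.valley_width >= 12_500:
            raise ValueError("valley_width must stay below the stitch distance")


@dataclass
class TruthRegion:
    """A planted super-enhancer with its dynamics pattern and target gene."""

    interval: GenomicInterval
    pattern: str
    n_constituents: int
    base_signal: float
    target_gene: str | None
    constituents: list[GenomicInterval] = field(default_factory=list)

    @property
    def presence(self) -> tuple[int, int, int]:
        return PATTERN_PRESENCE[self.pattern]


@dataclass
class ToyGenome:
    annotation: GeneAnnotation
    chrom_sizes: dict[str, int]
    sequences: dict[str, str]
    tf_catalog: dict[str, str]           # TF gene id -> motif id
    motifs: list[MotifPFM]
    module_sets: dict[str, GeneSetRecord]


@dataclass
class ChIPSim:
    samples: pd.DataFrame                # index: sample id; condition, replicate
    tracks: dict[str, CoverageTrack]
    peaks: dict[str, list[GenomicInterval]]
    input_track: CoverageTrack


# ---------------------------------------------------------------------------
# deterministic geometry
# ---------------------------------------------------------------------------


def _se_geometry(cfg: SimulationConfig):
    """Planted SE coordinates: (chrom, se index per chrom, constituents).

    SE k (patterns x repeats, fixed order) goes to chromosome ``k % n_chroms``
    at slot ``k // n_chroms``; constituent count cycles between
    min_constituents..max_constituents.
    """
    n_se = len(PATTERNS) * cfg.n_per_pattern
    span = cfg.max_constituents - cfg.min_constituents + 1
    out = []
    for k in range(n_se):
        pattern = PATTERNS[k // cfg.n_per_pattern]
        chrom = f"chr{k % cfg.n_chroms + 1}"
        slot = k // cfg.n_chroms
        n_c = cfg.min_constituents + (k % span)
        start = slot * cfg.se_slot + 10_000
        constituents = []
        pos = start
        for _ in range(n_c):
            constituents.append(GenomicInterval(chrom, pos, pos + cfg.constituent_width))
            pos += cfg.constituent_width + cfg.valley_width
        end = constituents[-1].end
        out.append((k, pattern, chrom, GenomicInterval(chrom, start, end), constituents))
    return out


def _chrom_regions(cfg: SimulationConfig):
    """Per-chromosome layout: (end of SE slots, gene region start, peak region
    start, required length)."""
    n_se = len(PATTERNS) * cfg.n_per_pattern
    layout = {}
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n_slots = (n_se - c + cfg.n_chroms - 1) // cfg.n_chroms if n_se else 0
        se_end = n_slots * cfg.se_slot
        gene_start = se_end + 60_000
        n_genes = _count_round_robin(cfg.n_background_genes + 2 * cfg.n_module_genes,
                                     cfg.n_chroms, c)
        peak_start = gene_start + n_genes * 5_000 + 60_000
        n_peaks = _count_round_robin(cfg.n_background_peaks, cfg.n_chroms, c)
        required = peak_start + n_peaks * 30_000 + 20_000
        layout[chrom] = (se_end, gene_start, peak_start, required)
    return layout


def _count_round_robin(total: int, n_bins: int, idx: int) -> int:
    return (total - idx + n_bins - 1) // n_bins if total else 0


def build_toy_genome(cfg: SimulationConfig) -> tuple[GeneAnnotation, dict[str, int], ToyGenome]:
    """Deterministic annotation and chromosome sizes, plus random sequence.

    Returns ``(annotation, chrom_sizes, genome)`` where ``genome`` bundles the
    sequences, motif catalog and planted gene modules.  Raises when a supplied
    ``chrom_length`` cannot hold the requested regions.
    """
    layout = _chrom_regions(cfg)
    chrom_sizes = {}
    for chrom, (_, _, _, required) in layout.items():
        if cfg.chrom_length is not None:
            if cfg.chrom_length < required:
                raise ValueError(
                    f"chrom_length {cfg.chrom_length} cannot hold the requested "
                    f"regions on {chrom} (need {required})"
                )
            chrom_sizes[chrom] = cfg.chrom_length
        else:
            chrom_sizes[chrom] = required

    genes: list[Gene] = []
    geometry = _se_geometry(cfg)
    for k, pattern, chrom, se_iv, _ in geometry:
        for label, offset in (
            ("T", cfg.target_tss_offset),
            ("ND", cfg.near_decoy_offset),
            ("FD", cfg.far_decoy_offset),
        ):
            tss = se_iv.end + offset
            genes.append(Gene(f"G{k:03d}{label}", chrom, tss, "+", tss, tss + cfg.gene_span))

    # background + module genes in a dedicated segment per chromosome
    module_up, module_down = [], []
    bg_ids = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    up_ids = [f"MODUP{i:03d}" for i in range(cfg.n_module_genes)]
    dn_ids = [f"MODDN{i:03d}" for i in range(cfg.n_module_genes)]
    module_up, module_down = up_ids, dn_ids
    all_extra = bg_ids + up_ids + dn_ids
    counters = {c: 0 for c in range(cfg.n_chroms)}
    for i, gid in enumerate(all_extra):
        c = i % cfg.n_chroms
        chrom = f"chr{c + 1}"
        tss = layout[chrom][1] + counters[c] * 5_000 + 500
        counters[c] += 1
        genes.append(Gene(gid, chrom, tss, "+", tss, tss + cfg.gene_span))

    annotation = GeneAnnotation(genes)

    # sequence: random bases, then spliced circuit motif sites
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    sequences = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, size in chrom_sizes.items():
        arr = bases[rng.integers(0, 4, size=size)]
        sequences[chrom] = arr.tobytes().decode("ascii")

    motifs = [
        MotifPFM(f"MA{i:04d}.1", _consensus_pfm(seq), name=f"TFMOT{i}")
        for i, seq in enumerate(_CRC_MOTIF_CONSENSUS + _DECOY_MOTIF_CONSENSUS)
    ]
    tf_catalog: dict[str, str] = {}
    if cfg.plant_crc and cfg.n_per_pattern > 0:
        crc_ses = [g for g in geometry if g[1] == "unchanged_present"]
        n_tf = min(4, len(crc_ses))
        tf_gene_ids = [f"G{crc_ses[i][0]:03d}T" for i in range(n_tf)]
        for i, gid in enumerate(tf_gene_ids):
            tf_catalog[gid] = motifs[i].motif_id
        # splice every circuit motif into the first constituent of each TF SE
        for i in range(n_tf):
            _, _, chrom, _, constituents = crc_ses[i]
            seq = sequences[chrom]
            first = constituents[0]
            for j in range(n_tf):
                pos = first.start + 200 + 30 * j
                site = _CRC_MOTIF_CONSENSUS[j]
                seq = seq[:pos] + site + seq[pos + len(site):]
            sequences[chrom] = seq
        # decoy TF catalog entries: background genes without a super-enhancer
        if len(bg_ids) >= 2:
            tf_catalog[bg_ids[0]] = motifs[4].motif_id
            tf_catalog[bg_ids[1]] = motifs[5].motif_id

    module_sets = {
        "MOD:NEURON": GeneSetRecord("MOD:NEURON", "neuronal-like planted module",
                                    tuple(module_up)),
        "MOD:CYCLE": GeneSetRecord("MOD:CYCLE", "cell-cycle-like planted module",
                                   tuple(module_down)),
    }
    genome = ToyGenome(
        annotation=annotation,
        chrom_sizes=chrom_sizes,
        sequences=sequences,
        tf_catalog=tf_catalog,
        motifs=motifs,
        module_sets=module_sets,
    )
    return annotation, chrom_sizes, genome


def _consensus_pfm(consensus: str, strength: float = 20.0) -> np.ndarray:
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = strength
    return counts


def plant_truth(genome: ToyGenome, cfg: SimulationConfig) -> list[TruthRegion]:
    """The planted super-enhancer regions, ``n_per_pattern`` per class."""
    truth = []
    for k, pattern, chrom, se_iv, constituents in _se_geometry(cfg):
        target = f"G{k:03d}T"
        expected_area = cfg.present_depth_mean * cfg.constituent_width * len(constituents)
        truth.append(
            TruthRegion(
                interval=se_iv,
                pattern=pattern,
                n_constituents=len(constituents),
                base_signal=expected_area,
                target_gene=target if target in genome.annotation else None,
            )
        )
        truth[-1].constituents = list(constituents)
    return truth


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------


def _background_peak_intervals(cfg: SimulationConfig) -> list[GenomicInterval]:
    layout = _chrom_regions(cfg)
    out = []
    for i in range(cfg.n_background_peaks):
        c = i % cfg.n_chroms
        chrom = f"chr{c + 1}"
        start = layout[chrom][2] + (i // cfg.n_chroms) * 30_000
        out.append(GenomicInterval(chrom, start, start + cfg.background_peak_width))
    return out


def simulate_h3k27ac(
    truth: list[TruthRegion], cfg: SimulationConfig, chrom_sizes: dict[str, int]
) -> ChIPSim:
    """Per (condition, replicate) coverage + called peaks, plus a flat input.

    Constituents of a present SE emit depth ``present_depth_mean x
    lognormal(0, replicate_noise_sd)``; valleys and everything else sit at the
    ``absent_depth_mean`` floor; low-depth background enhancers are present in
    every sample.  Peaks are reported wherever depth reaches the calling
    threshold.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    bg_peaks = _background_peak_intervals(cfg)
    sample_rows = []
    tracks: dict[str, CoverageTrack] = {}
    peaks: dict[str, list[GenomicInterval]] = {}
    for ci, cond in enumerate(cfg.conditions):
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{cond}_rep{rep}"
            sample_rows.append((sid, cond, rep))
            features: dict[str, list[tuple[int, int, float]]] = {
                chrom: [] for chrom in chrom_sizes
            }
            for region in truth:
                present = region.presence[ci]
                for const in region.constituents:
                    noise = float(np.exp(rng.normal(0.0, cfg.replicate_noise_sd))) \
                        if cfg.replicate_noise_sd > 0 else 1.0
                    if not present:
                        continue
                    depth = cfg.present_depth_mean * noise
                    features[const.chrom].append((const.start, const.end, depth))
            for pk in bg_peaks:
                noise = float(np.exp(rng.normal(0.0, cfg.replicate_noise_sd))) \
                    if cfg.replicate_noise_sd > 0 else 1.0
                features[pk.chrom].append((pk.start, pk.end, cfg.background_peak_depth * noise))
            track = _track_with_floor(features, chrom_sizes, cfg.absent_depth_mean)
            tracks[sid] = track
            peaks[sid] = _call_threshold_peaks(track, cfg.peak_call_threshold)

    input_track = _track_with_floor(
        {chrom: [] for chrom in chrom_sizes}, chrom_sizes, cfg.absent_depth_mean
    )
    samples = pd.DataFrame(
        [(c, r) for _, c, r in sample_rows],
        index=[s for s, _, _ in sample_rows],
        columns=["condition", "replicate"],
    )
    samples.index.name = "sample_id"
    return ChIPSim(samples=samples, tracks=tracks, peaks=peaks, input_track=input_track)


def _track_with_floor(
    features: dict[str, list[tuple[int, int, float]]],
    chrom_sizes: dict[str, int],
    floor: float,
) -> CoverageTrack:
    runs = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        for start, end, depth in sorted(features.get(chrom, [])):
            if start > pos and floor > 0:
                runs.append((chrom, pos, start, floor))
            runs.append((chrom, start, end, depth))
            pos = end
        if pos < size and floor > 0:
            runs.append((chrom, pos, size, floor))
    return CoverageTrack.from_runs(runs, merge_equal=False)


def _call_threshold_peaks(track: CoverageTrack, threshold: float) -> list[GenomicInterval]:
    """Maximal runs of depth >= threshold (adjacent qualifying runs merged)."""
    out: list[GenomicInterval] = []
    for chrom in track.chroms:
        open_start = None
        open_end = None
        for start, end, depth in track.runs(chrom):
            if depth >= threshold:
                if open_end == start:
                    open_end = end
                else:
                    if open_start is not None:
                        out.append(GenomicInterval(chrom, open_start, open_end))
                    open_start, open_end = start, end
            else:
                if open_start is not None:
                    out.append(GenomicInterval(chrom, open_start, open_end))
                    open_start = open_end = None
        if open_start is not None:
            out.append(GenomicInterval(chrom, open_start, open_end))
    return out


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: list[TruthRegion],
    genome: ToyGenome,
    cfg: SimulationConfig,
    chip: ChIPSim,
) -> ExpressionMatrix:
    """Negative-binomial counts whose target-gene means track SE H3K27ac.

    A target gene's mean in sample s is ``base_target_expression`` times the
    ratio of its SE's constituent H3K27ac area in that sample's ChIP track to
    the expected fully-present area; decoys, background and module genes have
    condition-dependent constant means.  ``nb_dispersion=0`` is the
    deterministic degenerate case (counts = rounded means).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    sample_ids = list(chip.samples.index)
    lib = rng.uniform(*cfg.library_size_range, size=len(sample_ids))
    lib_factor = lib / lib.mean()

    target_of = {r.target_gene: r for r in truth if r.target_gene}
    cond_of = chip.samples["condition"].to_dict()
    means = {}
    for gene in genome.annotation.genes:
        gid = gene.gene_id
        row = np.zeros(len(sample_ids))
        for j, sid in enumerate(sample_ids):
            if gid in target_of:
                region = target_of[gid]
                area = sum(
                    chip.tracks[sid].interval_area(c) for c in region.constituents
                )
                expected = cfg.present_depth_mean * cfg.constituent_width * region.n_constituents
                mu = cfg.base_target_expression * area / expected
            elif gid.startswith("MODUP"):
                fold = cfg.module_fold if cond_of[sid] in ("treated", "withdrawn") else 1.0
                mu = cfg.background_expression * fold
            elif gid.startswith("MODDN"):
                fold = 1.0 if cond_of[sid] == "control" else 1.0 / cfg.module_fold
                mu = cfg.background_expression * cfg.module_fold * fold
            else:
                mu = cfg.background_expression
            row[j] = mu * lib_factor[j]
        means[gid] = row

    data = {}
    for gid, mu_row in means.items():
        if cfg.nb_dispersion == 0:
            data[gid] = np.rint(mu_row).astype(np.int64)
        else:
            n = 1.0 / cfg.nb_dispersion
            p = n / (n + np.maximum(mu_row, 1e-12))
            data[gid] = rng.negative_binomial(n, p)
    values = pd.DataFrame.from_dict(data, orient="index", columns=sample_ids)
    samples = chip.samples.copy()
    samples["cell_line"] = "SIM1"
    return ExpressionMatrix(values=values, samples=samples)


def simulate_all(cfg: SimulationConfig):
    """Convenience wrapper: genome, truth, ChIP and expression in one call."""
    annotation, chrom_sizes, genome = build_toy_genome(cfg)
    truth = plant_truth(genome, cfg)
    chip = simulate_h3k27ac(truth, cfg, chrom_sizes)
    expr = simulate_expression(truth, genome, cfg, chip)
    return genome, truth, chip, expr
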