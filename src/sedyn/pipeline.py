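"""End-to-end orchestration: simulate -> call-se -> consensus -> dynamics ->
link -> expression -> crc -> report, with a structured config, derived
per-stage seeds, and a run manifest.

Every stage writes its tables before the next starts; rerunning with the
same config and seed reproduces identical non-log outputs (the manifest,
which carries timestamps, is provenance, not data).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import crc as crcmod
from . import dynamics as dyn
from . import expression as exprmod
from . import io as sio
from . import linking
from . import rose
from .evaluation import link_precision_recall, pattern_recovery
from .intervals import CoverageTrack, GenomicInterval, merge_intervals
from .simulate import SimulationConfig, simulate_all

__all__ = ["PipelineConfig", "PipelineResult", "run", "report", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived by hashing the stage name with the global seed,
    so stage-level reproducibility is independent of execution order."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with their pipeline defaults."""

    out_dir: str = "sedyn_out"
    seed: int = 0
    simulate: bool = True
    # simulation overrides (applied on top of SimulationConfig defaults)
    sim_n_per_pattern: int = 5
    sim_replicate_noise_sd: float = 0.3
    # super-enhancer calling
    stitch_distance: int = 12500
    tss_exclusion: bool = False
    # consensus
    min_support: int = 2
    min_overlap_bp: int = 1
    # dynamics
    bin_width: int = 200
    n_states: int = 8
    binarize_p: float = 1e-4
    # target linking
    link_window: int = 50_000
    link_alpha: float = 0.05
    # expression
    padj_threshold: float = 0.05
    lfc_threshold: float = 2.0
    # CRC
    crc_expression_cutoff: float = 33.0
    crc_extension: int = 500
    crc_score_fraction: float = 0.8
    crc_condition: str = "treated"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self, n_replicates: int) -> None:
        if self.min_support > n_replicates:
            raise ValueError(
                f"min_support={self.min_support} exceeds n_replicates={n_replicates}"
            )


@dataclass
class PipelineResult:
    """In-memory handles on everything the run produced."""

    config: PipelineConfig
    out_dir: Path
    genome: object = None
    truth: list = field(default_factory=list)
    chip: object = None
    expr: object = None
    per_sample_regions: dict = field(default_factory=dict)
    per_condition_highconf: dict = field(default_factory=dict)
    consensus: list = field(default_factory=list)
    signal_raw: object = None
    signal_norm: object = None
    bins: object = None
    hmm: object = None
    labels: object = None
    pattern_calls: list = field(default_factory=list)
    links: list = field(default_factory=list)
    de_results: dict = field(default_factory=dict)
    module_scores: object = None
    crc_networks: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig) -> PipelineResult:
    """Execute all stages on a synthetic dataset with planted truth.

    Writes each stage's tables under ``config.out_dir`` and a run manifest
    (written on success or failure).
    """
    out = Path(config.out_dir)
    sim_cfg = SimulationConfig(
        seed=stage_seed(config.seed, "simulate"),
        n_per_pattern=config.sim_n_per_pattern,
        replicate_noise_sd=config.sim_replicate_noise_sd,
    )
    config.validate(sim_cfg.n_replicates)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "checksums": {},
    }
    result = PipelineResult(config=config, out_dir=out)
    try:
        _run_stages(config, sim_cfg, out, manifest, result)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return result


def _run_stages(config, sim_cfg, out, manifest, result):
    # --- simulate -----------------------------------------------------------
    genome, truth, chip, expr = simulate_all(sim_cfg)
    result.genome, result.truth, result.chip, result.expr = genome, truth, chip, expr
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    sio.write_annotation_file(data_dir / "annotation.tsv", genome.annotation)
    sio.write_expression_file(data_dir / "expression.tsv", expr)
    sio.write_motif_file(data_dir / "motifs.jaspar", genome.motifs)
    sio.write_coverage_file(data_dir / "input.bedGraph", chip.input_track)
    for sid in chip.samples.index:
        sio.write_interval_file(data_dir / f"{sid}.narrowPeak", chip.peaks[sid],
                                dialect="narrowPeak")
    with open(data_dir / "truth.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tpattern\tn_constituents\ttarget_gene\n")
        for r in truth:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                     f"{r.pattern}\t{r.n_constituents}\t{r.target_gene or '.'}\n")
    manifest["stages"]["simulate"] = {
        "n_truth_regions": len(truth),
        "n_samples": len(chip.samples),
        "n_genes": len(expr.gene_ids),
    }
    manifest["checksums"]["truth.tsv"] = _checksum(data_dir / "truth.tsv")
    manifest["checksums"]["annotation.tsv"] = _checksum(data_dir / "annotation.tsv")

    # --- call-se ------------------------------------------------------------
    rose_cfg = rose.RoseConfig(
        stitch_distance=config.stitch_distance, tss_exclusion=config.tss_exclusion
    )
    per_sample: dict[str, list[rose.StitchedRegion]] = {}
    rows = []
    for sid in chip.samples.index:
        regions = rose.stitch(chip.peaks[sid], rose_cfg)
        for r in regions:
            r.signal = rose.score_region(r, chip.tracks[sid], chip.input_track)
        ranked = rose.call_superenhancers(regions)
        per_sample[sid] = ranked
        for r in ranked:
            rows.append((sid, r.interval.chrom, r.interval.start, r.interval.end,
                         r.n_constituents, r.signal, r.rank, r.is_super))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                "n_constituents", "signal", "rank", "is_super"]
                 ).to_csv(out / "stitched_regions.tsv", sep="\t", index=False)
    result.per_sample_regions = per_sample
    manifest["stages"]["call_se"] = {
        "n_regions": len(rows),
        "n_super": int(sum(r[-1] for r in rows)),
    }

    # --- consensus ----------------------------------------------------------
    conditions = list(sim_cfg.conditions)
    highconf: dict[str, list[GenomicInterval]] = {}
    for cond in conditions:
        rep_sets = []
        for sid in chip.samples.index[chip.samples["condition"] == cond]:
            rep_sets.append([r.interval for r in per_sample[sid] if r.is_super])
        highconf[cond] = cns.replicate_filter(
            rep_sets, min_support=config.min_support,
            min_overlap_bp=config.min_overlap_bp,
        )
    consensus = cns.build_consensus(highconf)
    signal_raw = cns.quantify_matrix(consensus, chip.tracks, chip.samples)
    signal_norm = cns.normalize_library(signal_raw)
    result.per_condition_highconf = highconf
    result.consensus, result.signal_raw, result.signal_norm = (
        consensus, signal_raw, signal_norm)
    sio.write_interval_file(
        out / "consensus_se.bed",
        [GenomicInterval(se.interval.chrom, se.interval.start, se.interval.end,
                         name=se.se_id) for se in consensus],
    )
    signal_norm.values.to_csv(out / "signal_matrix.tsv", sep="\t",
                              index_label="se_id")
    manifest["stages"]["consensus"] = {
        "n_highconf": {c: len(v) for c, v in highconf.items()},
        "n_consensus": len(consensus),
    }

    # --- dynamics -----------------------------------------------------------
    pooled = {}
    for cond in conditions:
        sids = chip.samples.index[chip.samples["condition"] == cond]
        pooled[cond] = CoverageTrack.pool([chip.tracks[s] for s in sids])
    bins = dyn.binarize(pooled, genome.chrom_sizes, bin_width=config.bin_width,
                        p_threshold=config.binarize_p)
    hmm = dyn.fit_state_model(bins, n_states=config.n_states,
                              seed=stage_seed(config.seed, "dynamics"))
    labels = dyn.decode(bins, hmm)
    calls = dyn.call_patterns(consensus, bins, hmm, labels=labels)
    result.bins, result.hmm, result.labels, result.pattern_calls = (
        bins, hmm, labels, calls)
    with open(out / "hmm_model.json", "w") as fh:
        json.dump({
            "initial": hmm.initial.tolist(),
            "transition": hmm.transition.tolist(),
            "emission": hmm.emission.tolist(),
            "log_likelihoods": hmm.log_likelihoods,
            "converged": hmm.converged,
        }, fh, indent=2)
    pd.DataFrame(
        [(c.se_id, c.state, *c.presence, c.pattern) for c in calls],
        columns=["se_id", "state", "p_control", "p_treated", "p_withdrawn",
                 "pattern"],
    ).to_csv(out / "se_patterns.tsv", sep="\t", index=False)
    manifest["stages"]["dynamics"] = {
        "n_bins": bins.n_bins,
        "em_iterations": len(hmm.log_likelihoods),
        "converged": hmm.converged,
    }

    # --- link ---------------------------------------------------------------
    logfpm = exprmod.log_fpm(expr.values, expr.library_sizes)
    links = linking.link_all(consensus, genome.annotation, signal_norm.values,
                             logfpm, window=config.link_window,
                             alpha=config.link_alpha)
    result.links = links
    pd.DataFrame(
        [(l.se_id, l.gene_id, l.distance,
          "" if l.r is None else f"{l.r:.6g}",
          "" if l.p is None else f"{l.p:.6g}", l.method) for l in links],
        columns=["se_id", "gene_id", "distance", "r", "p", "method"],
    ).to_csv(out / "se_gene_links.tsv", sep="\t", index=False)
    manifest["stages"]["link"] = {
        "n_links": len(links),
        "n_correlation": sum(l.method == "correlation" for l in links),
    }

    # --- expression ---------------------------------------------------------
    sample_by_cond = {
        c: list(chip.samples.index[chip.samples["condition"] == c])
        for c in conditions
    }
    contrasts = [("treated", "control"), ("withdrawn", "treated"),
                 ("withdrawn", "control")]
    de_results = {}
    for b, a in contrasts:
        label = f"{b}_vs_{a}"
        de_results[label] = exprmod.differential_expression(
            expr.values, expr.library_sizes, sample_by_cond[a], sample_by_cond[b],
            contrast=label,
        )
        de_results[label].table.to_csv(out / f"de_{label}.tsv", sep="\t",
                                       index_label="gene_id")
    scores = pd.DataFrame({
        sid: exprmod.module_score(logfpm, gs)
        for sid, gs in genome.module_sets.items()
    }).T
    scores.to_csv(out / "module_scores.tsv", sep="\t", index_label="set_id")
    result.de_results, result.module_scores = de_results, scores
    manifest["stages"]["expression"] = {
        "contrasts": list(de_results),
        "n_significant": {
            k: int(len(v.significant(config.padj_threshold, config.lfc_threshold)))
            for k, v in de_results.items()
        },
    }

    # --- crc ----------------------------------------------------------------
    pwms = {m.motif_id: crcmod.pwm_from_pfm(m) for m in genome.motifs}
    se_constituents = _consensus_constituents(consensus, chip, conditions)
    networks = {}
    fpm = (expr.values.div(expr.library_sizes, axis=1) * 1e6)
    for cond in conditions:
        cond_expr = fpm[sample_by_cond[cond]].mean(axis=1)
        nodes = crcmod.candidate_crc_tfs(
            links, genome.tf_catalog, cond_expr, cutoff=config.crc_expression_cutoff
        )
        if nodes:
            net = crcmod.build_network(
                nodes, se_constituents, genome.sequences, pwms, genome.tf_catalog,
                extension=config.crc_extension,
                score_fraction=config.crc_score_fraction,
            )
            networks[cond] = crcmod.find_crcs(net)
        else:
            networks[cond] = crcmod.CRCNetwork(nodes=[], edges=set())
    result.crc_networks = networks
    with open(out / "crc_cliques.json", "w") as fh:
        json.dump({
            cond: {
                "nodes": [n.tf_id for n in net.nodes],
                "edges": sorted(map(list, net.edges)),
                "cliques": [list(c) for c in net.cliques],
                "tf_frequency": net.tf_frequency,
            } for cond, net in networks.items()
        }, fh, indent=2)
    manifest["stages"]["crc"] = {
        cond: {"n_nodes": len(net.nodes), "n_cliques": len(net.cliques)}
        for cond, net in networks.items()
    }

    # --- report -------------------------------------------------------------
    result.report = report(result)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    manifest["stages"]["report"] = {"written": True}


def _consensus_constituents(consensus, chip, conditions):
    """Constituents per consensus SE: merged called peaks inside its span,
    pooled over every sample (an SE absent in one condition still has its
    constituents defined by the conditions where it is present)."""
    out: dict[str, list[GenomicInterval]] = {}
    for se in consensus:
        inside = [
            pk
            for sid in chip.samples.index
            for pk in chip.peaks[sid]
            if pk.overlap_bp(se.interval) > 0
        ]
        out[se.se_id] = merge_intervals(inside, min_gap=1)
    return out


def report(result: PipelineResult) -> dict:
    """Summary tallies: SE counts, pattern table, maintained/reverted
    fractions, link methods, CRC membership, and truth-recovery metrics."""
    calls = result.pattern_calls
    pattern_counts: dict[str, int] = {}
    for c in calls:
        pattern_counts[c.pattern] = pattern_counts.get(c.pattern, 0) + 1
    gained = [c for c in calls if c.pattern.startswith("gained")]
    lost = [c for c in calls if c.pattern.startswith("lost")]

    def _frac(sub, label):
        n = len(sub)
        k = sum(c.pattern.endswith("maintained") for c in sub)
        return {"n": n, "maintained": k, "reverted": n - k,
                "maintained_fraction": k / n if n else None}

    rep = {
        "n_consensus_se": len(result.consensus),
        "per_condition_highconf": {
            c: len(v) for c, v in result.per_condition_highconf.items()
        },
        "pattern_counts": pattern_counts,
        "gained": _frac(gained, "gained"),
        "lost": _frac(lost, "lost"),
        "link_methods": {
            m: sum(l.method == m for l in result.links)
            for m in ("correlation", "nearest-fallback")
        },
        "crc": {
            cond: {"cliques": [list(c) for c in net.cliques]}
            for cond, net in result.crc_networks.items()
        },
    }
    if result.truth:
        frac, n_correct, n_total = pattern_recovery(
            result.truth, result.consensus, calls)
        precision, recall = link_precision_recall(
            result.truth, result.consensus, result.links)
        rep["truth_recovery"] = {
            "pattern_fraction": frac,
            "n_correct": n_correct,
            "n_recoverable": n_total,
            "link_precision": precision,
            "link_recall": recall,
        }
    return rep
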