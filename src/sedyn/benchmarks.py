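"""Whole-package validation measurements.

Each function sets up a randomized or planted problem, runs the relevant
implementation, and measures agreement with an independent reference
(brute-force oracle, planted truth, or closed form).  Used by the test suite
and by ``scripts/acceptance.py``; every function takes an explicit seed.
"""

from __future__ import annotations

import tempfile
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import oracles
from .consensus import SignalMatrix, normalize_library
from .crc import CRCNetwork, TFNode, find_crcs
from .dynamics import BinMatrix, fit_state_model
from .expression import GeneSet, differential_expression, ora_hypergeometric
from .intervals import GenomicInterval
from .pipeline import PipelineConfig, run
from .rose import RoseConfig, elbow_cutoff_index, stitch

__all__ = [
    "stitch_oracle_agreement",
    "elbow_oracle_agreement",
    "pipeline_recovery",
    "hmm_emission_recovery_error",
    "normalization_invariance_error",
    "clique_oracle_agreement",
    "ora_fixture_pvalue",
    "de_null_type1_rate",
]


def stitch_oracle_agreement(
    n_sets: int = 1000, seed: int = 0, max_peaks: int = 200
) -> float:
    """Fraction of random peak sets where stitching matches the
    dilate-merge-contract oracle set-exactly (grouping of member peaks)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sets):
        n = int(rng.integers(1, max_peaks + 1))
        starts = np.sort(rng.integers(0, 500_000, n))
        widths = rng.integers(1, 4000, n)
        chroms = rng.choice(["chr1", "chr2", "chr3"], n)
        peaks = [
            GenomicInterval(str(c), int(s), int(s + w))
            for c, s, w in zip(chroms, starts, widths)
        ]
        dist = int(rng.choice([1000, 12_500, 40_000]))
        got = {
            frozenset((c.chrom, c.start, c.end) for c in r.constituents)
            for r in stitch(peaks, RoseConfig(stitch_distance=dist))
        }
        want = set(oracles.stitch_by_dilation(peaks, dist))
        agree += got == want
    return agree / n_sets


def elbow_oracle_agreement(n_vectors: int = 500, seed: int = 0) -> float:
    """Fraction of random signal vectors where the elbow cutoff index equals
    the exhaustive exact-arithmetic tangent scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        n = int(rng.integers(3, 200))
        signals = rng.integers(0, 100_000, n).tolist()
        got = elbow_cutoff_index(np.asarray(signals, dtype=float))
        want = oracles.elbow_by_tangent_scan(signals)
        agree += got == want
    return agree / n_vectors


def pipeline_recovery(
    noise_sd: float, seed: int = 0, n_per_pattern: int = 5,
    out_dir: str | None = None,
):
    """Run the full pipeline on synthetic data and score it against truth.

    Returns a dict with planted-pattern recovery fraction, link precision and
    recall, and the planted-circuit recovery flag.
    """
    if out_dir is None:
        tmp = tempfile.mkdtemp(prefix="sedyn_bench_")
        out_dir = str(Path(tmp) / f"run_noise{noise_sd}")
    cfg = PipelineConfig(out_dir=out_dir, seed=seed,
                         sim_n_per_pattern=n_per_pattern,
                         sim_replicate_noise_sd=noise_sd)
    result = run(cfg)
    rec = result.report["truth_recovery"]
    planted_tfs = tuple(sorted(result.genome.tf_catalog))
    planted_circuit = tuple(t for t in planted_tfs if t.endswith("T"))
    circuit_ok = all(
        net.cliques == [planted_circuit]
        for net in result.crc_networks.values()
    )
    return {
        "pattern_fraction": rec["pattern_fraction"],
        "n_correct": rec["n_correct"],
        "n_recoverable": rec["n_recoverable"],
        "link_precision": rec["link_precision"],
        "link_recall": rec["link_recall"],
        "circuit_recovered": circuit_ok,
        "result": result,
    }


def hmm_emission_recovery_error(
    n_bins: int = 100_000, seed: int = 0, self_transition: float = 0.95,
    corner_low: float = 0.1, corner_high: float = 0.9, max_iter: int = 100,
) -> float:
    """Max absolute emission error after optimal state matching.

    Samples a state path from a known sticky 8-state chain, draws Bernoulli
    presence calls from corner emissions, fits the model, and matches fitted
    to planted states by minimum-cost assignment on emission rows.
    """
    rng = np.random.default_rng(seed)
    K, C = 8, 3
    true_B = np.array(
        [[corner_high if (k >> c) & 1 else corner_low for c in range(C)]
         for k in range(K)]
    )
    A = np.full((K, K), (1 - self_transition) / (K - 1))
    np.fill_diagonal(A, self_transition)
    states = np.zeros(n_bins, dtype=np.int64)
    states[0] = rng.integers(K)
    # vectorized chain: jump times are geometric
    u = rng.random(n_bins)
    jump = u > self_transition
    for t in range(1, n_bins):
        if jump[t]:
            others = [k for k in range(K) if k != states[t - 1]]
            states[t] = others[int(rng.integers(K - 1))]
        else:
            states[t] = states[t - 1]
    X = (rng.random((n_bins, C)) < true_B[states]).astype(np.int8)
    bm = BinMatrix(
        values=X,
        conditions=("control", "treated", "withdrawn"),
        bin_chroms=np.array(["chr1"] * n_bins, dtype=object),
        bin_starts=np.arange(n_bins) * 200,
        bin_width=200,
        segments=[(0, n_bins)],
    )
    params = fit_state_model(bm, n_states=K, seed=seed, max_iter=max_iter)
    cost = np.abs(params.emission[:, None, :] - true_B[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return float(np.abs(params.emission[rows] - true_B[cols]).max())


def normalization_invariance_error(seed: int = 0, scale: float = 1e3) -> float:
    """Max relative difference of the normalized matrix after globally
    rescaling every library size by a constant."""
    rng = np.random.default_rng(seed)
    values = pd.DataFrame(
        rng.uniform(0, 1e5, (30, 9)),
        index=[f"SE{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(9)],
    )
    lib = pd.Series(rng.uniform(1e5, 1e7, 9), index=values.columns)
    samples = pd.DataFrame(index=values.columns)
    base = normalize_library(SignalMatrix(values, lib, samples)).values
    scaled = normalize_library(SignalMatrix(values, lib * scale, samples)).values
    denom = np.maximum(np.abs(base.to_numpy()), 1e-300)
    return float((np.abs(base.to_numpy() - scaled.to_numpy()) / denom).max())


def clique_oracle_agreement(n_graphs: int = 100, seed: int = 0) -> float:
    """Fraction of random digraphs (<= 10 nodes) where circuitry enumeration
    equals exhaustive subset enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(1, 11))
        tfs = [f"T{i}" for i in range(n)]
        edges = {(a, b) for a in tfs for b in tfs if rng.random() < 0.5}
        net = CRCNetwork(
            nodes=[TFNode(t, f"SE_{t}", 99.0) for t in tfs], edges=edges
        )
        got = find_crcs(net).cliques
        want = oracles.maximal_cliques_bruteforce(tfs, edges)
        agree += got == want
    return agree / n_graphs


def ora_fixture_pvalue() -> tuple[float, float]:
    """(computed p, exact expected p) for the universe-20/set-5/list-5
    perfect-overlap fixture; expected = 1 / C(20, 5)."""
    universe = [f"g{i}" for i in range(20)]
    gs = {"S": GeneSet("S", "fixture", tuple(universe[:5]))}
    res = ora_hypergeometric(universe[:5], gs, universe)
    return float(res.loc["S", "p"]), 1.0 / comb(20, 5)


def de_null_type1_rate(
    n_genes: int = 2000, n_per_group: int = 10, seed: int = 0,
    mean: float = 100.0, dispersion: float = 0.1, alpha: float = 0.05,
) -> float:
    """Fraction of null genes rejected at raw p < alpha by the stand-in DE
    test on negative-binomial counts with no planted effect."""
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = pd.DataFrame(
        rng.negative_binomial(r, p, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    lib = pd.Series([float(mean * n_genes)] * n_samples, index=counts.columns)
    de = differential_expression(
        counts, lib,
        list(counts.columns[:n_per_group]), list(counts.columns[n_per_group:]),
    )
    return float((de.table["p"] < alpha).mean())
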