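"""Chromatin-state dynamics via a multivariate Bernoulli hidden Markov model.

The genome is tiled into fixed-width bins (default 200 bp) and each bin is
called present/absent for H3K27ac independently in each treatment condition
(control, treated, withdrawn) with a Poisson upper-tail test against the
genome-wide background rate.  An 8-state HMM — one state per presence/absence
combination over the three conditions — with independent per-condition
Bernoulli emissions is fitted to the binary bin matrix by Baum-Welch EM, and
bins are labelled by Viterbi decoding.  Each super-enhancer is assigned its
predominant state (the state covering the largest fraction of its bins) and
classified from that state's thresholded emission row into
gained/lost x maintained/reverted, unchanged, or other.

The Markov chain is reset at chromosome boundaries: no transition is counted
or scored across a sequence break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .consensus import ConsensusSE
from .intervals import CoverageTrack

__all__ = [
    "BinMatrix",
    "HMMParams",
    "PatternCall",
    "RESPONSIVE_PATTERNS",
    "PATTERN_BY_PRESENCE",
    "binarize",
    "fit_state_model",
    "decode",
    "predominant_state",
    "classify_pattern",
    "call_patterns",
]

logger = logging.getLogger(__name__)

#: the closed vocabulary of responsive dynamics classes
RESPONSIVE_PATTERNS = (
    "gained_maintained",
    "gained_reverted",
    "lost_maintained",
    "lost_reverted",
)

#: binary (control, treated, withdrawn) presence -> pattern label
PATTERN_BY_PRESENCE = {
    (0, 1, 1): "gained_maintained",
    (0, 1, 0): "gained_reverted",
    (1, 0, 0): "lost_maintained",
    (1, 0, 1): "lost_reverted",
    (0, 0, 0): "unchanged",
    (1, 1, 1): "unchanged",
    (0, 0, 1): "other",
    (1, 1, 0): "other",
}


@dataclass
class BinMatrix:
    """Binary presence calls on fixed-width bins, one column per condition.

    ``values`` is (n_bins, n_conditions) in {0,1}; ``bin_chroms`` and
    ``bin_starts`` locate each bin; ``segments`` lists (start, stop) index
    ranges of contiguous same-chromosome bins (chain-reset boundaries).
    """

    values: np.ndarray
    conditions: tuple[str, ...]
    bin_chroms: np.ndarray
    bin_starts: np.ndarray
    bin_width: int
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("bin matrix entries must be 0/1")
        self.values = v.astype(np.int8)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_range(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins overlapping [start, end) on chrom."""
        mask = self.bin_chroms == chrom
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            return idx
        starts = self.bin_starts[idx]
        keep = (starts < end) & (starts + self.bin_width > start)
        return idx[keep]


@dataclass
class HMMParams:
    """Bernoulli-emission HMM parameters.

    ``emission[k, c]`` is the probability of observing H3K27ac presence in
    condition c given state k; rows of ``transition`` sum to 1.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)


@dataclass
class PatternCall:
    """Pattern classification of one consensus super-enhancer."""

    se_id: str
    state: int
    presence: tuple[float, ...]      # predominant state's emission row
    pattern: str
    densities: np.ndarray            # per-state window-count fraction


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize(
    coverage_by_condition: dict[str, CoverageTrack],
    chrom_sizes: dict[str, int],
    bin_width: int = 200,
    background_rate: float | None = None,
    p_threshold: float = 1e-4,
) -> BinMatrix:
    """Poisson presence/absence calls on fixed-width bins per condition.

    A bin is present (1) when the upper-tail Poisson p-value of its rounded
    coverage area under the background mean is below ``p_threshold``.  The
    background rate defaults to the genome-wide mean per-bin area of that
    condition's track.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    conditions = tuple(coverage_by_condition)
    chroms = sorted(chrom_sizes)
    chrom_bins = {c: int(np.ceil(chrom_sizes[c] / bin_width)) for c in chroms}
    n_bins = sum(chrom_bins.values())

    values = np.zeros((n_bins, len(conditions)), dtype=np.int8)
    bin_chroms = np.empty(n_bins, dtype=object)
    bin_starts = np.zeros(n_bins, dtype=np.int64)
    segments: list[tuple[int, int]] = []
    offset = 0
    for chrom in chroms:
        nb = chrom_bins[chrom]
        bin_chroms[offset : offset + nb] = chrom
        bin_starts[offset : offset + nb] = np.arange(nb) * bin_width
        segments.append((offset, offset + nb))
        offset += nb

    for j, cond in enumerate(conditions):
        track = coverage_by_condition[cond]
        areas = np.concatenate(
            [track.bin_areas(chrom, bin_width, chrom_sizes[chrom]) for chrom in chroms]
        )
        rate = background_rate if background_rate is not None else float(areas.mean())
        if rate <= 0:
            continue  # no signal anywhere: all-absent
        counts = np.rint(areas).astype(np.int64)
        # P(X >= k) under Poisson(rate)
        pvals = stats.poisson.sf(counts - 1, rate)
        values[:, j] = (pvals < p_threshold).astype(np.int8)

    return BinMatrix(
        values=values,
        conditions=conditions,
        bin_chroms=bin_chroms,
        bin_starts=bin_starts,
        bin_width=bin_width,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# Baum-Welch EM
# ---------------------------------------------------------------------------

_EPS = 1e-10


def _corner_init(n_states: int, n_conditions: int) -> np.ndarray:
    """Seed emission rows at the binary corners, smoothed to {0.1, 0.9}.

    With 8 states over 3 conditions each state starts at one presence/absence
    combination, giving an identifiable start and a stable state<->pattern
    mapping.  Extra states (if any) start at 0.5.
    """
    corners = np.array(
        [[(k >> c) & 1 for c in range(n_conditions)] for k in range(2**n_conditions)],
        dtype=float,
    )
    emission = np.full((n_states, n_conditions), 0.5)
    take = min(n_states, len(corners))
    emission[:take] = 0.1 + 0.8 * corners[:take]
    return emission


def _emission_probs(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(T, K) likelihood of each observation under each state."""
    B = np.clip(emission, _EPS, 1 - _EPS)
    logp = X @ np.log(B).T + (1 - X) @ np.log(1 - B).T
    return np.exp(logp)


def _forward_backward(obs_prob, pi, A):
    """Scaled forward-backward for one segment.

    Returns (log-likelihood, gamma (T,K), xi_sum (K,K)).
    """
    T, K = obs_prob.shape
    alpha = np.zeros((T, K))
    scale = np.zeros(T)
    a = pi * obs_prob[0]
    scale[0] = a.sum() or _EPS
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * obs_prob[t]
        scale[t] = a.sum() or _EPS
        alpha[t] = a / scale[t]
    beta = np.zeros((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = beta[t + 1] * obs_prob[t + 1]
        beta[t] = (A @ bb) / scale[t + 1]
        xi_sum += np.outer(alpha[t], bb / scale[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return float(np.sum(np.log(scale))), gamma, xi_sum


def fit_state_model(
    bins: BinMatrix,
    n_states: int = 8,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> HMMParams:
    """Baum-Welch EM for the Bernoulli-emission HMM.

    Emissions start at the smoothed binary corners; the initial distribution
    starts uniform and the transition matrix sticky (0.9 on the diagonal),
    reflecting that presence calls come in genomic runs — a uniform start
    lets the overwhelming all-absent background mass bleed into the rare
    states and collapse them (``seed`` only perturbs the start
    infinitesimally to break symmetry when extra states exist).  Chromosome
    breaks reset the chain.  Raises on fewer than ``n_states * 10`` bins;
    returns with ``converged=False`` and a warning if ``max_iter`` is hit
    before the log-likelihood gain drops below ``tol``.
    """
    X = bins.values.astype(np.float64)
    T, C = X.shape
    if T < n_states * 10:
        raise ValueError(f"need >= {n_states * 10} bins to fit {n_states} states, got {T}")
    rng = np.random.default_rng(seed)
    pi = np.full(n_states, 1.0 / n_states)
    A = np.full((n_states, n_states), 0.1 / (n_states - 1))
    np.fill_diagonal(A, 0.9)
    B = _corner_init(n_states, C)
    if n_states > 2**C:
        B = np.clip(B + rng.normal(0, 1e-3, B.shape), _EPS, 1 - _EPS)

    segments = bins.segments or [(0, T)]
    log_likelihoods: list[float] = []
    converged = False
    for _ in range(max_iter):
        obs_all = _emission_probs(X, B)
        ll = 0.0
        gamma_sum = np.zeros(n_states)
        gamma_obs = np.zeros((n_states, C))
        xi_total = np.zeros((n_states, n_states))
        pi_acc = np.zeros(n_states)
        gammas = np.zeros((T, n_states))
        for s0, s1 in segments:
            if s1 <= s0:
                continue
            seg_ll, gamma, xi = _forward_backward(obs_all[s0:s1], pi, A)
            ll += seg_ll
            gammas[s0:s1] = gamma
            pi_acc += gamma[0]
            xi_total += xi
        gamma_sum = gammas.sum(axis=0)
        gamma_obs = gammas.T @ X
        log_likelihoods.append(ll)
        if len(log_likelihoods) > 1 and ll - log_likelihoods[-2] < tol:
            converged = True
            break
        # M-step
        pi = pi_acc / pi_acc.sum()
        row = xi_total.sum(axis=1, keepdims=True)
        A = np.where(row > 0, xi_total / np.where(row > 0, row, 1.0), 1.0 / n_states)
        B = gamma_obs / np.maximum(gamma_sum[:, None], _EPS)
        B = np.clip(B, _EPS, 1 - _EPS)

    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return HMMParams(
        initial=pi,
        transition=A,
        emission=B,
        log_likelihoods=log_likelihoods,
        converged=converged,
    )


def decode(bins: BinMatrix, params: HMMParams) -> np.ndarray:
    """Viterbi path per chromosome segment (deterministic given params)."""
    X = bins.values.astype(np.float64)
    T = X.shape[0]
    K = params.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.clip(params.initial, _EPS, None))
        log_A = np.log(np.clip(params.transition, _EPS, None))
        B = np.clip(params.emission, _EPS, 1 - _EPS)
    log_obs = X @ np.log(B).T + (1 - X) @ np.log(1 - B).T
    path = np.zeros(T, dtype=np.int64)
    for s0, s1 in bins.segments or [(0, T)]:
        if s1 <= s0:
            continue
        n = s1 - s0
        delta = np.zeros((n, K))
        back = np.zeros((n, K), dtype=np.int64)
        delta[0] = log_pi + log_obs[s0]
        for t in range(1, n):
            cand = delta[t - 1][:, None] + log_A
            back[t] = np.argmax(cand, axis=0)
            delta[t] = cand[back[t], np.arange(K)] + log_obs[s0 + t]
        state = int(np.argmax(delta[-1]))
        out = np.zeros(n, dtype=np.int64)
        out[-1] = state
        for t in range(n - 2, -1, -1):
            state = back[t + 1][state]
            out[t] = state
        path[s0:s1] = out
    return path


# ---------------------------------------------------------------------------
# per-SE classification
# ---------------------------------------------------------------------------


def predominant_state(
    se: ConsensusSE, bins: BinMatrix, labels: np.ndarray, n_states: int
) -> tuple[int, np.ndarray]:
    """State covering the largest window-count fraction of the SE's bins.

    Ties break toward the lower state index.  Raises if the SE overlaps no
    bin.
    """
    idx = bins.bin_range(se.interval.chrom, se.interval.start, se.interval.end)
    if len(idx) == 0:
        raise ValueError(f"{se.se_id} overlaps no bins; cannot classify")
    counts = np.bincount(labels[idx], minlength=n_states)
    densities = counts / counts.sum()
    return int(np.argmax(densities)), densities


def classify_pattern(
    presence: np.ndarray | tuple[float, ...], present_threshold: float = 0.5
) -> str:
    """Map a (control, treated, withdrawn) presence-probability vector to its
    dynamics class by thresholding each entry at ``present_threshold``."""
    p = np.asarray(presence, dtype=float)
    if p.shape != (3,):
        raise ValueError("presence vector must have 3 entries (control, treated, withdrawn)")
    key = tuple(int(v > present_threshold) for v in p)
    return PATTERN_BY_PRESENCE[key]


def call_patterns(
    consensus: list[ConsensusSE],
    bins: BinMatrix,
    params: HMMParams,
    labels: np.ndarray | None = None,
    present_threshold: float = 0.5,
) -> list[PatternCall]:
    """Classify every consensus SE from its predominant state's emission row."""
    if labels is None:
        labels = decode(bins, params)
    calls = []
    for se in consensus:
        state, densities = predominant_state(se, bins, labels, params.n_states)
        presence = tuple(float(v) for v in params.emission[state])
        calls.append(
            PatternCall(
                se_id=se.se_id,
                state=state,
                presence=presence,
                pattern=classify_pattern(presence, present_threshold),
                densities=densities,
            )
        )
    return calls
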