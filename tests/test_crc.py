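"""PWM construction, motif scanning, and circuitry clique inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedyn.consensus import ConsensusSE
from sedyn.crc import (
    CRCNetwork,
    TFNode,
    build_network,
    candidate_crc_tfs,
    find_crcs,
    pwm_from_pfm,
    reverse_complement,
    scan,
)
from sedyn.intervals import GenomicInterval
from sedyn.io import MotifPFM
from sedyn.linking import SEGeneLink
from sedyn.oracles import maximal_cliques_bruteforce, scan_per_window


def _pfm(consensus, strength=20.0):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strength
    return MotifPFM("M1", counts)


class TestPwmFromPfm:
    def test_uniform_pfm_gives_zero_pwm(self):
        pfm = MotifPFM("M", np.ones((4, 5)))
        pwm = pwm_from_pfm(pfm)
        assert np.allclose(pwm.matrix, 0.0)

    def test_single_column_arithmetic(self):
        pfm = MotifPFM("M", np.array([[10.0], [0], [0], [0]]))
        pwm = pwm_from_pfm(pfm, pseudocount=0.5)
        assert pwm.matrix[0, 0] == pytest.approx(np.log2((10.5 / 12) / 0.25))

    def test_max_score_equals_best_sequence_bruteforce(self):
        rng = np.random.default_rng(0)
        pfm = MotifPFM("M", rng.uniform(0, 9, (4, 4)))
        pwm = pwm_from_pfm(pfm)
        best = max(
            sum(pwm.matrix["ACGT".index(b), j] for j, b in enumerate(word))
            for word in _all_words(4)
        )
        assert pwm.max_score == pytest.approx(best)


def _all_words(L):
    from itertools import product
    for combo in product("ACGT", repeat=L):
        yield "".join(combo)


class TestScan:
    def test_consensus_sequence_hits_at_zero_with_max_score(self):
        pwm = pwm_from_pfm(_pfm("ACGTAC"))
        hits = scan("ACGTAC", pwm)
        assert any(h.position == 0 and h.score == pytest.approx(pwm.max_score)
                   for h in hits)

    def test_all_n_sequence_has_no_hits(self):
        pwm = pwm_from_pfm(_pfm("ACGT"))
        assert scan("N" * 50, pwm) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        pwm = pwm_from_pfm(_pfm("ACGTACGT"))
        assert scan("ACG", pwm) == []

    def test_reverse_strand_hit_reported_at_forward_position(self):
        motif = "ACGGTCAAGC"
        pwm = pwm_from_pfm(_pfm(motif))
        seq = "T" * 20 + reverse_complement(motif) + "T" * 20
        hits = scan(seq, pwm)
        assert [(h.position, h.strand) for h in hits] == [(20, "-")]

    def test_random_sequence_matches_per_window_oracle(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=300))
        pfm = MotifPFM("M", rng.uniform(0, 10, (4, 6)))
        pwm = pwm_from_pfm(pfm)
        threshold = 0.8 * pwm.max_score
        got = {(h.position, h.strand) for h in scan(seq, pwm, 0.8)}
        want = {(p, s) for p, s, _ in scan_per_window(seq, pwm.matrix, threshold)}
        assert got == want

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pwm = pwm_from_pfm(MotifPFM("M", rng.uniform(0, 10, (4, 7))))
        fwd_hits = scan(seq, pwm, 0.75)
        rc_hits = scan(reverse_complement(seq), pwm, 0.75)
        n, L = len(seq), pwm.length
        mirrored = {(n - L - h.position, {"+": "-", "-": "+"}[h.strand],
                     round(h.score, 9)) for h in rc_hits}
        assert {(h.position, h.strand, round(h.score, 9)) for h in fwd_hits} \
            == mirrored

    def test_raising_score_fraction_never_adds_hits(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        pwm = pwm_from_pfm(MotifPFM("M", rng.uniform(0, 5, (4, 5))))
        loose = {(h.position, h.strand) for h in scan(seq, pwm, 0.6)}
        tight = {(h.position, h.strand) for h in scan(seq, pwm, 0.8)}
        assert tight <= loose


class TestCandidateTfs:
    def _links(self):
        return [SEGeneLink("SE1", "TFA", 0, 0.9, 1e-3, "correlation"),
                SEGeneLink("SE2", "TFB", 100, 0.8, 1e-2, "correlation"),
                SEGeneLink("SE3", "NOTF", 0, 0.9, 1e-3, "correlation")]

    def test_expression_cutoff_boundary(self):
        catalog = {"TFA": "M1", "TFB": "M2"}
        expr = {"TFA": 32.9, "TFB": 33.0}
        nodes = candidate_crc_tfs(self._links(), catalog, expr, cutoff=33.0)
        assert [n.tf_id for n in nodes] == ["TFB"]

    def test_non_tf_gene_never_a_node(self):
        catalog = {"TFA": "M1"}
        expr = {"TFA": 100.0, "NOTF": 1000.0}
        nodes = candidate_crc_tfs(self._links(), catalog, expr)
        assert [n.tf_id for n in nodes] == ["TFA"]


class TestBuildNetwork:
    def _setup(self, offset):
        """TF A's consensus site placed ``offset`` bp beyond B's constituent."""
        motif = "ACGGTCAAGC"
        chrom = "c"
        const = GenomicInterval(chrom, 2000, 3000)
        seq = list("T" * 6000)
        pos = const.end + offset if offset >= 0 else const.start + 100
        seq[pos : pos + len(motif)] = motif
        genome = {chrom: "".join(seq)}
        nodes = [TFNode("A", "SE_A", 50.0), TFNode("B", "SE_B", 50.0)]
        consts = {"SE_A": [GenomicInterval(chrom, 4500, 5000)],
                  "SE_B": [const]}
        pwms = {"M_A": pwm_from_pfm(_pfm(motif)),
                "M_B": pwm_from_pfm(_pfm("TGCATCGGAT"))}
        catalog = {"A": "M_A", "B": "M_B"}
        net = build_network(nodes, consts, genome, pwms, catalog, extension=500)
        return net

    def test_site_inside_constituent_gives_edge(self):
        assert ("A", "B") in self._setup(-1).edges

    def test_site_400bp_outside_still_within_extension(self):
        assert ("A", "B") in self._setup(400).edges

    def test_site_600bp_outside_beyond_extension(self):
        assert ("A", "B") not in self._setup(600).edges

    def test_missing_sequence_names_region(self):
        nodes = [TFNode("A", "SE_A", 50.0)]
        consts = {"SE_A": [GenomicInterval("chrX", 0, 100)]}
        with pytest.raises(KeyError, match="chrX"):
            build_network(nodes, consts, {}, {"M": pwm_from_pfm(_pfm("ACGT"))},
                          {"A": "M"})


class TestFindCrcs:
    def _net(self, tfs, edges):
        return CRCNetwork(nodes=[TFNode(t, f"SE_{t}", 99.0) for t in tfs],
                          edges=set(edges))

    def test_single_autoregulating_tf_is_a_clique(self):
        net = find_crcs(self._net(["A"], [("A", "A")]))
        assert net.cliques == [("A",)]

    def test_three_mutual_tfs_form_one_clique(self):
        tfs = ["A", "B", "C"]
        edges = {(a, b) for a in tfs for b in tfs}
        net = find_crcs(self._net(tfs, edges))
        assert net.cliques == [("A", "B", "C")]
        assert net.tf_frequency == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_tf_without_self_edge_in_no_clique(self):
        tfs = ["A", "B"]
        edges = {("A", "A"), ("A", "B"), ("B", "A")}  # B lacks self-edge
        net = find_crcs(self._net(tfs, edges))
        assert net.cliques == [("A",)]

    def test_one_directional_pair_not_interconnected(self):
        edges = {("A", "A"), ("B", "B"), ("A", "B")}
        net = find_crcs(self._net(["A", "B"], edges))
        assert net.cliques == [("A",), ("B",)]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_subset_enumeration_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        tfs = [f"T{i}" for i in range(n)]
        edges = {(a, b) for a in tfs for b in tfs if rng.random() < 0.45}
        got = find_crcs(self._net(tfs, edges)).cliques
        want = maximal_cliques_bruteforce(tfs, edges)
        assert got == want

    def test_planted_circuit_is_unique_maximal_clique(self, noisy_run):
        tf_ids = sorted(noisy_run.genome.tf_catalog)
        planted = tuple(t for t in tf_ids if t.startswith("G"))
        for cond in ("control", "treated", "withdrawn"):
            net = noisy_run.crc_networks[cond]
            assert net.cliques == [planted]
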