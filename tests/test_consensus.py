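"""Replicate consensus, cross-condition merge, normalization, z-scores."""

import numpy as np
import pandas as pd
import pytest

from sedyn.consensus import (
    ConsensusSE,
    SignalMatrix,
    build_consensus,
    normalize_library,
    quantify_matrix,
    replicate_filter,
    row_zscore,
)
from sedyn.intervals import CoverageTrack, GenomicInterval
from sedyn.oracles import coverage_area_per_bp


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestReplicateFilter:
    def test_support_one_of_three_dropped(self):
        out = replicate_filter([[_iv(100, 500)], [], []])
        assert out == []

    def test_one_bp_overlap_retained_as_union(self):
        out = replicate_filter([[_iv(100, 500)], [_iv(499, 900)], []])
        assert [(r.start, r.end) for r in out] == [(100, 900)]

    def test_identical_in_all_three_unchanged(self):
        out = replicate_filter([[_iv(100, 500)]] * 3)
        assert [(r.start, r.end) for r in out] == [(100, 500)]

    def test_touching_but_not_overlapping_not_supported(self):
        out = replicate_filter([[_iv(100, 500)], [_iv(500, 900)], []])
        assert out == []

    def test_min_support_above_replicates_is_config_error(self):
        with pytest.raises(ValueError, match="min_support"):
            replicate_filter([[], []], min_support=3)

    def test_min_support_one_equals_plain_merge(self):
        rng = np.random.default_rng(5)
        rep_sets = []
        for _ in range(3):
            starts = np.sort(rng.integers(0, 50_000, 8))
            rep_sets.append([_iv(int(s), int(s + rng.integers(100, 3000)))
                             for s in starts])
        merged = replicate_filter(rep_sets, min_support=1)
        # oracle: greedy union of every interval, strict overlap
        ivs = sorted((iv.start, iv.end) for reps in rep_sets for iv in reps)
        expected = []
        for s, e in ivs:
            if expected and s < expected[-1][1]:
                expected[-1] = (expected[-1][0], max(expected[-1][1], e))
            else:
                expected.append((s, e))
        assert [(r.start, r.end) for r in merged] == expected


class TestBuildConsensus:
    def test_disjoint_conditions_concatenate_sorted(self):
        out = build_consensus(
            {"a": [_iv(5000, 6000)], "b": [_iv(100, 200)], "c": []}
        )
        assert [(c.interval.start, c.interval.end) for c in out] == [
            (100, 200), (5000, 6000)]
        assert out[0].source_conditions == ("b",)

    def test_same_region_in_all_conditions_single_entry(self):
        out = build_consensus({c: [_iv(100, 900)] for c in "abc"})
        assert len(out) == 1
        assert sorted(out[0].source_conditions) == ["a", "b", "c"]
        assert out[0].support == {"a": 1, "b": 1, "c": 1}

    def test_transitive_chain_merges(self):
        out = build_consensus({
            "a": [_iv(0, 100)],
            "b": [_iv(90, 200)],
            "c": [_iv(190, 300)],
        })  # a-b overlap, b-c overlap, a-c disjoint
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 300)

    def test_output_disjoint_sorted_and_partitions_inputs(self):
        rng = np.random.default_rng(9)
        sets = {}
        for cond in ("a", "b", "c"):
            starts = np.sort(rng.integers(0, 100_000, 10))
            sets[cond] = [_iv(int(s), int(s + rng.integers(50, 4000)))
                          for s in starts]
        out = build_consensus(sets)
        for prev, cur in zip(out, out[1:]):
            if prev.interval.chrom == cur.interval.chrom:
                assert prev.interval.end <= cur.interval.start
        # every input region inside exactly one consensus region
        for cond, ivs in sets.items():
            for iv in ivs:
                containing = [
                    c for c in out
                    if c.interval.start <= iv.start and iv.end <= c.interval.end
                ]
                assert len(containing) == 1


class TestQuantifyAndNormalize:
    def _setup(self):
        consensus = [
            ConsensusSE("SE1", _iv(0, 1000), {}, ()),
            ConsensusSE("SE2", _iv(5000, 5100), {}, ()),
        ]
        coverage = {
            "s1": CoverageTrack.from_runs([("chr1", 0, 1000, 3.0)]),
            "s2": CoverageTrack.from_runs([("chr1", 0, 8000, 1.0)]),
        }
        samples = pd.DataFrame(index=["s1", "s2"])
        return consensus, coverage, samples

    def test_flat_depth_area(self):
        consensus, coverage, samples = self._setup()
        m = quantify_matrix(consensus, coverage, samples)
        assert m.values.loc["SE1", "s1"] == 3000.0
        assert m.values.loc["SE2", "s1"] == 0.0
        assert m.values.loc["SE2", "s2"] == 100.0

    def test_random_fixture_matches_per_bp_oracle(self):
        rng = np.random.default_rng(2)
        runs = []
        pos = 0
        for _ in range(15):
            pos += int(rng.integers(0, 50))
            w = int(rng.integers(1, 120))
            runs.append(("chr1", pos, pos + w, float(rng.uniform(0, 5))))
            pos += w
        coverage = {"s": CoverageTrack.from_runs(runs)}
        consensus = [ConsensusSE("SE1", _iv(40, 1500), {}, ())]
        m = quantify_matrix(consensus, coverage, pd.DataFrame(index=["s"]))
        assert m.values.loc["SE1", "s"] == pytest.approx(
            coverage_area_per_bp(runs, "chr1", 40, 1500))

    def test_missing_sample_coverage_names_sample(self):
        consensus, coverage, _ = self._setup()
        samples = pd.DataFrame(index=["s1", "s2", "s3"])
        with pytest.raises(KeyError, match="s3"):
            quantify_matrix(consensus, coverage, samples)

    def test_equal_library_sizes_leave_matrix_unchanged(self):
        values = pd.DataFrame([[10.0, 20.0]], index=["SE1"], columns=["a", "b"])
        m = SignalMatrix(values, pd.Series([5.0, 5.0], index=["a", "b"]),
                         pd.DataFrame(index=["a", "b"]))
        out = normalize_library(m)
        assert np.allclose(out.values, values)

    def test_doubling_one_library_halves_its_column_scale(self):
        values = pd.DataFrame([[10.0, 10.0]], index=["SE1"], columns=["a", "b"])
        lib = pd.Series([1.0, 2.0], index=["a", "b"])
        out = normalize_library(
            SignalMatrix(values, lib, pd.DataFrame(index=["a", "b"])))
        # mean lib 1.5: a scaled by 1.5, b scaled by 0.75
        assert out.values.loc["SE1", "a"] == pytest.approx(15.0)
        assert out.values.loc["SE1", "b"] == pytest.approx(7.5)

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.uniform(0, 100, (6, 4)),
                              index=[f"SE{i}" for i in range(6)],
                              columns=list("abcd"))
        lib = pd.Series(rng.uniform(1, 10, 4), index=list("abcd"))
        base = normalize_library(
            SignalMatrix(values, lib, pd.DataFrame(index=list("abcd"))))
        scaled = normalize_library(
            SignalMatrix(values, lib * 137.0, pd.DataFrame(index=list("abcd"))))
        assert np.allclose(base.values, scaled.values, rtol=1e-12)

    def test_zero_library_size_rejected(self):
        values = pd.DataFrame([[1.0]], index=["SE1"], columns=["a"])
        m = SignalMatrix(values, pd.Series([0.0], index=["a"]),
                         pd.DataFrame(index=["a"]))
        with pytest.raises(ValueError):
            normalize_library(m)


class TestRowZscore:
    def test_closed_form_sample_sd(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"],
                              columns=list("abc"))
        out = row_zscore(values)
        assert np.allclose(out.loc["r"], [-1.0, 0.0, 1.0])  # sd(n-1) = 1

    def test_constant_row_becomes_zeros(self):
        values = pd.DataFrame([[4.0, 4.0, 4.0]], index=["r"],
                              columns=list("abc"))
        assert (row_zscore(values).loc["r"] == 0).all()

    def test_row_means_vanish_within_groups(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.uniform(0, 9, (5, 6)),
                              index=[f"r{i}" for i in range(5)],
                              columns=list("abcdef"))
        grouping = pd.Series(["L1"] * 3 + ["L2"] * 3, index=list("abcdef"))
        out = row_zscore(values, grouping)
        for group, cols in (("L1", list("abc")), ("L2", list("def"))):
            assert np.abs(out[cols].mean(axis=1)).max() < 1e-12
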