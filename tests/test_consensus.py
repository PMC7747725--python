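"""Consensus regions, breed-specificity, coverage and F_ROH."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohtrace.consensus import (
    ConsensusRegion,
    breed_specific_filter,
    consensus_regions,
    coverage_table,
    froh,
    mean_froh,
)
from rohtrace.model import GenomeSpec
from rohtrace.roh import ROHSegment


def seg(sample, start, end, chrom="1"):
    return ROHSegment(sample, chrom, start, end, n_snps=max(end - start, 1),
                      n_het=0, n_missing=0)


def per_base_support(segments, lo, hi, chrom="1"):
    """Oracle: count per-bp support over an explicit position array."""
    arr = np.zeros(hi - lo + 1, dtype=int)
    for s in segments:
        if s.chrom != chrom:
            continue
        a, b = max(s.start_bp, lo), min(s.end_bp, hi)
        if a <= b:
            arr[a - lo:b - lo + 1] += 1
    return arr


def regions_from_support(arr, lo, min_support):
    out = []
    in_run = False
    for i, v in enumerate(arr):
        if v >= min_support and not in_run:
            start, in_run = i, True
        elif v < min_support and in_run:
            out.append((lo + start, lo + i - 1))
            in_run = False
    if in_run:
        out.append((lo + start, lo + len(arr) - 1))
    return out


class TestConsensus:
    def test_identical_segments_full_support(self):
        segments = [seg("a", 100, 200), seg("b", 100, 200)]
        regions = consensus_regions(segments, ["a", "b"], "all")
        assert [(r.start_bp, r.end_bp, r.support) for r in regions] == \
            [(100, 200, 2)]

    def test_disjoint_segments_no_consensus(self):
        segments = [seg("a", 100, 200), seg("b", 300, 400)]
        assert consensus_regions(segments, ["a", "b"], 2) == []

    def test_member_without_segments_warns(self):
        segments = [seg("a", 100, 200)]
        with pytest.warns(UserWarning, match="no ROH"):
            regions = consensus_regions(segments, ["a", "b"], 1)
        assert len(regions) == 1

    def test_random_sets_match_per_base_oracle(self, rng):
        for _ in range(30):
            n_samples = int(rng.integers(2, 6))
            segments = []
            for i in range(n_samples):
                cursor = 1
                while cursor < 900:
                    start = cursor + int(rng.integers(0, 60))
                    end = start + int(rng.integers(0, 120))
                    if end > 1000:
                        break
                    segments.append(seg(f"s{i}", start, end))
                    cursor = end + 2
            min_support = int(rng.integers(1, n_samples + 1))
            got = consensus_regions(segments,
                                    [f"s{i}" for i in range(n_samples)],
                                    min_support)
            arr = per_base_support(segments, 1, 1000)
            expected = regions_from_support(arr, 1, min_support)
            assert [(r.start_bp, r.end_bp) for r in got] == expected
            # per-bp rescan: every region bp reaches min_support
            for r in got:
                assert arr[r.start_bp - 1:r.end_bp].min() >= min_support


class TestBreedSpecific:
    def test_no_overlap_region_flagged_specific(self):
        regions = [ConsensusRegion("1", 100, 200, 3)]
        out = breed_specific_filter(regions, [], 1, 10)
        assert out[0].breed_specific and (out[0].start_bp, out[0].end_bp) == \
            (100, 200)

    def test_full_overlap_single_excluded_member_removes(self):
        regions = [ConsensusRegion("1", 100, 200, 3)]
        out = breed_specific_filter(regions, [seg("x", 50, 300)], 1, 10)
        assert out == []

    def test_partial_overlap_fragments_match_oracle(self, rng):
        for _ in range(30):
            region = ConsensusRegion("1", 1, 1000, 5)
            excluded = []
            for i in range(int(rng.integers(1, 4))):
                a = int(rng.integers(1, 900))
                excluded.append(seg(f"x{i}", a, a + int(rng.integers(10, 200))))
            thr = int(rng.integers(1, 3))
            min_frag = int(rng.integers(1, 50))
            out = breed_specific_filter([region], excluded, thr, min_frag)
            arr = per_base_support(excluded, 1, 1000)
            expected = [iv for iv in regions_from_support(arr < thr, 1, 1)
                        if iv[1] - iv[0] + 1 >= min_frag]
            assert [(r.start_bp, r.end_bp) for r in out] == expected

    def test_drop_whole_region_mode(self):
        regions = [ConsensusRegion("1", 100, 200, 3),
                   ConsensusRegion("1", 400, 500, 3)]
        out = breed_specific_filter(regions, [seg("x", 150, 160)], 1, 10,
                                    drop_whole_region=True)
        assert [(r.start_bp, r.end_bp) for r in out] == [(400, 500)]

    def test_threshold_above_overlap_count_keeps_region(self):
        regions = [ConsensusRegion("1", 100, 200, 3)]
        out = breed_specific_filter(regions, [seg("x", 100, 200)], 5, 10)
        assert [(r.start_bp, r.end_bp) for r in out] == [(100, 200)]


class TestCoverage:
    def test_whole_chromosome_region_is_full_coverage(self):
        genome = GenomeSpec(chrom_lengths={"1": 1_000_000})
        rows = coverage_table([ConsensusRegion("1", 1, 1_000_000, 2)], genome)
        assert rows.loc[0, "coverage_pct"] == pytest.approx(100.0)

    def test_no_regions_all_zero(self):
        genome = GenomeSpec(chrom_lengths={"1": 10, "2": 20})
        rows = coverage_table([], genome)
        assert (rows["total_consensus_kb"] == 0).all()
        assert list(rows["chrom"]) == ["1", "2"]

    def test_arithmetic(self):
        genome = GenomeSpec(chrom_lengths={"1": 3_000_000})
        regions = [ConsensusRegion("1", 1, 10_000, 2),
                   ConsensusRegion("1", 100_001, 120_000, 2)]
        rows = coverage_table(regions, genome)
        assert rows.loc[0, "total_consensus_kb"] == pytest.approx(30.0)
        assert rows.loc[0, "coverage_pct"] == pytest.approx(1.0)

    def test_unknown_chromosome_errors(self):
        genome = GenomeSpec(chrom_lengths={"1": 100})
        with pytest.raises(ValueError, match="absent"):
            coverage_table([ConsensusRegion("7", 1, 10, 1)], genome)


class TestFroh:
    def test_no_segments_zero(self):
        genome = GenomeSpec(chrom_lengths={"1": 100})
        res = froh([], genome, ["a"])
        assert res[0].froh == 0.0

    def test_full_capture_is_one(self):
        genome = GenomeSpec(chrom_lengths={"1": 1000},
                            autosomal_captured_bp=1000)
        res = froh([seg("a", 1, 1000)], genome)
        assert res[0].froh == pytest.approx(1.0)

    def test_published_denominator_arithmetic(self):
        """453,079,016 bp of ROH over the captured autosome gives 0.2."""
        genome = GenomeSpec(chrom_lengths={"1": 2_265_395_079})
        res = froh([seg("a", 1, 453_079_016)], genome)
        assert res[0].froh == pytest.approx(453_079_016 / 2_265_395_079)
        assert res[0].froh == pytest.approx(0.2, abs=1e-9)

    def test_excluded_chromosomes_ignored(self):
        genome = GenomeSpec(chrom_lengths={"1": 1000, "X": 1000},
                            autosomal_captured_bp=1000)
        res = froh([seg("a", 1, 500), seg("a", 1, 800, chrom="X")], genome)
        assert res[0].sum_roh_bp == 500

    def test_overlapping_segments_error(self):
        genome = GenomeSpec(chrom_lengths={"1": 1000})
        with pytest.raises(ValueError, match="overlap"):
            froh([seg("a", 1, 500), seg("a", 400, 600)], genome)

    def test_additive_over_chromosomes_and_group_mean(self):
        genome = GenomeSpec(chrom_lengths={"1": 1000, "2": 1000},
                            autosomal_captured_bp=2000)
        segments = [seg("a", 1, 500), seg("a", 1, 300, chrom="2"),
                    seg("b", 1, 100)]
        res = froh(segments, genome, ["a", "b"])
        assert res[0].froh == pytest.approx(800 / 2000)
        table = mean_froh(res, {"a": "g1", "b": "g1"})
        assert table.loc[0, "mean_froh"] == pytest.approx((0.4 + 0.05) / 2)
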