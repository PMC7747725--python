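"""ROH detector: window flags, segment assembly, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from rohtrace.model import GenotypeMatrix, SampleRecord, VariantSite
from rohtrace.roh import (
    CHIP_PRESET,
    ROHParams,
    WGS_PRESET,
    brute_force_roh,
    call_roh,
    make_params,
    segments_from_flags,
    snp_hit_rates,
)

from conftest import make_matrix


def random_instance(rng, max_snps=200):
    """A random single-chromosome genotype vector plus random parameters."""
    n = int(rng.integers(1, max_snps + 1))
    p_het = rng.uniform(0, 0.6)
    p_mis = rng.uniform(0, 0.3)
    u = rng.random(n)
    genos = np.where(u < p_het, 1,
                     np.where(u < p_het + p_mis, -1,
                              rng.choice([0, 2], size=n))).astype(np.int8)
    spacing = rng.choice([50, 500, 5000, 60_000])
    gaps = np.maximum(1, rng.exponential(spacing, size=n)).astype(np.int64)
    positions = np.cumsum(gaps) + 1
    w = int(rng.integers(2, 26))
    params = ROHParams(
        window_snps=w,
        window_het=int(rng.integers(0, w)),
        window_missing=int(rng.integers(0, w + 1)),
        hit_rate_threshold=float(rng.uniform(0.01, 1.0)),
        min_snps=int(rng.integers(2, 31)),
        min_length_kb=float(rng.uniform(0.1, 50)),
        density_kb_per_snp=float(rng.uniform(0.05, 2000)),
        max_gap_kb=float(rng.uniform(1, 200)),
        strict_window=bool(rng.integers(0, 2)),
    )
    return genos, positions, params


def instance_matrix(genos, positions):
    sites = [VariantSite("1", int(p), "A", "G") for p in positions]
    samples = [SampleRecord("s0", "b", "case")]
    return GenotypeMatrix(sites, samples, genos.reshape(1, -1))


class TestHitRates:
    def test_all_homozygous_all_flagged(self):
        flags = snp_hit_rates(np.zeros(100, dtype=np.int8), WGS_PRESET)
        assert flags.all()

    def test_all_heterozygous_none_flagged(self):
        flags = snp_hit_rates(np.ones(100, dtype=np.int8), WGS_PRESET)
        assert not flags.any()

    def test_het_cluster_matches_window_enumeration(self):
        """Four adjacent hets exceed the 3-het window allowance; flags must
        equal explicit enumeration of all windows."""
        genos = np.zeros(50, dtype=np.int8)
        genos[[10, 11, 12, 13]] = 1
        params = make_params("wgs", hit_rate_threshold=0.05)
        w = params.window_snps
        window_ok = [
            ((genos[s:s + w] == 1).sum() <= params.window_het)
            for s in range(50 - w + 1)
        ]
        expected = []
        for i in range(50):
            cov = [window_ok[s] for s in range(50 - w + 1)
                   if s <= i <= s + w - 1]
            expected.append(sum(cov) / len(cov) >= params.hit_rate_threshold)
        got = snp_hit_rates(genos, params)
        assert got.tolist() == expected

    def test_short_chromosome_truncated_window(self):
        genos = np.zeros(5, dtype=np.int8)
        assert snp_hit_rates(genos, WGS_PRESET).all()
        strict = make_params("wgs", strict_window=True)
        assert not snp_hit_rates(genos, strict).any()

    def test_missing_allowance(self):
        genos = np.zeros(30, dtype=np.int8)
        genos[:6] = -1  # 6 missing > allowance of 5 in the first window
        rates = snp_hit_rates(genos, WGS_PRESET, return_rates=True)
        assert rates[-1] == 1.0
        assert rates[0] < 1.0


class TestSegments:
    def test_twenty_snps_spanning_min_length_one_segment(self):
        """Exactly the WGS boundary: 20 SNPs over 2.4 kb at 0.12 kb/SNP."""
        n = 20
        positions = np.arange(n) * 126 + 1000  # span = 19*126+1 = 2395 bp
        positions[-1] = positions[0] + 2400 - 1  # exactly 2.4 kb
        genos = np.zeros(n, dtype=np.int8)
        flags = np.ones(n, dtype=bool)
        segs = segments_from_flags(flags, positions, genos, WGS_PRESET,
                                   "s", "1")
        assert len(segs) == 1
        assert segs[0].length_kb == pytest.approx(2.4)
        assert segs[0].n_snps == 20

    def test_below_min_snps_no_segment(self):
        n = 19
        positions = np.arange(n) * 126 + 1
        segs = segments_from_flags(np.ones(n, bool), positions,
                                   np.zeros(n, np.int8), WGS_PRESET, "s", "1")
        assert segs == []

    def test_gap_splits_run(self):
        """A 100.001-kb internal spacing splits one flagged run in two."""
        params = make_params("wgs", min_snps=3, min_length_kb=0.1,
                             density_kb_per_snp=10_000)
        positions = np.array([1000, 2000, 3000, 103_001 + 3000, 104_001 + 3000,
                              105_001 + 3000])
        genos = np.zeros(6, dtype=np.int8)
        segs = segments_from_flags(np.ones(6, bool), positions, genos, params,
                                   "s", "1")
        assert len(segs) == 2
        assert segs[0].end_bp == 3000 and segs[1].start_bp == 106_001


class TestCallRoh:
    def test_fully_homozygous_sample_single_segment(self):
        m = make_matrix(np.zeros((1, 40)), positions=np.arange(40) * 100 + 1)
        segs = call_roh(m, WGS_PRESET)
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (1, 3901)

    def test_heterozygous_sample_yields_nothing(self):
        geno = np.vstack([np.zeros(40), np.ones(40)])
        m = make_matrix(geno, positions=np.arange(40) * 100 + 1)
        segs = call_roh(m, WGS_PRESET)
        assert {s.sample_id for s in segs} == {"s0"}

    def test_brute_force_refuses_large_input(self):
        m = make_matrix(np.zeros((1, 10_001)),
                        positions=np.arange(10_001) * 10 + 1)
        with pytest.raises(ValueError, match="10,000"):
            brute_force_roh(m, WGS_PRESET)

    def test_single_snp_no_segment(self):
        m = make_matrix(np.zeros((1, 1)))
        assert call_roh(m, WGS_PRESET) == brute_force_roh(m, WGS_PRESET) == []

    def test_empty_matrix(self):
        m = make_matrix(np.zeros((1, 0)))
        assert call_roh(m, WGS_PRESET) == []


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self, rng):
        """Vectorised caller and explicit enumeration agree exactly."""
        for _ in range(150):
            genos, positions, params = random_instance(rng)
            m = instance_matrix(genos, positions)
            assert call_roh(m, params) == brute_force_roh(m, params)

    def test_presets_match_brute_force_on_structured_data(self, rng):
        """Homozygous tracts embedded in noisy background, both presets."""
        for preset in (WGS_PRESET, CHIP_PRESET):
            for _ in range(20):
                n = 200
                spacing = 100 if preset is WGS_PRESET else 50_000
                positions = np.cumsum(
                    np.maximum(1, rng.exponential(spacing, n)).astype(int))
                genos = rng.choice([0, 1, 2], size=n,
                                   p=[0.3, 0.45, 0.25]).astype(np.int8)
                a, b = sorted(rng.integers(0, n, 2))
                genos[a:b] = 0
                m = instance_matrix(genos, positions)
                assert call_roh(m, preset) == brute_force_roh(m, preset)


class TestInvariants:
    def test_monotonicity_in_min_snps_and_length(self, rng):
        """Stricter thresholds only remove segments, never alter survivors."""
        for _ in range(40):
            genos, positions, params = random_instance(rng)
            m = instance_matrix(genos, positions)
            loose = call_roh(m, params)
            for stricter in (
                ROHParams(**{**params.__dict__,
                             "min_snps": params.min_snps + 5}),
                ROHParams(**{**params.__dict__,
                             "min_length_kb": params.min_length_kb * 2}),
            ):
                strict = call_roh(m, stricter)
                assert set(strict) <= set(loose)

    def test_segments_never_overlap_within_sample(self, rng):
        for _ in range(40):
            genos, positions, params = random_instance(rng)
            segs = call_roh(instance_matrix(genos, positions), params)
            segs.sort(key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                assert a.end_bp < b.start_bp

    def test_window_het_bound_inside_reported_segments(self, rng):
        """Rescan: within a segment, every full window of window_snps
        consecutive SNPs obeys the het allowance whenever the segment was
        built from fully-hit windows (threshold 1.0)."""
        for _ in range(40):
            genos, positions, params = random_instance(rng)
            params = ROHParams(**{**params.__dict__,
                                  "hit_rate_threshold": 1.0})
            m = instance_matrix(genos, positions)
            pos_list = positions.tolist()
            for seg in call_roh(m, params):
                i0 = pos_list.index(seg.start_bp)
                i1 = pos_list.index(seg.end_bp)
                inside = genos[i0:i1 + 1]
                w = params.window_snps
                for s in range(max(0, len(inside) - w + 1)):
                    assert (inside[s:s + w] == 1).sum() <= params.window_het
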