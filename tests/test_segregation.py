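"""Genotype-frequency tables, co-segregation, dominance, imputation error."""

from __future__ import annotations

import numpy as np
import pytest

from rohtrace.segregation import (
    dominance_consistency,
    genotype_frequencies,
    imputation_error,
    round_half_up,
    two_locus_table,
)

from conftest import make_matrix


def validation_matrix(straight_counts, curly_counts, n_straight=None,
                      n_curly=None):
    """One-site matrix realising the given (hom-ref, het, hom-alt) counts
    per phenotype cohort."""
    def expand(counts, n):
        genos = [0] * counts[0] + [1] * counts[1] + [2] * counts[2]
        genos += [-1] * (n - len(genos))
        return genos

    n_straight = n_straight or sum(straight_counts)
    n_curly = n_curly or sum(curly_counts)
    geno = np.array(expand(straight_counts, n_straight)
                    + expand(curly_counts, n_curly)).reshape(-1, 1)
    phen = ["straight"] * n_straight + ["curly"] * n_curly
    return make_matrix(geno, phenotypes=phen)


class TestGenotypeFrequencies:
    def test_published_cell_arithmetic(self):
        """968 hom-ref of 1275 straight -> 0.759; 24 hom-alt of 61 curly
        -> 0.393 (three-decimal display)."""
        m = validation_matrix((968, 244, 63), (7, 30, 24))
        table = genotype_frequencies(m, [("1", 1000)])
        cell = table.set_index(["cohort", "genotype"])
        assert cell.loc[("straight", "0/0"), "freq_display"] == 0.759
        assert cell.loc[("curly", "1/1"), "freq_display"] == 0.393
        assert cell.loc[("curly", "1/1"), "count"] == 24

    def test_all_missing_cohort(self):
        m = validation_matrix((0, 0, 0), (1, 0, 0), n_straight=5)
        total = genotype_frequencies(m, [("1", 1000)])
        s = total[(total.cohort == "straight")]
        assert (s["freq"] == 0).all()
        called = genotype_frequencies(m, [("1", 1000)],
                                      denominator_mode="called_only")
        s = called[(called.cohort == "straight")]
        assert s["freq"].isna().all()

    def test_unknown_site_errors(self):
        m = validation_matrix((1, 0, 0), (1, 0, 0))
        with pytest.raises(KeyError, match="9:123"):
            genotype_frequencies(m, [("9", 123)])

    def test_counts_recoverable_from_frequencies(self, rng):
        counts_s = tuple(int(x) for x in rng.integers(0, 400, 3))
        counts_c = tuple(int(x) for x in rng.integers(0, 40, 3))
        m = validation_matrix(counts_s, counts_c)
        table = genotype_frequencies(m, [("1", 1000)])
        for row in table.itertuples():
            assert abs(row.freq * row.cohort_size - row.count) < 0.5

    def test_round_half_up_convention(self):
        assert round_half_up(0.0005) == 0.001
        assert round_half_up(0.3935) == 0.394


class TestTwoLocus:
    def test_double_het_increments_expected_cell(self):
        geno = np.array([[1, 1]])
        m = make_matrix(geno, phenotypes=["curly"])
        table = two_locus_table(m, ("1", 1000), ("1", 2000))
        cell = table.set_index(["cohort", "genotype_a", "genotype_b"])
        assert cell.loc[("curly", "0/1", "0/1"), "count"] == 1

    def test_same_site_errors(self):
        m = make_matrix(np.zeros((1, 2)), phenotypes=["curly"])
        with pytest.raises(ValueError, match="differ"):
            two_locus_table(m, ("1", 1000), ("1", 1000))

    def test_marginals_match_single_locus_counts(self, rng):
        geno = rng.integers(-1, 3, size=(40, 2)).astype(np.int8)
        phen = list(rng.choice(["curly", "straight"], 40))
        m = make_matrix(geno, phenotypes=phen)
        table = two_locus_table(m, ("1", 1000), ("1", 2000))
        freq = genotype_frequencies(m, [("1", 1000)])
        for cohort in ("curly", "straight"):
            sub = table[table.cohort == cohort]
            mask = np.array(phen) == cohort
            missing_either = ((geno[mask, 0] == -1)
                              | (geno[mask, 1] == -1))
            for code, label in ((0, "0/0"), (1, "0/1"), (2, "1/1")):
                marginal = sub[sub.genotype_a == label]["count"].sum()
                naive = int(((geno[mask, 0] == code) & ~missing_either).sum())
                assert marginal == naive


class TestDominance:
    def test_curly_het_at_one_candidate_concordant(self):
        geno = np.array([[1, 0]])
        m = make_matrix(geno, phenotypes=["curly"])
        assert dominance_consistency(m, [("1", 1000), ("1", 2000)]) == []

    def test_straight_carrier_discordant(self):
        geno = np.array([[2]])
        m = make_matrix(geno, phenotypes=["straight"])
        out = dominance_consistency(m, [("1", 1000)])
        assert [d.sample_id for d in out] == ["s0"]

    def test_curly_noncarrier_discordant_and_unknown_skipped(self):
        geno = np.array([[0], [0]])
        m = make_matrix(geno, phenotypes=["curly", "unknown"])
        out = dominance_consistency(m, [("1", 1000)])
        assert [d.sample_id for d in out] == ["s0"]


class TestImputationError:
    def test_identical_matrices_zero(self):
        m = make_matrix(np.array([[0, 1], [2, 0]]))
        report = imputation_error(m, m)
        assert (report.per_snp["error_rate"] == 0).all()
        assert report.mean_error == 0.0

    def test_one_of_four_differs(self):
        a = make_matrix(np.array([[0], [0], [0], [0]]))
        b = make_matrix(np.array([[1], [0], [0], [0]]))
        report = imputation_error(a, b)
        assert report.per_snp.loc[0, "error_rate"] == pytest.approx(0.25)

    def test_missing_excluded_from_denominator(self):
        a = make_matrix(np.array([[0], [-1], [2]]))
        b = make_matrix(np.array([[1], [0], [2]]))
        report = imputation_error(a, b)
        assert report.per_snp.loc[0, "n_compared"] == 2
        assert report.per_snp.loc[0, "error_rate"] == pytest.approx(0.5)

    def test_symmetric(self, rng):
        a = make_matrix(rng.integers(-1, 3, size=(10, 5)).astype(np.int8))
        b = make_matrix(rng.integers(-1, 3, size=(10, 5)).astype(np.int8))
        r1 = imputation_error(a, b)
        r2 = imputation_error(b, a)
        assert r1.mean_error == pytest.approx(r2.mean_error)

    def test_empty_intersection_errors(self):
        a = make_matrix(np.zeros((1, 1)), chrom="1")
        b = make_matrix(np.zeros((1, 1)), chrom="2")
        with pytest.raises(ValueError, match="shared"):
            imputation_error(a, b)
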