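"""Validation statistics for candidate variants.

Covers the descriptive statistics used to validate candidates in larger
cohorts: genotype-frequency tables split by hair phenotype, two-locus
co-segregation cross-tabulation, an autosomal-dominant consistency
check, and the imputation error rate (discordance between imputed and
assay-validated genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GENO_HET, GENO_HOM_ALT, GENO_MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

GENOTYPE_LABELS = {0: "0/0", 1: "0/1", 2: "1/1"}


def round_half_up(x: float, digits: int = 3) -> float:
    """Display rounding in the half-up convention (0.0005 -> 0.001)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _phenotype_cohorts(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    phen = np.array([s.phenotype for s in matrix.samples])
    n_unknown = int((phen == "unknown").sum())
    if n_unknown:
        log.info("excluding %d samples with unknown phenotype from cohort "
                 "tables", n_unknown)
    return {p: phen == p for p in ("curly", "straight")}


def genotype_frequencies(
    matrix: GenotypeMatrix,
    sites: Sequence[tuple[str, int]],
    denominator_mode: str = "total_cohort",
) -> pd.DataFrame:
    """Genotype counts and frequencies per phenotype cohort per site.

    ``denominator_mode`` is ``total_cohort`` (counts over the full
    cohort size, the convention of published validation tables) or
    ``called_only``.  Frequencies are reported raw (``freq``) and
    display-rounded half-up to three decimals (``freq_display``); a
    cohort with nothing called yields 0 under ``total_cohort`` and NA
    under ``called_only``.
    """
    if denominator_mode not in ("total_cohort", "called_only"):
        raise ValueError("denominator_mode must be total_cohort or called_only")
    cohorts = _phenotype_cohorts(matrix)
    rows = []
    for chrom, pos in sites:
        j = matrix.site_index(chrom, pos)  # raises KeyError naming the site
        site = matrix.sites[j]
        for cohort, mask in cohorts.items():
            genos = matrix.geno[mask, j]
            n_total = int(mask.sum())
            n_missing = int((genos == GENO_MISSING).sum())
            n_called = n_total - n_missing
            for code in (0, 1, 2):
                count = int((genos == code).sum())
                if denominator_mode == "total_cohort":
                    freq = count / n_total if n_total else 0.0
                else:
                    freq = count / n_called if n_called else float("nan")
                rows.append((chrom, pos, site.ref, site.alt, cohort,
                             GENOTYPE_LABELS[code], count, n_total, n_missing,
                             freq,
                             round_half_up(freq) if freq == freq else
                             float("nan")))
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "cohort", "genotype", "count",
        "cohort_size", "n_missing", "freq", "freq_display",
    ])


def two_locus_table(
    matrix: GenotypeMatrix,
    site_a: tuple[str, int],
    site_b: tuple[str, int],
) -> pd.DataFrame:
    """3x3 cross-tabulation of combined genotypes at two loci, per
    phenotype cohort; individuals missing at either locus are counted
    separately in ``n_missing_either``."""
    if site_a == site_b:
        raise ValueError("the two loci must differ")
    ja = matrix.site_index(*site_a)
    jb = matrix.site_index(*site_b)
    cohorts = _phenotype_cohorts(matrix)
    rows = []
    for cohort, mask in cohorts.items():
        ga = matrix.geno[mask, ja]
        gb = matrix.geno[mask, jb]
        missing = (ga == GENO_MISSING) | (gb == GENO_MISSING)
        for ca in (0, 1, 2):
            for cb in (0, 1, 2):
                count = int(((ga == ca) & (gb == cb) & ~missing).sum())
                rows.append((cohort, GENOTYPE_LABELS[ca], GENOTYPE_LABELS[cb],
                             count, int(missing.sum())))
    return pd.DataFrame(rows, columns=[
        "cohort", "genotype_a", "genotype_b", "count", "n_missing_either",
    ])


@dataclass(frozen=True)
class Discordance:
    sample_id: str
    phenotype: str
    genotypes: tuple[int, ...]


def dominance_consistency(
    matrix: GenotypeMatrix, candidate_sites: Sequence[tuple[str, int]]
) -> list[Discordance]:
    """Samples inconsistent with a dominant model over the candidates.

    Under an autosomal-dominant model a curly-haired sample should carry
    at least one alternative allele at at least one candidate site, and
    a straight-haired sample none at any.  Missing genotypes carry no
    evidence; unknown phenotypes are skipped.
    """
    idx = [matrix.site_index(*s) for s in candidate_sites]
    discordant = []
    for i, rec in enumerate(matrix.samples):
        if rec.phenotype == "unknown":
            continue
        genos = tuple(int(matrix.geno[i, j]) for j in idx)
        carries = any(g in (GENO_HET, GENO_HOM_ALT) for g in genos)
        if rec.phenotype == "curly" and not carries:
            discordant.append(Discordance(rec.sample_id, rec.phenotype, genos))
        elif rec.phenotype == "straight" and carries:
            discordant.append(Discordance(rec.sample_id, rec.phenotype, genos))
    return discordant


@dataclass
class ErrorRateReport:
    """Imputation accuracy: per-SNP discordance and its mean."""

    per_snp: pd.DataFrame  # chrom, pos, n_compared, n_discordant, error_rate
    mean_error: float
    n_compared_total: int


def imputation_error(
    imputed: GenotypeMatrix, assay: GenotypeMatrix
) -> ErrorRateReport:
    """Genotype-level discordance between imputed and assay genotypes.

    The comparison runs on the intersection of samples and sites;
    genotypes missing in either matrix are excluded from the
    denominator.  The per-SNP error rate is discordant/compared, and the
    mean is taken over SNPs with at least one comparison.  The measure
    is symmetric in its inputs.
    """
    shared_samples = [s for s in imputed.sample_ids if s in set(assay.sample_ids)]
    site_keys_assay = {s.key for s in assay.sites}
    shared_sites = [s.key for s in imputed.sites if s.key in site_keys_assay]
    if not shared_samples or not shared_sites:
        raise ValueError("no shared samples/sites between the two matrices")
    rows = []
    total_cmp = 0
    total_disc = 0
    a_rows = [assay.sample_index(s) for s in shared_samples]
    i_rows = [imputed.sample_index(s) for s in shared_samples]
    for chrom, pos in shared_sites:
        ja = assay.site_index(chrom, pos)
        ji = imputed.site_index(chrom, pos)
        ga = assay.geno[a_rows, ja]
        gi = imputed.geno[i_rows, ji]
        ok = (ga != GENO_MISSING) & (gi != GENO_MISSING)
        n_cmp = int(ok.sum())
        n_disc = int((ga[ok] != gi[ok]).sum())
        rate = n_disc / n_cmp if n_cmp else float("nan")
        rows.append((chrom, pos, n_cmp, n_disc, rate))
        total_cmp += n_cmp
        total_disc += n_disc
    per_snp = pd.DataFrame(rows, columns=["chrom", "pos", "n_compared",
                                          "n_discordant", "error_rate"])
    with_data = per_snp[per_snp["n_compared"] > 0]
    mean_error = float(with_data["error_rate"].mean()) if len(with_data) else \
        float("nan")
    return ErrorRateReport(per_snp, mean_error, total_cmp)
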