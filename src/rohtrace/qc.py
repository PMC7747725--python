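"""Site and genotype quality control for sequence and SNP-array data.

Two filter families mirror the two data types the pipeline handles:

* depth QC for sequence genotypes — per-genotype read-depth bounds and
  per-site mean-depth / missing-count cutoffs;
* chip QC for array genotypes — per-site call rate, minor allele
  frequency, and removal of sex/unplaced chromosomes.

Both preserve site order and are idempotent.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import (
    GENO_MISSING,
    ChipQCParams,
    DepthQCParams,
    GenomeSpec,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)


def apply_depth_qc(matrix: GenotypeMatrix, params: DepthQCParams) -> GenotypeMatrix:
    """Mask genotypes with depth outside ``[min_dp, max_dp]``, then drop
    sites whose mean depth falls below ``min_mean_dp`` or whose missing
    count exceeds ``max_missing_count``.

    The mean depth is taken over all samples at the site.  Returns a new
    matrix; raises if the input carries no depth information.
    """
    if matrix.depth is None:
        raise ValueError(
            "matrix has no depth information; skip depth QC for this input"
        )
    out_of_range = (matrix.depth < params.min_dp) | (matrix.depth > params.max_dp)
    geno = np.where(out_of_range, GENO_MISSING, matrix.geno).astype(np.int8)

    mean_dp = matrix.depth.mean(axis=0)
    n_missing = (geno == GENO_MISSING).sum(axis=0)
    keep = (mean_dp >= params.min_mean_dp) & (n_missing <= params.max_missing_count)
    result = GenotypeMatrix(matrix.sites, matrix.samples, geno, matrix.depth)
    result = result.subset_sites(keep)
    log.info("depth QC: %d/%d sites retained", result.n_sites, matrix.n_sites)
    return result


def site_call_rate(matrix: GenotypeMatrix) -> np.ndarray:
    called = (matrix.geno != GENO_MISSING).sum(axis=0)
    return called / max(matrix.n_samples, 1)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site MAF over called genotypes; 0 where nothing is called."""
    called = matrix.geno != GENO_MISSING
    n_called = called.sum(axis=0)
    alt_copies = np.where(called, matrix.geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, alt_copies / (2 * n_called), 0.0)
    return np.minimum(alt_freq, 1.0 - alt_freq)


def apply_chip_qc(
    matrix: GenotypeMatrix, params: ChipQCParams, genome: GenomeSpec
) -> GenotypeMatrix:
    """Drop sites failing call rate or MAF, and sites on excluded
    (sex/mito/unplaced) chromosomes when ``drop_sex_chroms`` is set."""
    keep = site_call_rate(matrix) >= params.min_call_rate
    keep &= minor_allele_frequency(matrix) >= params.min_maf
    if params.drop_sex_chroms:
        excluded = genome.excluded_chroms
        on_excluded = np.array([s.chrom in excluded for s in matrix.sites])
        keep &= ~on_excluded
    result = matrix.subset_sites(keep)
    if result.n_sites == 0:
        log.warning("chip QC removed every site")
    log.info("chip QC: %d/%d sites retained", result.n_sites, matrix.n_sites)
    return result
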