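"""Shared fixtures and small matrix builders."""

from __future__ import annotations

import numpy as np
import pytest

from rohtrace.model import GenotypeMatrix, SampleRecord, VariantSite


def make_matrix(
    geno,
    positions=None,
    chrom: str = "1",
    groups=None,
    phenotypes=None,
    depth=None,
    impacts=None,
):
    """Build a one-chromosome GenotypeMatrix from a genotype array.

    ``geno`` is (n_samples, n_sites); positions default to 1000, 2000, ...
    """
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(n_sites)]
    if groups is None:
        groups = ["control"] * n_samples
    if phenotypes is None:
        phenotypes = ["unknown"] * n_samples
    if impacts is None:
        impacts = ["NONE"] * n_sites
    sites = [VariantSite(chrom, int(p), "A", "G", impact=i)
             for p, i in zip(positions, impacts)]
    samples = [SampleRecord(f"s{i}", "breed", g, ph)
               for i, (g, ph) in enumerate(zip(groups, phenotypes))]
    return GenotypeMatrix(sites, samples, geno, depth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
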