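"""Core data model: samples, variant sites, genotype matrices, genome spec.

Genotype codes follow the usual diploid biallelic convention:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.  All genomic
coordinates held in memory are 1-based and fully closed (the VCF
convention); conversion to 0-based half-open happens only in the BED
writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

GENO_HOM_REF = 0
GENO_HET = 1
GENO_HOM_ALT = 2
GENO_MISSING = -1

GROUPS = ("case", "crossbreed", "control")
PHENOTYPES = ("curly", "straight", "unknown")

#: SnpEff-style impact classes ordered by severity; NONE means unannotated.
IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0, "NONE": -1}
VAR_CLASSES = ("SNP", "INDEL", "SV")


@dataclass(frozen=True)
class SampleRecord:
    """One individual: breed label, analysis group, hair phenotype.

    ``group`` and ``phenotype`` are independent: a crossbreed may be
    curly or straight.
    """

    sample_id: str
    breed: str
    group: str
    phenotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"unknown phenotype {self.phenotype!r} for {self.sample_id}"
            )


@dataclass(frozen=True)
class VariantSite:
    """A biallelic site with an optional predicted-effect impact class."""

    chrom: str
    pos: int  # 1-based bp
    ref: str
    alt: str
    impact: str = "NONE"
    var_class: str = "SNP"
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.impact not in IMPACT_RANK:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenomeSpec:
    """Chromosome lengths plus the captured autosomal size used for F_ROH.

    ``autosomal_captured_bp`` is the denominator of the genomic inbreeding
    coefficient: the summed autosomal genome length captured by the SNP
    set.  The default is the Sscrofa11.1 value used for pig WGS panels.
    """

    chrom_lengths: dict[str, int] = field(default_factory=dict)
    autosomal_captured_bp: int = 2_265_395_079
    excluded_chroms: frozenset[str] = frozenset({"X", "Y", "Mt", "Un"})

    def __post_init__(self) -> None:
        if self.autosomal_captured_bp <= 0:
            raise ValueError("autosomal_captured_bp must be positive")
        self.excluded_chroms = frozenset(self.excluded_chroms)

    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in self.excluded_chroms]


@dataclass(frozen=True)
class DepthQCParams:
    """Per-genotype and per-site read-depth filters for sequence data."""

    min_dp: int = 3
    max_dp: int = 60
    min_mean_dp: float = 6.0
    max_missing_count: int = 30

    def __post_init__(self) -> None:
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp must not exceed max_dp")
        if min(self.min_dp, self.max_dp) < 0 or self.min_mean_dp < 0:
            raise ValueError("depth bounds must be non-negative")
        if self.max_missing_count < 0:
            raise ValueError("max_missing_count must be non-negative")


@dataclass(frozen=True)
class ChipQCParams:
    """SNP-array QC: per-site call rate, minor allele frequency, sex chroms."""

    min_call_rate: float = 0.99
    min_maf: float = 0.05
    drop_sex_chroms: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


class GenotypeMatrix:
    """Samples x ordered sites genotype matrix with optional depth.

    Sites are sorted by (chrom, pos) with strictly increasing positions
    within each chromosome; ``geno`` is an int8 array of shape
    (n_samples, n_sites); ``depth`` an optional int32 array of the same
    shape.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        samples: Sequence[SampleRecord],
        geno: np.ndarray,
        depth: np.ndarray | None = None,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.geno = np.asarray(geno, dtype=np.int8)
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int32)
        self._validate()

    def _validate(self) -> None:
        if self.geno.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.depth is not None and self.depth.shape != self.geno.shape:
            raise ValueError("depth shape does not match geno shape")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        last: tuple[str, int] | None = None
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        for site in self.sites:
            if site.chrom != prev_chrom:
                if site.chrom in seen_chroms:
                    raise ValueError(f"sites not grouped by chromosome: {site.chrom}")
                seen_chroms.add(site.chrom)
                prev_chrom = site.chrom
                last = None
            # equal positions are tolerated (multi-allelic splits); going
            # backwards is not
            if last is not None and site.pos < last[1]:
                raise ValueError(
                    f"positions decrease on {site.chrom}: "
                    f"{last[1]} -> {site.pos}"
                )
            last = (site.chrom, site.pos)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def site_index(self, chrom: str, pos: int) -> int:
        if not hasattr(self, "_site_key_index"):
            # first key wins for duplicated positions (multi-allelic splits)
            index: dict[tuple[str, int], int] = {}
            for i, s in enumerate(self.sites):
                index.setdefault((s.chrom, s.pos), i)
            self._site_key_index = index
        try:
            return self._site_key_index[(chrom, pos)]
        except KeyError:
            raise KeyError(f"site {chrom}:{pos} not in matrix") from None

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out

    def iter_chrom_blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield (chrom, column slice) per chromosome, in site order."""
        start = 0
        for i in range(1, self.n_sites + 1):
            if i == self.n_sites or self.sites[i].chrom != self.sites[start].chrom:
                yield self.sites[start].chrom, slice(start, i)
                start = i

    # -- subsetting ------------------------------------------------------
    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a matrix with the site columns selected by a boolean mask
        or integer index array; order is preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sites = [self.sites[i] for i in keep]
        depth = None if self.depth is None else self.depth[:, keep]
        return GenotypeMatrix(sites, self.samples, self.geno[:, keep], depth)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        samples = [self.samples[i] for i in idx]
        depth = None if self.depth is None else self.depth[idx, :]
        return GenotypeMatrix(self.sites, samples, self.geno[idx, :], depth)

    def group_members(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def with_geno(self, geno: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites, self.samples, geno, self.depth)

    def copy(self) -> "GenotypeMatrix":
        depth = None if self.depth is None else self.depth.copy()
        return GenotypeMatrix(
            list(self.sites), list(self.samples), self.geno.copy(), depth
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites, "
            f"depth={'yes' if self.depth is not None else 'no'})"
        )


def max_impact(impacts: Sequence[str]) -> str:
    """Aggregate transcript-level impact annotations to the most severe."""
    best = "NONE"
    for imp in impacts:
        if imp in IMPACT_RANK and IMPACT_RANK[imp] > IMPACT_RANK[best]:
            best = imp
    return best


__all__ = [
    "GENO_HOM_REF",
    "GENO_HET",
    "GENO_HOM_ALT",
    "GENO_MISSING",
    "IMPACT_RANK",
    "SampleRecord",
    "VariantSite",
    "GenomeSpec",
    "DepthQCParams",
    "ChipQCParams",
    "GenotypeMatrix",
    "max_impact",
    "replace",
]
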