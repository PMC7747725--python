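"""Synthetic genotype cohorts with planted autozygosity and private variants.

The generator emulates the genotypic structure of a selection-signature
study contrasting a highly inbred case breed with outbred controls and
F1 crossbreeds:

* controls draw Hardy–Weinberg genotypes from symmetric-Beta allele
  frequencies;
* case samples carry planted homozygous tracts (autozygosity) on an
  otherwise outbred background, a configured number of tracts being
  planted identically in every case sample (the consensus truth), of
  which a subset is additionally planted in the crossbreeds;
* F1 crossbreeds combine one case-derived and one control-derived
  allele per site, so they are heterozygous wherever the two pools are
  fixed for different alleles and carry no long homozygous tracts;
* breed-private coding variants with configurable impact classes are
  inserted (plus decoys that violate exclusivity), one of which can act
  as a dominant causal locus for the hair phenotype;
* genotyping missingness and imputation errors are injected last, with
  the pre-error matrix kept for accuracy evaluation.

Tracts are planted directly rather than simulated through a coalescent
process: the downstream analysis consumes genotypes, not genealogies.
Every output is a deterministic function of the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as rio
from .model import (
    GENO_HET,
    GENO_HOM_ALT,
    GENO_HOM_REF,
    GENO_MISSING,
    GenomeSpec,
    GenotypeMatrix,
    SampleRecord,
    VariantSite,
)

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    The default scale mirrors a WGS-style study design shrunk to desk
    size: two 20-Mb chromosomes, 9 case animals, 3 F1 crossbreeds and 22
    controls, with a mean inter-SNP spacing of 100 bp (the density of a
    multi-million-SNP WGS panel).  ``chip_like`` gives the array-style
    counterpart (sparser SNPs, larger cohort of crossbreeds).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 20_000_000
    snp_spacing_mode: str = "exponential"  # or "uniform"
    mean_spacing_bp: int = 100
    n_case: int = 9
    n_cross: int = 3
    n_control: int = 22
    n_planted_tracts: int = 4          # private tracts per case sample
    n_consensus_tracts: int = 6        # tracts planted in every case sample
    n_cross_shared_tracts: int = 2     # consensus tracts also in crossbreeds
    tract_length_bounds: tuple[int, int] = (500_000, 2_000_000)  # log-uniform
    min_tract_gap_bp: int = 50_000
    background_het_rate: float = 0.45
    within_tract_het_leak: float = 0.0
    n_private_variants: int = 20
    n_decoy_variants: int = 10
    private_impact_mix: dict = field(default_factory=lambda: {
        "HIGH": 0.3, "MODERATE": 0.4, "LOW": 0.2, "MODIFIER": 0.1})
    min_private_case_carriers: int = 3
    causal_site: bool = True
    genotyping_missing_rate: float = 0.0
    imputation_error_rate: float = 0.0
    mean_depth: float = 20.0
    allele_freq_beta: float = 5.0

    def __post_init__(self) -> None:
        for name in ("background_het_rate", "within_tract_het_leak",
                     "genotyping_missing_rate", "imputation_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_case, self.n_cross, self.n_control) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.n_cross_shared_tracts > self.n_consensus_tracts:
            raise ValueError("n_cross_shared_tracts exceeds n_consensus_tracts")
        if self.tract_length_bounds[0] > self.tract_length_bounds[1]:
            raise ValueError("tract_length_bounds out of order")
        if self.tract_length_bounds[1] > self.chrom_length_bp:
            raise ValueError("tract longer than chromosome")

    @classmethod
    def chip_like(cls, **overrides) -> "SimConfig":
        """Array-style defaults: sparse SNPs, 19/15/17 cohort split."""
        base = dict(mean_spacing_bp=50_000, snp_spacing_mode="uniform",
                    n_case=19, n_cross=15,
                    n_control=17, tract_length_bounds=(1_000_000, 3_000_000),
                    n_planted_tracts=1, n_consensus_tracts=4,
                    n_cross_shared_tracts=1, min_tract_gap_bp=1_000_000)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int
    impact: str
    case_carriers: tuple[str, ...]
    cross_carriers: tuple[str, ...]
    control_carriers: tuple[str, ...]
    causal: bool = False
    decoy: bool = False


@dataclass
class TruthSet:
    """Ground truth emitted next to the genotypes.

    ``consensus_tracts`` are (chrom, start, end, cross_shared) planted in
    every case sample; ``sample_tracts`` maps each case sample to all of
    its planted tract intervals (consensus + private);
    ``private_variants`` lists the planted exclusivity-funnel variants
    (decoys flagged); ``causal`` names the dominant phenotype locus.
    """

    consensus_tracts: list[tuple[str, int, int, bool]]
    sample_tracts: dict[str, list[tuple[str, int, int]]]
    private_variants: list[PlantedVariant]
    causal: tuple[str, int] | None
    phenotypes: dict[str, str]

    def expected_funnel_survivors(
        self, impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    ) -> set[tuple[str, int]]:
        return {(v.chrom, v.pos) for v in self.private_variants
                if not v.decoy and v.impact in impacts}

    def planted_fraction(self, sample_id: str, genome: GenomeSpec) -> float:
        """Union of planted tract bp over the captured autosome size."""
        ivals = sorted(self.sample_tracts.get(sample_id, []))
        total = 0
        cur: list | None = None
        for chrom, s, e in ivals:
            if cur is not None and chrom == cur[0] and s <= cur[2] + 1:
                cur[2] = max(cur[2], e)
            else:
                if cur is not None:
                    total += cur[2] - cur[1] + 1
                cur = [chrom, s, e]
        if cur is not None:
            total += cur[2] - cur[1] + 1
        return total / genome.autosomal_captured_bp

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rio.write_intervals_bed(
            [(c, s, e, "shared" if x else "case_only")
             for c, s, e, x in self.consensus_tracts],
            outdir / "truth_consensus_tracts.bed", name_field="name",
        )
        rows = [(sid, c, s, e) for sid, ivals in self.sample_tracts.items()
                for c, s, e in ivals]
        with open(outdir / "truth_sample_tracts.tsv", "w") as fh:
            fh.write("sample_id\tchrom\tstart\tend\n")
            for sid, c, s, e in rows:
                fh.write(f"{sid}\t{c}\t{s}\t{e}\n")
        with open(outdir / "truth_private_variants.tsv", "w") as fh:
            fh.write("chrom\tpos\timpact\tcausal\tdecoy\tcase_carriers\t"
                     "cross_carriers\tcontrol_carriers\n")
            for v in self.private_variants:
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.impact}\t{int(v.causal)}\t"
                    f"{int(v.decoy)}\t{','.join(v.case_carriers)}\t"
                    f"{','.join(v.cross_carriers)}\t"
                    f"{','.join(v.control_carriers)}\n"
                )
        with open(outdir / "truth_meta.json", "w") as fh:
            json.dump({"causal": list(self.causal) if self.causal else None,
                       "phenotypes": self.phenotypes}, fh, indent=1,
                      sort_keys=True)


@dataclass
class SimResult:
    """Generator output: clean/observed/imputed matrices plus truth."""

    matrix: GenotypeMatrix          # pre-error, pre-missingness
    observed: GenotypeMatrix        # with missingness injected
    imputed: GenotypeMatrix         # with imputation errors injected
    truth: TruthSet
    genome: GenomeSpec
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        """Emit VCF, PLINK text MAP/PED, metadata and truth files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rio.write_vcf(self.observed, outdir / "cohort.vcf")
        rio.write_plink_text(self.observed, outdir / "cohort.map",
                             outdir / "cohort.ped")
        rio.write_metadata(self.observed.samples, outdir / "metadata.tsv")
        rio.write_genome_spec(self.genome, outdir / "genome.tsv")
        self.truth.write(outdir)


def _place_tracts(
    rng: np.random.Generator,
    lengths: list[int],
    chrom_names: list[str],
    chrom_length: int,
    min_gap: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> list[tuple[str, int, int]]:
    """Place tracts of the given lengths without overlap (stick-breaking
    of the free space per chromosome); raises when they cannot fit."""
    occupied = occupied or {}
    # free space per chromosome, excluding already-occupied blocks
    free: dict[str, list[tuple[int, int]]] = {}
    for c in chrom_names:
        segments = []
        cursor = 1
        for s, e in sorted(occupied.get(c, [])):
            if s - cursor >= 1:
                segments.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= chrom_length:
            segments.append((cursor, chrom_length))
        free[c] = segments

    out: list[tuple[str, int, int]] = []
    # largest first so fragmentation cannot strand a big tract
    for L in sorted(lengths, reverse=True):
        placed = False
        for c in rng.permutation(chrom_names):
            for i, (fs, fe) in enumerate(free[c]):
                avail = fe - fs + 1 - 2 * min_gap
                if avail < L:
                    continue
                offset = int(rng.integers(0, avail - L + 1))
                start = fs + min_gap + offset
                end = start + L - 1
                out.append((c, start, end))
                pieces = [(fs, start - 1), (end + 1, fe)]
                free[c][i:i + 1] = [p for p in pieces if p[1] >= p[0]]
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ValueError(
                f"cannot place tract of {L} bp: chromosomes too full"
            )
    return sorted(out)


def simulate(config: SimConfig) -> SimResult:
    """Generate a cohort according to ``config`` (deterministic in the
    seed); see the module docstring for the construction."""
    rng = np.random.default_rng(config.seed)
    chrom_names = [str(i + 1) for i in range(config.n_chroms)]
    genome = GenomeSpec(
        chrom_lengths={c: config.chrom_length_bp for c in chrom_names},
        autosomal_captured_bp=config.n_chroms * config.chrom_length_bp,
    )

    # --- sample sheet ----------------------------------------------------
    samples: list[SampleRecord] = []
    case_ids = [f"case{i + 1:02d}" for i in range(config.n_case)]
    cross_ids = [f"cross{i + 1:02d}" for i in range(config.n_cross)]
    control_ids = [f"ctrl{i + 1:02d}" for i in range(config.n_control)]

    # --- SNP grid --------------------------------------------------------
    positions: dict[str, np.ndarray] = {}
    for c in chrom_names:
        n_expect = int(config.chrom_length_bp / config.mean_spacing_bp * 1.2)
        if config.snp_spacing_mode == "exponential":
            gaps = rng.exponential(config.mean_spacing_bp, size=n_expect)
        elif config.snp_spacing_mode == "uniform":
            gaps = rng.uniform(0.5 * config.mean_spacing_bp,
                               1.5 * config.mean_spacing_bp, size=n_expect)
        else:
            raise ValueError(f"unknown spacing mode {config.snp_spacing_mode!r}")
        gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
        pos = np.cumsum(gaps) + int(rng.integers(1, config.mean_spacing_bp + 1))
        pos = pos[pos <= config.chrom_length_bp]
        positions[c] = np.unique(pos)

    # --- allele frequencies & base genotypes -----------------------------
    n_samples = config.n_case + config.n_cross + config.n_control
    geno_blocks: list[np.ndarray] = []
    site_blocks: list[list[VariantSite]] = []
    founder_allele: dict[str, np.ndarray] = {}  # per chrom per site
    tract_masks: dict[str, dict[str, np.ndarray]] = {}

    # tract placement: consensus tracts first, then per-sample private
    k_cons = config.n_consensus_tracts
    cons_lengths = _tract_lengths(rng, k_cons, config.tract_length_bounds)
    consensus = _place_tracts(rng, cons_lengths, chrom_names,
                              config.chrom_length_bp, config.min_tract_gap_bp)
    cross_shared_flags = ([True] * config.n_cross_shared_tracts
                          + [False] * (k_cons - config.n_cross_shared_tracts))
    occupied = {}
    for c, s, e in consensus:
        occupied.setdefault(c, []).append((s, e))

    sample_tracts: dict[str, list[tuple[str, int, int]]] = {}
    for sid in case_ids:
        priv_lengths = _tract_lengths(rng, config.n_planted_tracts,
                                      config.tract_length_bounds)
        private = _place_tracts(rng, priv_lengths, chrom_names,
                                config.chrom_length_bp,
                                config.min_tract_gap_bp, occupied=occupied)
        sample_tracts[sid] = sorted(consensus) + private

    base_seed = rng.integers(0, 2**31 - 1)
    grng = np.random.default_rng(base_seed)
    for c in chrom_names:
        pos = positions[c]
        m = pos.size
        q = grng.beta(config.allele_freq_beta, config.allele_freq_beta, size=m)
        founder = (grng.random(m) < q).astype(np.int8)  # tract haplotype
        founder_allele[c] = founder

        block = np.empty((n_samples, m), dtype=np.int8)
        row = 0
        # cases: outbred-style background, tracts overwritten below
        for sid in case_ids:
            het = grng.random(m) < config.background_het_rate
            hom_alt = grng.random(m) < q
            g = np.where(het, GENO_HET,
                         np.where(hom_alt, GENO_HOM_ALT, GENO_HOM_REF))
            block[row] = g
            row += 1
        # crossbreeds: one case-derived + one control-derived allele
        for sid in cross_ids:
            case_allele = np.where(
                _in_any_tract(pos, consensus, c), founder,
                (grng.random(m) < q).astype(np.int8))
            control_allele = (grng.random(m) < q).astype(np.int8)
            block[row] = (case_allele + control_allele).astype(np.int8)
            row += 1
        # controls: Hardy-Weinberg
        for sid in control_ids:
            block[row] = (
                (grng.random(m) < q).astype(np.int8)
                + (grng.random(m) < q).astype(np.int8)
            )
            row += 1

        # overwrite planted tracts for cases (hom founder, optional leak)
        for i, sid in enumerate(case_ids):
            mask = _in_any_tract(pos, sample_tracts[sid], c)
            hom = (2 * founder).astype(np.int8)
            block[i] = np.where(mask, hom, block[i])
            if config.within_tract_het_leak > 0:
                leak = mask & (grng.random(m) < config.within_tract_het_leak)
                block[i] = np.where(leak, GENO_HET, block[i])
        # cross-shared tracts: crossbreeds also homozygous for the founder
        shared = [t for t, flag in zip(consensus, cross_shared_flags) if flag]
        if shared:
            mask = _in_any_tract(pos, shared, c)
            hom = (2 * founder).astype(np.int8)
            for i in range(config.n_case, config.n_case + config.n_cross):
                block[i] = np.where(mask, hom, block[i])

        geno_blocks.append(block)
        site_blocks.append([
            VariantSite(c, int(p), "A", "G") for p in pos
        ])

    # --- private variants and decoys ------------------------------------
    vrng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    private_variants: list[PlantedVariant] = []
    causal_key: tuple[str, int] | None = None
    impact_names = list(IMPACTS)
    impact_probs = np.array([config.private_impact_mix.get(i, 0.0)
                             for i in impact_names], dtype=float)
    if impact_probs.sum() <= 0:
        raise ValueError("private_impact_mix must have positive mass")
    impact_probs = impact_probs / impact_probs.sum()

    def _free_position(chrom: str) -> int:
        taken = set(int(p) for p in positions[chrom])
        taken |= {v.pos for v in private_variants if v.chrom == chrom}
        while True:
            p = int(vrng.integers(1, config.chrom_length_bp + 1))
            if p not in taken:
                return p

    n_priv = config.n_private_variants
    if config.causal_site and n_priv == 0:
        raise ValueError("causal_site requires n_private_variants >= 1")
    for v_idx in range(n_priv + config.n_decoy_variants):
        decoy = v_idx >= n_priv
        chrom = chrom_names[int(vrng.integers(0, len(chrom_names)))]
        pos = _free_position(chrom)
        causal = config.causal_site and v_idx == 0
        if causal:
            impact = "HIGH" if config.private_impact_mix.get("HIGH", 0) > 0 \
                else "MODERATE"
        else:
            impact = impact_names[int(vrng.choice(len(impact_names),
                                                  p=impact_probs))]
        if decoy:
            impact = "HIGH" if vrng.random() < 0.5 else "MODERATE"
        # carriers
        if causal:
            case_c = tuple(case_ids)
            cross_c = tuple(cross_ids)
        else:
            lo = min(config.min_private_case_carriers, config.n_case)
            k_case = int(vrng.integers(lo, config.n_case + 1)) \
                if config.n_case else 0
            case_c = tuple(sorted(vrng.choice(case_ids, size=k_case,
                                              replace=False))) \
                if k_case else ()
            k_cross = int(vrng.integers(1, config.n_cross + 1)) \
                if config.n_cross else 0
            cross_c = tuple(sorted(vrng.choice(cross_ids, size=k_cross,
                                               replace=False))) \
                if k_cross else ()
        if decoy:
            k_ctrl = int(vrng.integers(1, max(2, config.n_control // 4)))
            control_c = tuple(sorted(vrng.choice(control_ids, size=k_ctrl,
                                                 replace=False)))
        else:
            control_c = ()
        if not decoy and config.n_case and len(case_c) < \
                config.min_private_case_carriers:
            raise ValueError("infeasible private-variant carrier counts")
        private_variants.append(PlantedVariant(
            chrom, pos, impact, case_c, cross_c, control_c,
            causal=causal, decoy=decoy))
        if causal:
            causal_key = (chrom, pos)

    # --- assemble matrix (grid + planted variant sites) ------------------
    all_ids = case_ids + cross_ids + control_ids
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    planted_by_chrom: dict[str, list[PlantedVariant]] = {}
    for v in private_variants:
        planted_by_chrom.setdefault(v.chrom, []).append(v)

    for c, grid_sites, block in zip(chrom_names, site_blocks, geno_blocks):
        merged: list[tuple[int, VariantSite, np.ndarray | None, int]] = [
            (s.pos, s, None, j) for j, s in enumerate(grid_sites)
        ]
        for v in sorted(planted_by_chrom.get(c, []), key=lambda v: v.pos):
            col = np.zeros(n_samples, dtype=np.int8)
            for sid in v.case_carriers:
                g = GENO_HOM_ALT if (v.causal or vrng.random() < 0.5) \
                    else GENO_HET
                col[all_ids.index(sid)] = g
            for sid in v.cross_carriers:
                col[all_ids.index(sid)] = GENO_HET
            for sid in v.control_carriers:
                col[all_ids.index(sid)] = GENO_HET
            site = VariantSite(c, v.pos, "C", "T", impact=v.impact,
                               var_class="SNP")
            merged.append((v.pos, site, col, -1))
        merged.sort(key=lambda t: (t[0], t[3]))
        for pos_, site, col, j in merged:
            sites.append(site)
            columns.append(block[:, j] if col is None else col)

    geno = np.stack(columns, axis=1) if columns else \
        np.zeros((n_samples, 0), dtype=np.int8)

    # --- phenotypes ------------------------------------------------------
    phenotypes: dict[str, str] = {}
    if config.causal_site and causal_key is not None:
        key_idx = next(i for i, s in enumerate(sites)
                       if (s.chrom, s.pos) == causal_key)
        for i, sid in enumerate(all_ids):
            carrier = geno[i, key_idx] in (GENO_HET, GENO_HOM_ALT)
            phenotypes[sid] = "curly" if carrier else "straight"
    else:
        for sid in case_ids + cross_ids:
            phenotypes[sid] = "curly"
        for sid in control_ids:
            phenotypes[sid] = "straight"

    for sid in case_ids:
        samples.append(SampleRecord(sid, "case_breed", "case",
                                    phenotypes[sid]))
    for sid in cross_ids:
        samples.append(SampleRecord(sid, "f1_cross", "crossbreed",
                                    phenotypes[sid]))
    for sid in control_ids:
        samples.append(SampleRecord(sid, "control_breed", "control",
                                    phenotypes[sid]))

    # --- depth, missingness, imputation error ----------------------------
    drng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    depth = drng.poisson(config.mean_depth, size=geno.shape).astype(np.int32)
    matrix = GenotypeMatrix(sites, samples, geno, depth)

    observed_geno = geno.copy()
    if config.genotyping_missing_rate > 0:
        mask = drng.random(geno.shape) < config.genotyping_missing_rate
        observed_geno = np.where(mask, GENO_MISSING, observed_geno)
    observed = GenotypeMatrix(sites, samples, observed_geno.astype(np.int8),
                              depth)

    imputed = inject_imputation_errors(
        matrix, config.imputation_error_rate,
        int(rng.integers(0, 2**31 - 1)))

    truth = TruthSet(
        consensus_tracts=[(c, s, e, flag) for (c, s, e), flag in
                          zip(consensus, cross_shared_flags)],
        sample_tracts=sample_tracts,
        private_variants=private_variants,
        causal=causal_key,
        phenotypes=phenotypes,
    )
    return SimResult(matrix, observed, imputed, truth, genome, config)


def _tract_lengths(rng, k, bounds) -> list[int]:
    lo, hi = bounds
    if k == 0:
        return []
    if lo == hi:
        return [int(lo)] * k
    return [int(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for _ in range(k)]


def _in_any_tract(pos: np.ndarray, tracts, chrom: str) -> np.ndarray:
    mask = np.zeros(pos.size, dtype=bool)
    for c, s, e in tracts:
        if c == chrom:
            mask |= (pos >= s) & (pos <= e)
    return mask


def inject_imputation_errors(
    matrix: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Replace each called genotype with one of the two other codes with
    probability ``rate`` (missing calls stay missing)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"error rate must be in [0, 1], got {rate}")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    geno = matrix.geno.copy()
    called = geno != GENO_MISSING
    flip = called & (rng.random(geno.shape) < rate)
    # new code: add 1 or 2 mod 3 -> always a different called code
    shift = rng.integers(1, 3, size=geno.shape)
    geno = np.where(flip, (geno + shift) % 3, geno).astype(np.int8)
    return matrix.with_geno(geno)
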