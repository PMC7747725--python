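"""Breed-private candidate-variant funnel.

A *carrier* holds one or two copies of the alternative allele (het or
hom-alt).  The funnel keeps variants carried by at least
``min_case_carriers`` case-breed animals and at least
``min_cross_carriers`` crossbreeds while being absent (at most
``max_control_carriers`` carriers) from the straight-haired controls,
then restricts to predicted HIGH/MODERATE-impact variants.  The same
presence/absence logic applies to interval-typed records (structural
variants), optionally restricted to windows around anchor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GENO_HET, GENO_HOM_ALT, GENO_MISSING, GenotypeMatrix, VariantSite


@dataclass(frozen=True)
class FunnelCriteria:
    """Presence/absence and impact thresholds of the candidate funnel.

    Defaults mirror the discovery screen: mutant alleles in >= 3 case
    animals and >= 1 crossbreed, none in controls, HIGH or MODERATE
    predicted effect.  Missing genotypes never count as carriers; with
    ``missing_disqualifies_controls`` a control missing call disqualifies
    the site instead of being ignored.
    """

    min_case_carriers: int = 3
    min_cross_carriers: int = 1
    max_control_carriers: int = 0
    impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    missing_disqualifies_controls: bool = False

    def __post_init__(self) -> None:
        if min(self.min_case_carriers, self.min_cross_carriers,
               self.max_control_carriers) < 0:
            raise ValueError("carrier thresholds must be >= 0")
        object.__setattr__(self, "impacts", frozenset(self.impacts))


@dataclass(frozen=True)
class CarrierCounts:
    """Per-site carrier/non-carrier/missing counts per analysis group."""

    site: VariantSite
    n_case_carriers: int
    n_cross_carriers: int
    n_control_carriers: int
    n_case_missing: int
    n_cross_missing: int
    n_control_missing: int


@dataclass
class FunnelReport:
    """Stage-by-stage survivor counts of the funnel."""

    n_input: int
    n_presence: int
    n_impact: int
    stages: list[tuple[str, int]] = field(default_factory=list)


def _group_masks(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    groups = np.array([s.group for s in matrix.samples])
    return {g: groups == g for g in ("case", "crossbreed", "control")}


def carrier_counts(matrix: GenotypeMatrix) -> list[CarrierCounts]:
    """Count carriers (het or hom-alt) and missing calls per site per
    group; group labels come from the matrix's sample metadata."""
    masks = _group_masks(matrix)
    carrier = (matrix.geno == GENO_HET) | (matrix.geno == GENO_HOM_ALT)
    missing = matrix.geno == GENO_MISSING
    out = []
    for j, site in enumerate(matrix.sites):
        out.append(CarrierCounts(
            site,
            int(carrier[masks["case"], j].sum()),
            int(carrier[masks["crossbreed"], j].sum()),
            int(carrier[masks["control"], j].sum()),
            int(missing[masks["case"], j].sum()),
            int(missing[masks["crossbreed"], j].sum()),
            int(missing[masks["control"], j].sum()),
        ))
    return out


def presence_mask(
    matrix: GenotypeMatrix, criteria: FunnelCriteria
) -> np.ndarray:
    """Boolean site mask for the presence/absence (exclusivity) screen."""
    masks = _group_masks(matrix)
    for group, needed in (("case", criteria.min_case_carriers),
                          ("crossbreed", criteria.min_cross_carriers)):
        if needed > 0 and not masks[group].any():
            raise ValueError(
                f"criteria require {group} carriers but metadata has no "
                f"{group} samples"
            )
    carrier = (matrix.geno == GENO_HET) | (matrix.geno == GENO_HOM_ALT)
    keep = carrier[masks["case"]].sum(axis=0) >= criteria.min_case_carriers
    keep &= (carrier[masks["crossbreed"]].sum(axis=0)
             >= criteria.min_cross_carriers)
    keep &= (carrier[masks["control"]].sum(axis=0)
             <= criteria.max_control_carriers)
    if criteria.missing_disqualifies_controls:
        control_missing = (matrix.geno[masks["control"]] == GENO_MISSING)
        keep &= control_missing.sum(axis=0) == 0
    return keep


def candidate_filter(
    matrix: GenotypeMatrix, criteria: FunnelCriteria = FunnelCriteria()
) -> tuple[list[VariantSite], FunnelReport]:
    """Run the two-stage funnel: presence/absence first, then impact.

    Returns the surviving sites (matrix order) and a report with the
    survivor count after each stage.  The two filters commute; the
    staging only fixes how the report reads.
    """
    keep_presence = presence_mask(matrix, criteria)
    impact_ok = np.array([s.impact in criteria.impacts for s in matrix.sites])
    keep = keep_presence & impact_ok
    report = FunnelReport(
        n_input=matrix.n_sites,
        n_presence=int(keep_presence.sum()),
        n_impact=int(keep.sum()),
        stages=[
            ("input", matrix.n_sites),
            ("presence/absence", int(keep_presence.sum())),
            ("impact " + "/".join(sorted(criteria.impacts)), int(keep.sum())),
        ],
    )
    survivors = [s for s, k in zip(matrix.sites, keep) if k]
    return survivors, report


@dataclass(frozen=True)
class IntervalVariant:
    """An interval-typed variant record (e.g. a structural variant) with
    per-sample genotype codes keyed by sample id."""

    chrom: str
    start_bp: int
    end_bp: int
    genotypes: tuple[tuple[str, int], ...]  # (sample_id, code) pairs
    var_id: str = ""

    def genotype_of(self, sample_id: str) -> int:
        for sid, g in self.genotypes:
            if sid == sample_id:
                return g
        return GENO_MISSING


def two_group_presence_screen(
    records: Sequence[IntervalVariant],
    metadata: Sequence,
    criteria: FunnelCriteria = FunnelCriteria(),
    anchors: Sequence[tuple[str, int]] | None = None,
    window_bp: int = 40_000_000,
) -> list[IntervalVariant]:
    """Presence/absence screen over interval-typed records.

    The impact filter is skipped (structural records carry no SnpEff
    class here).  With ``anchors``, records are first restricted to
    those overlapping a window of +/- ``window_bp`` around any anchor
    position (e.g. candidate SNPs).
    """
    group_of = {s.sample_id: s.group for s in metadata}
    survivors = []
    for rec in records:
        if anchors is not None:
            inside = any(
                rec.chrom == chrom
                and rec.start_bp <= pos + window_bp
                and rec.end_bp >= pos - window_bp
                for chrom, pos in anchors
            )
            if not inside:
                continue
        counts = {"case": 0, "crossbreed": 0, "control": 0}
        for sid, g in rec.genotypes:
            if g in (GENO_HET, GENO_HOM_ALT):
                grp = group_of.get(sid)
                if grp in counts:
                    counts[grp] += 1
        if (counts["case"] >= criteria.min_case_carriers
                and counts["crossbreed"] >= criteria.min_cross_carriers
                and counts["control"] <= criteria.max_control_carriers):
            survivors.append(rec)
    return survivors


def counts_to_frame(counts: Sequence[CarrierCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.site.chrom, c.site.pos, c.site.impact,
          c.n_case_carriers, c.n_cross_carriers, c.n_control_carriers,
          c.n_case_missing, c.n_cross_missing, c.n_control_missing)
         for c in counts],
        columns=["chrom", "pos", "impact", "case_carriers", "cross_carriers",
                 "control_carriers", "case_missing", "cross_missing",
                 "control_missing"],
    )
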