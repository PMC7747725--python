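"""Group-level consensus ROH regions (ROH islands), breed-specificity
filtering, per-chromosome coverage and the genomic inbreeding
coefficient F_ROH.

Consensus is computed at base-pair resolution with an endpoint sweep
over segment boundaries: a consensus region is a maximal interval in
which at least ``min_support`` group members each have a ROH covering
every base.  Breed-specific regions are obtained by subtracting, at
base-pair resolution, every position covered by ROH in at least
``max_support_excluded`` members of an excluded comparison group
(e.g. crossbreeds of the case breed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GenomeSpec
from .roh import ROHSegment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusRegion:
    """A genomic interval shared (covered by ROH) by ``support`` members
    of a group; ``breed_specific`` marks survival of the exclusion
    filter."""

    chrom: str
    start_bp: int
    end_bp: int
    support: int
    breed_specific: bool = False

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class ConsensusParams:
    """Consensus/exclusion thresholds.

    ``min_support_case`` is an integer or the string "all" (every group
    member must share the region).  ``max_support_excluded`` removes
    base pairs covered by ROH in at least that many excluded-group
    members; 1 means any overlap removes.  Fragments shorter than
    ``min_fragment_bp`` left over after subtraction are dropped.
    """

    min_support_case: int | str = "all"
    max_support_excluded: int = 1
    min_fragment_bp: int = 1000

    def __post_init__(self) -> None:
        if self.min_support_case != "all" and int(self.min_support_case) < 1:
            raise ValueError("min_support_case must be >= 1 or 'all'")
        if self.max_support_excluded < 1:
            raise ValueError("max_support_excluded must be >= 1")


@dataclass(frozen=True)
class FrohResult:
    """Per-sample genomic inbreeding: summed autosomal ROH length over
    the captured autosomal genome size."""

    sample_id: str
    sum_roh_bp: int
    froh: float


def _support_intervals(
    segments: Iterable[ROHSegment], min_support: int
) -> dict[str, list[tuple[int, int, int]]]:
    """Maximal intervals with per-bp support >= min_support, per chrom.

    Returns chrom -> list of (start, end, min support over interval...).
    Support at each bp counts samples with a ROH covering it; each
    returned interval carries the minimum support across it (which is
    >= min_support).
    """
    events: dict[str, dict[int, int]] = {}
    for seg in segments:
        ev = events.setdefault(seg.chrom, {})
        ev[seg.start_bp] = ev.get(seg.start_bp, 0) + 1
        ev[seg.end_bp + 1] = ev.get(seg.end_bp + 1, 0) - 1
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, ev in events.items():
        intervals: list[tuple[int, int, int]] = []
        support = 0
        open_start: int | None = None
        open_min = 0
        for pos in sorted(ev):
            prev_support = support
            support += ev[pos]
            if prev_support >= min_support and support >= min_support:
                open_min = min(open_min, support)
                continue
            if support >= min_support and prev_support < min_support:
                open_start = pos
                open_min = support
            elif support < min_support and prev_support >= min_support:
                intervals.append((open_start, pos - 1, open_min))
                open_start = None
        out[chrom] = intervals
    return out


def consensus_regions(
    segments: Sequence[ROHSegment],
    group_sample_ids: Sequence[str],
    min_support: int | str = "all",
) -> list[ConsensusRegion]:
    """Maximal intervals covered by a ROH in >= ``min_support`` members
    of the group ("all" = every member).

    Segments per sample must be non-overlapping (the caller contract of
    the ROH detector).  Group members with no segments contribute zero
    coverage and trigger a warning, not an error.
    """
    group = set(group_sample_ids)
    if min_support == "all":
        min_support = len(group)
    min_support = int(min_support)
    group_segments = [s for s in segments if s.sample_id in group]
    present = {s.sample_id for s in group_segments}
    for sid in sorted(group - present):
        warnings.warn(f"group sample {sid} has no ROH segments", stacklevel=2)
    regions = [
        # support reported per region is the minimum per-bp support across
        # it: the number of members sharing the least-shared base
        ConsensusRegion(chrom, start, end, support)
        for chrom, intervals in _support_intervals(group_segments,
                                                   min_support).items()
        for start, end, support in intervals
    ]
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def breed_specific_filter(
    consensus: Sequence[ConsensusRegion],
    excluded_segments: Sequence[ROHSegment],
    max_support_excluded: int = 1,
    min_fragment_bp: int = 1000,
    drop_whole_region: bool = False,
) -> list[ConsensusRegion]:
    """Remove from consensus regions every base covered by ROH in at
    least ``max_support_excluded`` excluded-group members.

    With ``drop_whole_region`` the entire region is discarded on any
    such overlap instead of being fragmented.  Fragments shorter than
    ``min_fragment_bp`` are dropped; survivors are flagged
    ``breed_specific``.
    """
    blocked = _support_intervals(excluded_segments, max_support_excluded)
    out: list[ConsensusRegion] = []
    for region in consensus:
        chrom_blocked = [
            (max(s, region.start_bp), min(e, region.end_bp))
            for s, e, _ in blocked.get(region.chrom, [])
            if s <= region.end_bp and e >= region.start_bp
        ]
        if not chrom_blocked:
            out.append(ConsensusRegion(region.chrom, region.start_bp,
                                       region.end_bp, region.support, True))
            continue
        if drop_whole_region:
            continue
        cursor = region.start_bp
        for s, e in sorted(chrom_blocked):
            if s > cursor:
                _append_fragment(out, region, cursor, s - 1, min_fragment_bp)
            cursor = max(cursor, e + 1)
        if cursor <= region.end_bp:
            _append_fragment(out, region, cursor, region.end_bp, min_fragment_bp)
    out.sort(key=lambda r: (r.chrom, r.start_bp))
    return out


def _append_fragment(out, region, start, end, min_fragment_bp):
    if end - start + 1 >= min_fragment_bp:
        out.append(ConsensusRegion(region.chrom, start, end, region.support,
                                   True))


def coverage_table(
    regions: Sequence[ConsensusRegion], genome: GenomeSpec
) -> pd.DataFrame:
    """Per-chromosome consensus size (kb) and coverage (% of chromosome
    length); chromosomes without regions appear with zeros."""
    totals: dict[str, int] = {c: 0 for c in genome.autosomes()}
    for r in regions:
        if r.chrom not in genome.chrom_lengths:
            raise ValueError(f"region on {r.chrom} absent from genome spec")
        totals[r.chrom] = totals.get(r.chrom, 0) + r.length_bp
    rows = []
    for chrom in genome.autosomes():
        length = genome.chrom_lengths[chrom]
        kb = totals.get(chrom, 0) / 1000.0
        rows.append((chrom, kb, 100.0 * totals.get(chrom, 0) / length))
    return pd.DataFrame(rows, columns=["chrom", "total_consensus_kb",
                                       "coverage_pct"])


def froh(
    segments: Sequence[ROHSegment],
    genome: GenomeSpec,
    sample_ids: Sequence[str] | None = None,
) -> list[FrohResult]:
    """Genomic inbreeding coefficient per sample.

    F_ROH = summed length of autosomal ROH / autosomal genome size
    captured by the SNP set.  Segments on excluded chromosomes are
    ignored; overlapping segments within a sample are a caller-contract
    violation and raise.
    """
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        if seg.chrom in genome.excluded_chroms:
            continue
        by_sample.setdefault(seg.sample_id, []).append(seg)
    if sample_ids is None:
        sample_ids = sorted(by_sample)
    results = []
    for sid in sample_ids:
        segs = sorted(by_sample.get(sid, []),
                      key=lambda s: (s.chrom, s.start_bp))
        total = 0
        prev: ROHSegment | None = None
        for seg in segs:
            if (prev is not None and seg.chrom == prev.chrom
                    and seg.start_bp <= prev.end_bp):
                raise ValueError(
                    f"overlapping ROH segments for {sid} on {seg.chrom}"
                )
            total += seg.length_bp
            prev = seg
        results.append(FrohResult(sid, total,
                                  total / genome.autosomal_captured_bp))
    return results


def mean_froh(
    results: Sequence[FrohResult], group_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Arithmetic mean of individual F_ROH, overall or per group label."""
    df = pd.DataFrame([(r.sample_id, r.sum_roh_bp, r.froh) for r in results],
                      columns=["sample_id", "sum_roh_bp", "froh"])
    if group_of is None:
        return pd.DataFrame({"group": ["all"], "mean_froh": [df["froh"].mean()],
                             "n": [len(df)]})
    df["group"] = df["sample_id"].map(group_of)
    out = df.groupby("group", dropna=False)["froh"].agg(["mean", "size"])
    return out.reset_index().rename(columns={"mean": "mean_froh", "size": "n"})


def regions_to_frame(regions: Sequence[ConsensusRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start_bp, r.end_bp, r.support, r.length_kb,
          r.breed_specific) for r in regions],
        columns=["chrom", "start_bp", "end_bp", "support", "length_kb",
                 "breed_specific"],
    )


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het,
          s.n_missing, s.length_kb) for s in segments],
        columns=["sample", "chrom", "start", "end", "n_snps", "n_het",
                 "n_missing", "length_kb"],
    )
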