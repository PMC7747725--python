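"""Sliding-window runs-of-homozygosity (ROH) calling.

The detector follows the incremental-window scheme popularised by PLINK's
``--homozyg``: a window of ``window_snps`` consecutive SNPs is "hit"
(homozygous) when it contains at most ``window_het`` heterozygous and at
most ``window_missing`` missing calls; each SNP's hit rate is the
fraction of hit windows among the windows overlapping it; SNPs whose hit
rate reaches ``hit_rate_threshold`` are eligible; maximal runs of
eligible SNPs — split wherever adjacent SNPs are further apart than
``max_gap_kb`` — become ROH segments if they satisfy the minimum SNP
count, minimum length and maximum kb-per-SNP density.

``brute_force_roh`` re-derives the same definition by explicit
enumeration of every window, SNP and run, independently of the vectorised
path, and serves as the correctness oracle on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model import GENO_HET, GENO_MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Parameters of the sliding-window ROH scan.

    Defaults are the whole-genome-sequencing preset: 20-SNP windows
    tolerating 3 heterozygous and 5 missing calls, runs of >= 20 SNPs
    spanning >= 2.4 kb at a density of at most 0.12 kb per SNP, with a
    maximum within-run gap of 100 kb.  ``hit_rate_threshold`` (the
    fraction of overlapping hit windows a SNP needs to be eligible) is
    a detector convention rather than a published value; 0.05 is the
    common default.  With ``strict_window`` set, chromosomes shorter
    than one window yield no calls instead of being evaluated as a
    single truncated window.
    """

    window_snps: int = 20
    window_het: int = 3
    window_missing: int = 5
    hit_rate_threshold: float = 0.05
    min_snps: int = 20
    min_length_kb: float = 2.4
    density_kb_per_snp: float = 0.12
    max_gap_kb: float = 100.0
    strict_window: bool = False
    max_segment_het: int | None = None
    max_segment_missing: int | None = None

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if self.window_het >= self.window_snps:
            raise ValueError("window_het must be < window_snps")
        if not 0 < self.hit_rate_threshold <= 1:
            raise ValueError("hit_rate_threshold must be in (0, 1]")
        for name in ("min_snps", "min_length_kb", "density_kb_per_snp",
                     "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: WGS preset: dense variant panels (one SNP per ~0.1 kb).
WGS_PRESET = ROHParams()
#: SNP-chip preset: sparse panels (one SNP per up to 1000 kb, >= 10 kb runs).
CHIP_PRESET = ROHParams(min_length_kb=10.0, density_kb_per_snp=1000.0)
PRESETS = {"wgs": WGS_PRESET, "chip": CHIP_PRESET}


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run for one sample (1-based closed coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def snp_hit_rates(
    genos: np.ndarray, params: ROHParams, *, return_rates: bool = False
) -> np.ndarray:
    """Per-SNP eligibility flags for one sample on one chromosome.

    For each SNP the hit rate is the fraction of the full ``window_snps``
    windows containing it that hold at most ``window_het`` het and
    ``window_missing`` missing calls; the flag is hit rate >=
    ``hit_rate_threshold``.  SNPs near chromosome ends use only the
    windows that exist; a chromosome with fewer SNPs than one window is
    evaluated as a single truncated window (all SNPs share its verdict)
    unless ``strict_window`` is set.
    """
    genos = np.asarray(genos)
    n = genos.size
    w = params.window_snps
    if n == 0:
        rates = np.zeros(0)
        return rates if return_rates else rates.astype(bool)
    het = (genos == GENO_HET).astype(np.int64)
    mis = (genos == GENO_MISSING).astype(np.int64)
    if n < w:
        if params.strict_window:
            rates = np.zeros(n)
        else:
            ok = het.sum() <= params.window_het and mis.sum() <= params.window_missing
            rates = np.full(n, 1.0 if ok else 0.0)
    else:
        # window s covers SNPs [s, s+w); there are n-w+1 windows
        chet = np.concatenate([[0], np.cumsum(het)])
        cmis = np.concatenate([[0], np.cumsum(mis)])
        win_het = chet[w:] - chet[:-w]
        win_mis = cmis[w:] - cmis[:-w]
        hit = ((win_het <= params.window_het)
               & (win_mis <= params.window_missing)).astype(np.int64)
        chit = np.concatenate([[0], np.cumsum(hit)])
        idx = np.arange(n)
        lo = np.maximum(0, idx - w + 1)
        hi = np.minimum(idx, n - w)  # inclusive last window index
        n_windows = hi - lo + 1
        n_hit = chit[hi + 1] - chit[lo]
        rates = n_hit / n_windows
    if return_rates:
        return rates
    return rates >= params.hit_rate_threshold


def segments_from_flags(
    flags: np.ndarray,
    positions: np.ndarray,
    genos: np.ndarray,
    params: ROHParams,
    sample_id: str = "",
    chrom: str = "",
) -> list[ROHSegment]:
    """Assemble ROH segments from per-SNP eligibility flags.

    Maximal runs of flagged SNPs are split wherever adjacent SNPs lie
    more than ``max_gap_kb`` apart; each piece survives iff it has at
    least ``min_snps`` SNPs, spans at least ``min_length_kb`` and has at
    most ``density_kb_per_snp`` kb per SNP.  Endpoints are the positions
    of the first and last SNP of the piece.
    """
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions, dtype=np.int64)
    genos = np.asarray(genos)
    max_gap_bp = params.max_gap_kb * 1000.0
    segments: list[ROHSegment] = []

    n = flags.size
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1]:
            j += 1
        # split [i, j] at gaps
        piece_start = i
        for k in range(i, j + 1):
            at_end = k == j
            split_after = (not at_end
                           and positions[k + 1] - positions[k] > max_gap_bp)
            if at_end or split_after:
                seg = _make_segment(piece_start, k, positions, genos, params,
                                    sample_id, chrom)
                if seg is not None:
                    segments.append(seg)
                piece_start = k + 1
        i = j + 1
    return segments


def _make_segment(first, last, positions, genos, params, sample_id, chrom):
    n_snps = last - first + 1
    length_bp = int(positions[last] - positions[first] + 1)
    length_kb = length_bp / 1000.0
    if n_snps < params.min_snps:
        return None
    if length_kb < params.min_length_kb:
        return None
    if length_kb / n_snps > params.density_kb_per_snp:
        return None
    piece = genos[first:last + 1]
    n_het = int((piece == GENO_HET).sum())
    n_missing = int((piece == GENO_MISSING).sum())
    if params.max_segment_het is not None and n_het > params.max_segment_het:
        return None
    if (params.max_segment_missing is not None
            and n_missing > params.max_segment_missing):
        return None
    return ROHSegment(sample_id, chrom, int(positions[first]),
                      int(positions[last]), n_snps, n_het, n_missing)


def call_roh(
    matrix: GenotypeMatrix,
    params: ROHParams = WGS_PRESET,
    genome=None,
) -> list[ROHSegment]:
    """Call ROH for every sample on every chromosome of the matrix.

    Output is ordered by sample (matrix order), then chromosome, then
    start position, and is deterministic given the inputs.
    """
    if params.window_snps > params.min_snps:
        log.warning(
            "window_snps (%d) exceeds min_snps (%d): runs shorter than one "
            "window cannot be flagged", params.window_snps, params.min_snps,
        )
    segments: list[ROHSegment] = []
    positions = matrix.positions()
    for i, rec in enumerate(matrix.samples):
        for chrom, block in matrix.iter_chrom_blocks():
            genos = matrix.geno[i, block]
            pos = positions[block]
            flags = snp_hit_rates(genos, params)
            segments.extend(
                segments_from_flags(flags, pos, genos, params,
                                    sample_id=rec.sample_id, chrom=chrom)
            )
    _log_summary(segments, matrix)
    return segments


def _log_summary(segments: list[ROHSegment], matrix: GenotypeMatrix) -> None:
    if not matrix.n_samples:
        return
    n = len(segments)
    total_kb = sum(s.length_kb for s in segments)
    per_sample = n / matrix.n_samples
    log.info(
        "called %d ROH (average number of ROHs %.2f per individual, "
        "total mean length %.1f kb)", n, per_sample,
        total_kb / matrix.n_samples,
    )


def roh_summary(segments: list[ROHSegment]) -> "pd.DataFrame":
    """Per-sample count and total length of ROH, as reported in run logs."""
    import pandas as pd

    rows: dict[str, list] = {}
    for s in segments:
        rows.setdefault(s.sample_id, []).append(s.length_kb)
    return pd.DataFrame(
        [(sid, len(v), sum(v)) for sid, v in sorted(rows.items())],
        columns=["sample_id", "n_roh", "total_kb"],
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_roh(
    matrix: GenotypeMatrix, params: ROHParams
) -> list[ROHSegment]:
    """Reference ROH caller by explicit enumeration (small inputs only).

    Evaluates every window, every SNP's hit rate and every maximal run
    with plain Python loops, independently of :func:`call_roh`.  Refuses
    matrices with more than 10,000 sites.
    """
    if matrix.n_sites > 10_000:
        raise ValueError("brute_force_roh is an oracle for <= 10,000 SNPs")
    segments: list[ROHSegment] = []
    for i, rec in enumerate(matrix.samples):
        for chrom, block in matrix.iter_chrom_blocks():
            genos = [int(g) for g in matrix.geno[i, block]]
            pos = [s.pos for s in matrix.sites[block]]
            flags = _bf_flags(genos, params)
            segments.extend(
                _bf_segments(flags, pos, genos, params, rec.sample_id, chrom)
            )
    return segments


def _bf_window_ok(genos: list[int], params: ROHParams) -> bool:
    n_het = sum(1 for g in genos if g == GENO_HET)
    n_mis = sum(1 for g in genos if g == GENO_MISSING)
    return n_het <= params.window_het and n_mis <= params.window_missing


def _bf_flags(genos: list[int], params: ROHParams) -> list[bool]:
    n = len(genos)
    w = params.window_snps
    if n == 0:
        return []
    if n < w:
        if params.strict_window:
            return [False] * n
        verdict = _bf_window_ok(genos, params)
        return [verdict] * n
    window_ok = [_bf_window_ok(genos[s:s + w], params) for s in range(n - w + 1)]
    flags = []
    for i in range(n):
        covering = [window_ok[s] for s in range(n - w + 1) if s <= i <= s + w - 1]
        rate = sum(covering) / len(covering)
        flags.append(rate >= params.hit_rate_threshold)
    return flags


def _bf_segments(flags, pos, genos, params, sample_id, chrom):
    out = []
    runs = []
    current: list[int] = []
    for i, f in enumerate(flags):
        if f:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    # split each maximal run at large gaps
    pieces = []
    for run in runs:
        piece = [run[0]]
        for idx in run[1:]:
            if pos[idx] - pos[piece[-1]] > params.max_gap_kb * 1000.0:
                pieces.append(piece)
                piece = []
            piece.append(idx)
        pieces.append(piece)
    for piece in pieces:
        n_snps = len(piece)
        length_bp = pos[piece[-1]] - pos[piece[0]] + 1
        length_kb = length_bp / 1000.0
        if n_snps < params.min_snps:
            continue
        if length_kb < params.min_length_kb:
            continue
        if length_kb / n_snps > params.density_kb_per_snp:
            continue
        n_het = sum(1 for idx in piece if genos[idx] == GENO_HET)
        n_mis = sum(1 for idx in piece if genos[idx] == GENO_MISSING)
        if params.max_segment_het is not None and n_het > params.max_segment_het:
            continue
        if (params.max_segment_missing is not None
                and n_mis > params.max_segment_missing):
            continue
        out.append(ROHSegment(sample_id, chrom, pos[piece[0]], pos[piece[-1]],
                              n_snps, n_het, n_mis))
    return out


def make_params(preset: str = "wgs", **overrides) -> ROHParams:
    """Return a preset parameter set, optionally with field overrides."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[preset], **overrides)
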