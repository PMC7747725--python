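"""Gene overlap of consensus regions and local gene-set enrichment.

Region-to-gene assignment uses any-overlap (>= 1 bp) semantics on
1-based closed intervals.  Enrichment is a local Fisher exact test on
the hypergeometric distribution, plus the EASE variant in which one
success is removed from the overlap before taking the tail — a
conservative adjustment used by DAVID-style annotation tools.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .consensus import ConsensusRegion


def genes_in_regions(
    regions: Sequence[ConsensusRegion], genes: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Genes overlapping each region by at least one base.

    ``genes`` is a DataFrame with columns ``gene_id chrom start end``
    (1-based closed; unsorted input is fine).  Returns a per-region
    table (one row per region x overlapping gene) and the deduplicated,
    sorted global gene list.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # IntervalTree is half-open; end+1 makes the closed end inclusive
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end) + 1, str(row.gene_id)
        )
    rows = []
    all_genes: set[str] = set()
    for r in regions:
        tree = trees.get(r.chrom)
        hits = sorted(iv.data for iv in tree.overlap(r.start_bp, r.end_bp + 1)) \
            if tree is not None else []
        for gid in hits:
            rows.append((r.chrom, r.start_bp, r.end_bp, gid))
        all_genes.update(hits)
    table = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                        "gene_id"])
    return table, sorted(all_genes)


def enrichment(
    gene_list: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]] | pd.DataFrame,
    ease_threshold: float = 0.1,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Fisher exact / EASE enrichment of ``gene_list`` against gene sets.

    For each set: N = background size, K = set members in the
    background, n = query size, k = overlap.  ``fisher_p`` is the
    one-sided hypergeometric upper tail P(X >= k); ``ease_p`` the same
    tail with one success removed (P(X >= k-1) on the same margins),
    defined as 1 when k <= 1.  Rows with ``ease_p <= ease_threshold``
    are flagged ``enriched``.  ``bh_correct`` adds Benjamini–Hochberg
    adjusted EASE scores.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene list")
    query = set(gene_list)
    stray = query - background
    if stray:
        raise ValueError(
            f"gene_list has {len(stray)} genes outside the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    if isinstance(gene_sets, pd.DataFrame):
        gene_sets = {
            set_id: set(sub["gene_id"])
            for set_id, sub in gene_sets.groupby("set_id")
        }
    N, n = len(background), len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & background
        K = len(members)
        k = len(query & members)
        fisher_p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        ease_p = float(hypergeom.sf(k - 2, N, K, n)) if k > 1 else 1.0
        rows.append((set_id, k, K, n, N, min(fisher_p, 1.0), min(ease_p, 1.0)))
    table = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N",
                                        "fisher_p", "ease_p"])
    if bh_correct and len(table):
        from statsmodels.stats.multitest import multipletests

        table["ease_p_bh"] = multipletests(table["ease_p"], method="fdr_bh")[1]
    table["enriched"] = table["ease_p"] <= ease_threshold
    return table
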