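"""Readers and writers for the external formats the pipeline touches.

VCF is read with cyvcf2; PLINK text MAP/PED, BED interval files, sample
metadata and genome-spec TSVs are simple whitespace/tab-delimited text.
Internal coordinates are always 1-based closed; the BED writer converts
to 0-based half-open on output and the BED reader converts back.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    GENO_MISSING,
    GenomeSpec,
    GenotypeMatrix,
    SampleRecord,
    VariantSite,
    max_impact,
)

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "breed", "group", "phenotype"]


# ---------------------------------------------------------------------------
# sample metadata / genome spec
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (`sample_id  breed  group  phenotype`)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks columns: {sorted(missing)}")
    records = [
        SampleRecord(r.sample_id, r.breed, r.group, r.phenotype)
        for r in df.itertuples(index=False)
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.breed, r.group, r.phenotype) for r in records],
        columns=METADATA_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_genome_spec(
    path: str | Path,
    autosomal_captured_bp: int | None = None,
    excluded_chroms: Iterable[str] = ("X", "Y", "Mt", "Un"),
) -> GenomeSpec:
    """Read a `chrom  length` TSV into a GenomeSpec."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, names=["chrom", "length"],
                     header=None, comment="#")
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    kwargs = {} if autosomal_captured_bp is None else {
        "autosomal_captured_bp": autosomal_captured_bp
    }
    return GenomeSpec(chrom_lengths=lengths,
                      excluded_chroms=frozenset(excluded_chroms), **kwargs)


def write_genome_spec(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_ann_impact(ann: str | None) -> str:
    """Highest-severity impact across SnpEff ANN transcript entries."""
    if not ann:
        return "NONE"
    impacts = []
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) > 2:
            impacts.append(fields[2].strip())
    return max_impact(impacts)


def read_vcf(
    path: str | Path,
    metadata: Sequence[SampleRecord],
    split_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Genotypes come from GT (0 hom-ref / 1 het / 2 hom-alt / -1 missing),
    per-sample depth from FORMAT/DP when present, and the impact class
    from INFO/ANN (maximum severity across transcripts).  Multi-allelic
    records are split into biallelic records at the same position by
    default, or skipped when ``split_multiallelic`` is false.
    """
    meta_by_id = {r.sample_id: r for r in metadata}
    vcf = VCF(str(path), gts012=True)
    for sid in vcf.samples:
        if sid not in meta_by_id:
            raise ValueError(f"VCF sample {sid!r} absent from metadata")
    samples = [meta_by_id[sid] for sid in vcf.samples]

    sites: list[VariantSite] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None

    for var in vcf:
        chrom, pos = var.CHROM, var.POS
        if chrom != prev_chrom:
            if chrom in seen_chroms:
                raise ValueError(f"unsorted VCF: chromosome {chrom} re-appears")
            seen_chroms.add(chrom)
            prev_chrom = chrom
        elif last is not None and pos < last[1]:
            raise ValueError(f"unsorted VCF at {chrom}:{pos}")
        last = (chrom, pos)

        alts = var.ALT
        if len(alts) != 1 and not split_multiallelic:
            continue
        impact = _parse_ann_impact(var.INFO.get("ANN"))
        try:
            dp = var.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            dp = np.asarray(dp, dtype=np.int32).reshape(-1)
            dp = np.where(dp < 0, 0, dp)
            any_depth = True
        else:
            dp = np.zeros(len(samples), dtype=np.int32)

        if len(alts) == 1:
            # gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            gt = np.asarray(var.gt_types, dtype=np.int8)
            codes = [np.where(gt == 3, GENO_MISSING, gt).astype(np.int8)]
        else:
            # decode per alt allele: code k = number of copies of allele k+1
            alleles = np.asarray([g[:2] for g in var.genotypes], dtype=np.int8)
            codes = []
            for k in range(len(alts)):
                cnt = (alleles == k + 1).sum(axis=1).astype(np.int8)
                cnt[np.any(alleles < 0, axis=1)] = GENO_MISSING
                codes.append(cnt)
            log.warning("multi-allelic record at %s:%d split into %d sites",
                        chrom, pos, len(alts))

        for alt, gt in zip(alts, codes):
            var_class = "SNP" if len(var.REF) == 1 and len(alt) == 1 else "INDEL"
            sites.append(
                VariantSite(chrom, pos, var.REF, alt, impact, var_class,
                            site_id=var.ID or "")
            )
            geno_rows.append(gt)
            depth_rows.append(dp)

    geno = (np.stack(geno_rows, axis=1)
            if geno_rows else np.zeros((len(samples), 0), dtype=np.int8))
    depth = (np.stack(depth_rows, axis=1)
             if depth_rows else np.zeros((len(samples), 0), dtype=np.int32))
    return GenotypeMatrix(sites, samples, geno,
                          depth if any_depth else None)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as an uncompressed VCF 4.2 with GT, DP and ANN."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = dict.fromkeys(s.chrom for s in matrix.sites)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,'
                 'Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        has_depth = matrix.depth is not None
        fmt = "GT:DP" if has_depth else "GT"
        for j, site in enumerate(matrix.sites):
            if site.impact != "NONE":
                info = f"ANN={site.alt}|variant|{site.impact}|gene{j}"
            else:
                info = "."
            cells = []
            for i in range(matrix.n_samples):
                g = gt_str[int(matrix.geno[i, j])]
                cells.append(f"{g}:{int(matrix.depth[i, j])}" if has_depth else g)
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id or '.'}\t"
                f"{site.ref}\t{site.alt}\t.\t.\t{info}\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK text MAP/PED
# ---------------------------------------------------------------------------

def read_plink_text(
    map_path: str | Path,
    ped_path: str | Path,
    metadata: Sequence[SampleRecord],
) -> GenotypeMatrix:
    """Read PLINK text MAP/PED into a GenotypeMatrix.

    Allele pairs are recoded against the major/minor alleles observed in
    the file: hom-major -> 0, het -> 1, hom-minor -> 2, ``0 0`` -> -1.
    """
    meta_by_id = {r.sample_id: r for r in metadata}
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns, "
                                 f"got {len(fields)}")
            map_rows.append((fields[0], fields[1], int(fields[3])))
    n_sites = len(map_rows)

    sample_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_sites:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_sites} columns "
                    f"for {n_sites} sites, got {len(fields)}"
                )
            sid = fields[1]
            if sid not in meta_by_id:
                raise ValueError(f"PED sample {sid!r} absent from metadata")
            sample_ids.append(sid)
            allele_pairs.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_sites)]
            )

    geno = np.full((len(sample_ids), n_sites), GENO_MISSING, dtype=np.int8)
    sites: list[VariantSite] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for pairs in allele_pairs:
            for a in pairs[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        # major first; deterministic tie-break on allele name
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        major = alleles[0] if alleles else "A"
        minor = alleles[1] if len(alleles) > 1 else ("B" if major != "B" else "C")
        for i, pairs in enumerate(allele_pairs):
            a, b = pairs[j]
            if a == "0" or b == "0":
                geno[i, j] = GENO_MISSING
            elif a == b:
                geno[i, j] = 0 if a == major else 2
            else:
                geno[i, j] = 1
        sites.append(VariantSite(chrom, pos, major, minor, site_id=snp_id))

    order = sorted(range(n_sites), key=lambda j: (sites[j].chrom, sites[j].pos))
    sites = [sites[j] for j in order]
    geno = geno[:, order]
    samples = [meta_by_id[sid] for sid in sample_ids]
    return GenotypeMatrix(sites, samples, geno)


def write_plink_text(
    matrix: GenotypeMatrix, map_path: str | Path, ped_path: str | Path
) -> None:
    """Write a matrix as PLINK text MAP/PED (ref allele as major)."""
    with open(map_path, "w") as fh:
        for j, s in enumerate(matrix.sites):
            fh.write(f"{s.chrom}\t{s.site_id or f'snp{j}'}\t0\t{s.pos}\n")
    with open(ped_path, "w") as fh:
        for i, rec in enumerate(matrix.samples):
            pheno = {"curly": "2", "straight": "1"}.get(rec.phenotype, "0")
            cells = [rec.breed.replace(" ", "_"), rec.sample_id, "0", "0", "0",
                     pheno]
            for j, s in enumerate(matrix.sites):
                g = int(matrix.geno[i, j])
                ref, alt = s.ref[0], s.alt[0]
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt),
                        -1: ("0", "0")}[g]
                cells.extend(pair)
            fh.write(" ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def write_intervals_bed(
    regions: Iterable, path: str | Path, name_field: str | None = None
) -> None:
    """Write intervals (1-based closed ``chrom``/``start_bp``/``end_bp``
    attributes or tuples) as sorted BED (0-based half-open)."""
    rows = []
    for r in regions:
        if hasattr(r, "chrom"):
            chrom, start, end = r.chrom, r.start_bp, r.end_bp
            name = getattr(r, name_field, "") if name_field else ""
        else:
            chrom, start, end = r[0], r[1], r[2]
            name = r[3] if name_field and len(r) > 3 else ""
        rows.append((chrom, start - 1, end, str(name)))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend" + ("\tname" if name_field else "") + "\n")
        for chrom, start, end, name in rows:
            line = f"{chrom}\t{start}\t{end}"
            if name_field:
                line += f"\t{name}"
            fh.write(line + "\n")


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED back into 1-based closed (chrom, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.split()
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


# ---------------------------------------------------------------------------
# gene intervals
# ---------------------------------------------------------------------------

def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from a TSV with columns
    ``gene_id chrom start end`` (1-based closed) or from BED
    (autodetected by numeric second column); returns a sorted DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"gene file {path} needs >= 3 columns")
    first = df.iloc[0]
    try:
        int(first[1])
        is_bed = True
    except (TypeError, ValueError):
        is_bed = False
    if is_bed:  # chrom start end name -> convert to 1-based closed
        out = pd.DataFrame({
            "gene_id": df[3] if df.shape[1] > 3 else df.index.astype(str),
            "chrom": df[0],
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
        })
    else:
        out = pd.DataFrame({
            "gene_id": df[0], "chrom": df[1],
            "start": df[2].astype(int), "end": df[3].astype(int),
        })
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
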