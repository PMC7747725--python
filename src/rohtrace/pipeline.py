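"""End-to-end pipeline: ROH -> consensus -> breed-specificity -> coverage
-> F_ROH -> candidate funnel -> validation tables, with a run manifest.

The pipeline either consumes a VCF + metadata + genome spec or generates
a synthetic cohort first; every stage writes a TSV into the output
directory and records its counts in ``manifest.json``.  Given the same
configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as rio
from .consensus import (
    ConsensusParams,
    breed_specific_filter,
    consensus_regions,
    coverage_table,
    froh,
    mean_froh,
    regions_to_frame,
    segments_to_frame,
)
from .model import DepthQCParams, GenomeSpec
from .qc import apply_depth_qc
from .roh import PRESETS, call_roh, make_params
from .segregation import dominance_consistency, genotype_frequencies, imputation_error
from .simulate import SimConfig, simulate
from .variants import FunnelCriteria, candidate_filter, counts_to_frame, carrier_counts

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "outdir", "seed", "preset", "vcf", "metadata", "genome",
    "simulate", "depth_qc", "roh", "consensus", "funnel", "log_level",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``simulate`` toggles synthetic-cohort generation (fields under
    ``sim_overrides`` are forwarded to :class:`SimConfig`); otherwise
    ``vcf``/``metadata``/``genome`` name the inputs.  Unknown keys in a
    config file are rejected.
    """

    outdir: str = "rohtrace_out"
    seed: int = 0
    preset: str = "wgs"
    vcf: str | None = None
    metadata: str | None = None
    genome: str | None = None
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    depth_qc: DepthQCParams | None = None
    roh_overrides: dict = field(default_factory=dict)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    min_support_case: int | str = "all"
    funnel: FunnelCriteria = field(default_factory=FunnelCriteria)
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("outdir", "seed", "preset", "vcf", "metadata", "genome",
                    "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "simulate" in raw:
            sim = raw["simulate"]
            if isinstance(sim, dict):
                kwargs["simulate"] = True
                kwargs["sim_overrides"] = sim
            else:
                kwargs["simulate"] = bool(sim)
        if "depth_qc" in raw:
            kwargs["depth_qc"] = DepthQCParams(**raw["depth_qc"])
        if "roh" in raw:
            kwargs["roh_overrides"] = raw["roh"]
        if "consensus" in raw:
            cons = dict(raw["consensus"])
            kwargs["min_support_case"] = cons.pop("min_support_case", "all")
            kwargs["consensus"] = ConsensusParams(
                min_support_case=kwargs["min_support_case"], **cons)
        if "funnel" in raw:
            fun = dict(raw["funnel"])
            if "impacts" in fun:
                fun["impacts"] = frozenset(fun["impacts"])
            kwargs["funnel"] = FunnelCriteria(**fun)
        return cls(**kwargs)


def _serialisable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialisable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: _serialisable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialisable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Stages: (optional) simulate -> depth QC -> ROH calling -> consensus
    regions -> breed-specific filter -> coverage -> F_ROH -> carrier
    counts + candidate funnel -> dominant-model check (-> imputation
    error on synthetic runs).  Any stage failure aborts with the stage
    name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "config": _serialisable(config), "stages": {}}
    stage = "setup"
    try:
        truth = None
        if config.simulate:
            stage = "simulate"
            sim_cfg = SimConfig(seed=config.seed, **config.sim_overrides)
            sim = simulate(sim_cfg)
            sim.write(outdir / "synthetic")
            matrix, genome, truth = sim.observed, sim.genome, sim.truth
        else:
            stage = "read inputs"
            if not (config.vcf and config.metadata and config.genome):
                raise ValueError("vcf, metadata and genome paths are required "
                                 "when simulate is off")
            metadata = rio.read_metadata(config.metadata)
            matrix = rio.read_vcf(config.vcf, metadata)
            genome = rio.read_genome_spec(config.genome)
            if matrix.n_sites == 0:
                raise ValueError(f"no usable records in VCF {config.vcf}")
        manifest["stages"]["input"] = {"n_samples": matrix.n_samples,
                                       "n_sites": matrix.n_sites}

        if config.depth_qc is not None:
            stage = "depth QC"
            matrix = apply_depth_qc(matrix, config.depth_qc)
            manifest["stages"]["depth_qc"] = {"n_sites": matrix.n_sites}

        stage = "ROH calling"
        params = make_params(config.preset, **config.roh_overrides)
        segments = call_roh(matrix, params, genome)
        segments_to_frame(segments).to_csv(outdir / "segments.tsv", sep="\t",
                                           index=False)
        manifest["stages"]["roh"] = {
            "n_segments": len(segments),
            "mean_per_sample": len(segments) / max(matrix.n_samples, 1),
        }

        stage = "consensus regions"
        case_ids = matrix.group_members("case")
        cons = consensus_regions(segments, case_ids,
                                 config.consensus.min_support_case)
        regions_to_frame(cons).to_csv(outdir / "consensus.tsv", sep="\t",
                                      index=False)
        manifest["stages"]["consensus"] = {
            "n_regions": len(cons),
            "total_kb": sum(r.length_kb for r in cons),
        }

        stage = "breed-specific filter"
        cross_ids = set(matrix.group_members("crossbreed"))
        cross_segments = [s for s in segments if s.sample_id in cross_ids]
        specific = breed_specific_filter(
            cons, cross_segments, config.consensus.max_support_excluded,
            config.consensus.min_fragment_bp)
        regions_to_frame(specific).to_csv(outdir / "breed_specific.tsv",
                                          sep="\t", index=False)
        rio.write_intervals_bed(specific, outdir / "breed_specific.bed")
        manifest["stages"]["breed_specific"] = {
            "n_regions": len(specific),
            "total_kb": sum(r.length_kb for r in specific),
        }

        stage = "coverage"
        coverage_table(specific, genome).to_csv(outdir / "coverage.tsv",
                                                sep="\t", index=False)

        stage = "F_ROH"
        froh_results = froh(segments, genome, matrix.sample_ids)
        breed_of = {s.sample_id: s.breed for s in matrix.samples}
        table = mean_froh(froh_results, breed_of)
        table.to_csv(outdir / "froh_group_means.tsv", sep="\t", index=False)
        import pandas as pd

        pd.DataFrame([(r.sample_id, r.sum_roh_bp, r.froh)
                      for r in froh_results],
                     columns=["sample_id", "sum_roh_bp", "froh"]).to_csv(
            outdir / "froh.tsv", sep="\t", index=False)
        manifest["stages"]["froh"] = {
            "mean_case_froh": float(
                table.loc[table["group"] == "case_breed", "mean_froh"].iloc[0]
            ) if (table["group"] == "case_breed").any() else None,
        }

        stage = "candidate funnel"
        counts_to_frame(carrier_counts(matrix)).to_csv(
            outdir / "carrier_counts.tsv", sep="\t", index=False)
        survivors, report = candidate_filter(matrix, config.funnel)
        with open(outdir / "funnel_report.tsv", "w") as fh:
            fh.write("stage\tn\n")
            for name, n in report.stages:
                fh.write(f"{name}\t{n}\n")
        with open(outdir / "funnel_survivors.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\timpact\n")
            for s in survivors:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                         f"{s.impact}\n")
        manifest["stages"]["funnel"] = {name: n for name, n in report.stages}

        stage = "dominant-model check"
        candidates = [(s.chrom, s.pos) for s in survivors]
        if candidates:
            discordant = dominance_consistency(matrix, candidates)
            manifest["stages"]["dominance"] = {
                "n_candidates": len(candidates),
                "n_discordant": len(discordant),
            }
            freq = genotype_frequencies(matrix, candidates)
            freq.to_csv(outdir / "genotype_frequencies.tsv", sep="\t",
                        index=False)

        if truth is not None and config.simulate:
            stage = "truth scoring"
            expected = truth.expected_funnel_survivors(config.funnel.impacts)
            got = {(s.chrom, s.pos) for s in survivors}
            tp = len(expected & got)
            manifest["stages"]["truth"] = {
                "funnel_precision": tp / len(got) if got else float("nan"),
                "funnel_recall": tp / len(expected) if expected else
                float("nan"),
            }
            stage = "imputation error"
            sim_cfg2 = SimConfig(seed=config.seed, **config.sim_overrides)
            if sim_cfg2.imputation_error_rate > 0:
                report2 = imputation_error(sim.imputed, sim.matrix)
                report2.per_snp.to_csv(outdir / "imputation_error.tsv",
                                       sep="\t", index=False)
                manifest["stages"]["imputation"] = {
                    "mean_error": report2.mean_error,
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return outdir
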