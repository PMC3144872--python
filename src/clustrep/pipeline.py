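"""End-to-end orchestration of the two-sample region-replication analysis.

Stages: per-sample association p-values (precomputed, allele-count
chi-square, or pool t-test) -> marker QC -> nominal selection -> cluster
scan -> cross-sample overlap -> Monte Carlo clustering and overlap nulls
-> gene annotation -> report bundle. Re-running with an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as cio
from .annotate import build_annotation_index, annotate_region
from .association import filter_snps
from .montecarlo import SnpMap, mc_clustering_null, mc_overlap_null
from .overlap import overlap_regions, summarize_overlap
from .scan import AUTOSOMES, ScanParams, find_clusters, genome_fraction, select_nominal

logger = logging.getLogger(__name__)

__all__ = ["SampleInput", "PipelineConfig", "SampleSummary", "run_pipeline"]

TEST_TYPES = ("precomputed_p", "chi2", "pool_t")


@dataclass(frozen=True)
class SampleInput:
    """One sample's association input and QC settings."""

    label: str
    path: str
    test_type: str = "precomputed_p"
    maf_min: float = 0.01
    missing_max: float = 0.05

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"test_type must be one of {TEST_TYPES}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline settings (mirrors the CLI/YAML surface)."""

    sample_a: SampleInput
    sample_b: SampleInput
    chrom_sizes_path: str
    out_dir: str
    scan: ScanParams = field(default_factory=ScanParams)
    gene_models_path: Optional[str] = None
    flank: int = 10_000
    gene_body_mode: bool = False
    n_trials: int = 1000
    seed: int = 0
    autosomes_only: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scan = ScanParams(**raw.pop("scan", {}))
        sample_a = SampleInput(**raw.pop("sample_a"))
        sample_b = SampleInput(**raw.pop("sample_b"))
        return cls(sample_a=sample_a, sample_b=sample_b, scan=scan, **raw)


@dataclass(frozen=True)
class SampleSummary:
    """Counts mirrored in the run log for line-by-line comparison."""

    label: str
    n_snps_assayed: int
    n_nominally_positive: int
    n_clusters: int
    genome_fraction: float


def _load_sample_records(sample: SampleInput):
    if sample.test_type == "precomputed_p":
        return cio.read_assoc_table(sample.path)
    if sample.test_type == "chi2":
        import numpy as np

        from .association import SnpRecord, chi2_allelic_arrays

        df = cio.read_genotype_count_table(sample.path)
        stat, p = chi2_allelic_arrays(
            df["CASE_MINOR"].to_numpy(),
            df["CASE_MAJOR"].to_numpy(),
            df["CTRL_MINOR"].to_numpy(),
            df["CTRL_MAJOR"].to_numpy(),
        )
        minor = df["CASE_MINOR"].to_numpy() + df["CTRL_MINOR"].to_numpy()
        total = minor + df["CASE_MAJOR"].to_numpy() + df["CTRL_MAJOR"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.minimum(minor / total, 1 - minor / total)
        records = []
        n_degenerate = 0
        for i, row in enumerate(df.itertuples(index=False)):
            if not np.isfinite(p[i]):
                n_degenerate += 1  # monomorphic: skipped, logged below
                continue
            records.append(
                SnpRecord(
                    chromosome=str(row.CHR),
                    position=int(row.BP),
                    snp_id=str(row.SNP),
                    p_value=float(p[i]),
                    maf=float(maf[i]),
                )
            )
        if n_degenerate:
            logger.warning(
                "%s: skipped %d monomorphic SNPs (degenerate tables)",
                sample.label,
                n_degenerate,
            )
        return records
    df, case_cols, ctrl_cols = cio.read_pool_table(sample.path)
    return cio.pool_table_to_records(df, case_cols, ctrl_cols)


def _analyze_sample(sample: SampleInput, config: PipelineConfig, chrom_sizes):
    records = _load_sample_records(sample)
    retained, exclusions = filter_snps(
        records, maf_min=sample.maf_min, missing_max=sample.missing_max
    )
    if config.autosomes_only:
        retained = [r for r in retained if r.chromosome in AUTOSOMES]
    nominal = select_nominal(retained, config.scan.alpha)
    regions = find_clusters(nominal, config.scan)
    snp_map = SnpMap.from_records(retained, n_positive=len(nominal))
    summary = SampleSummary(
        label=sample.label,
        n_snps_assayed=len(retained),
        n_nominally_positive=len(nominal),
        n_clusters=len(regions),
        genome_fraction=genome_fraction(regions, chrom_sizes),
    )
    return records, retained, exclusions, nominal, regions, snp_map, summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write the report bundle; return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = cio.read_chrom_sizes(config.chrom_sizes_path)
    if config.autosomes_only:
        chrom_sizes = {c: s for c, s in chrom_sizes.items() if c in AUTOSOMES}

    results = {}
    per_sample = {}
    for sample in (config.sample_a, config.sample_b):
        (records, retained, exclusions, nominal, regions, snp_map, summary) = _analyze_sample(
            sample, config, chrom_sizes
        )
        per_sample[sample.label] = (regions, snp_map, summary)
        cio.write_region_table(regions, out / f"regions_{sample.label}.tsv")
        cio.write_regions_bed(regions, out / f"regions_{sample.label}.bed")
        with open(out / f"exclusions_{sample.label}.tsv", "w") as fh:
            fh.write("snp_id\treason\n")
            for ex in exclusions:
                fh.write(f"{ex.snp_id}\t{ex.reason}\n")
        results[sample.label] = summary

    (label_a, (regions_a, map_a, sum_a)) = list(per_sample.items())[0]
    (label_b, (regions_b, map_b, sum_b)) = list(per_sample.items())[1]

    overlaps = overlap_regions(regions_a, regions_b)
    ov_summary = summarize_overlap(regions_a, regions_b, chrom_sizes)

    if config.gene_models_path:
        genes = cio.read_gene_models(config.gene_models_path)
        index = build_annotation_index(
            genes, flank=config.flank, gene_body_mode=config.gene_body_mode
        )
        for ov in overlaps:
            annotate_region(ov, index)
        gene_union = sorted(set().union(*(ov.genes for ov in overlaps)) if overlaps else set())
        with open(out / "genes.txt", "w") as fh:
            fh.write("\n".join(gene_union) + ("\n" if gene_union else ""))
    cio.write_overlap_table(overlaps, out / "overlap_regions.tsv")
    cio.write_overlaps_bed(overlaps, out / "overlap_regions.bed")

    mc_results = {}
    for label, (regions, snp_map, summary) in per_sample.items():
        mc = mc_clustering_null(
            snp_map,
            config.scan,
            observed_stat=summary.n_clusters,
            n_trials=config.n_trials,
            seed=config.seed,
        )
        mc_results[f"clustering_{label}"] = mc.to_dict()
        with open(out / f"mc_clustering_{label}.json", "w") as fh:
            fh.write(mc.to_json(indent=1))
    mc_ov = mc_overlap_null(
        map_a,
        map_b,
        config.scan,
        observed_stat=ov_summary.n_overlap_regions,
        n_trials=config.n_trials,
        seed=config.seed,
    )
    mc_results["overlap"] = mc_ov.to_dict()
    with open(out / "mc_overlap.json", "w") as fh:
        fh.write(mc_ov.to_json(indent=1))

    report = {
        "samples": {
            label: {
                "n_snps_assayed": s.n_snps_assayed,
                "n_nominally_positive": s.n_nominally_positive,
                "n_clusters": s.n_clusters,
                "genome_fraction": s.genome_fraction,
            }
            for label, (_, _, s) in per_sample.items()
        },
        "overlap": {
            "n_overlap_regions": ov_summary.n_overlap_regions,
            "n_pairs": ov_summary.n_pairs,
            "fraction_a": ov_summary.fraction_a,
            "fraction_b": ov_summary.fraction_b,
            "fraction_overlap": ov_summary.fraction_overlap,
            "enrichment_ratio_pct": ov_summary.enrichment_ratio,
        },
        "monte_carlo": mc_results,
        "params": {
            "alpha": config.scan.alpha,
            "min_cluster_size": config.scan.min_cluster_size,
            "max_gap": config.scan.max_gap,
            "flank": config.flank,
            "gene_body_mode": config.gene_body_mode,
            "n_trials": config.n_trials,
            "seed": config.seed,
            "autosomes_only": config.autosomes_only,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
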