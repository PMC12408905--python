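"""End-to-end orchestration of the two-library comparison.

``run_pipeline`` executes the whole workflow on a configuration object:
simulate the labeled genome and cohort, build the two sequencing
libraries and depth-match them, compute coverage summaries and the
windowed depth-difference outlier table, derive the two observed
genotype matrices and the concordance / AF / PCA battery, and run the
GWAS and cis-eQTL agreement analyses.  Every output is written as TSV or
JSON, stamped with the configuration hash and master seed, and all
randomness derives from ``seed`` through stable per-stage labels, so
inserting a stage never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    assoc_compare,
    coverage_metrics,
    library_sim,
    synthetic_data,
    variant_compare,
    window_outliers,
)
from .coverage_model import LibraryKind

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("cfcomp")


def stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage label XOR master."""
    return (zlib.crc32(label.encode("utf-8")) ^ int(master)) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the full comparison workflow."""

    # genome
    genome_length: int = 2_000_000
    regions: list = field(
        default_factory=lambda: [
            [900_000, 1_000_000, "centromere"],
            [1_000_000, 1_060_000, "difficult"],
            [1_500_000, 1_520_000, "gap"],
        ]
    )
    retention_bias: dict = field(
        default_factory=lambda: {
            "centromere": {"short_insert": 0.05, "long_insert": 0.30},
            "difficult": {"short_insert": 0.60, "long_insert": 0.85},
            "gap": {"short_insert": 0.0, "long_insert": 0.0},
        }
    )
    # libraries
    target_raw_depth: float = 46.73
    read_length: int = 100
    short_dup_lambda: float = 0.229
    long_dup_lambda: float = 0.0115
    short_insert_mean: float = 170.0
    short_insert_sd: float = 15.0
    long_insert_mean: float = 350.0
    long_insert_sd: float = 60.0
    # cohort
    n_individuals: int = 200
    n_variants: int = 3000
    ancestry_groups: int = 2
    # genotype observation noise per library kind
    obs_error_rate: float = 0.01
    obs_missing_rate: float = 0.01
    obs_dropout_short: dict = field(
        default_factory=lambda: {"normal": 0.02, "difficult": 0.10, "centromere": 0.15, "gap": 0.5}
    )
    obs_dropout_long: dict = field(
        default_factory=lambda: {"normal": 0.01, "difficult": 0.05, "centromere": 0.08, "gap": 0.5}
    )
    # analysis thresholds
    window_size: int = 10_000
    sd_multiplier: float = 3.0
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    miss_max: float = 0.10
    cis_window: int = 1_000_000
    eqtl_maf_min: float = 0.01
    n_perm: int = 1000
    fdr: float = 0.05
    # phenotypes / expression
    n_phenotypes: int = 1
    n_causal: int = 5
    causal_beta: float = 0.5
    heritability: float = 0.3
    n_genes: int = 40
    # bookkeeping
    seed: int = 0
    outdir: str = "cfcomp_out"

    def validate(self) -> None:
        if self.target_raw_depth <= 0 or self.window_size < 1:
            raise ValueError("invalid depth/window configuration")
        for v, lo, hi in [
            (self.maf_min, 0, 0.5),
            (self.miss_max, 0, 1),
            (self.fdr, 0, 1),
            (self.heritability, 0, 1),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"threshold {v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def library_models(self):
        short = dataclasses.replace(
            library_sim.short_insert_library(self.short_dup_lambda, self.read_length),
            mean_insert=self.short_insert_mean,
            sd_insert=self.short_insert_sd,
        )
        long = dataclasses.replace(
            library_sim.long_insert_library(self.long_dup_lambda, self.read_length),
            mean_insert=self.long_insert_mean,
            sd_insert=self.long_insert_sd,
        )
        return short, long

    def observation_model(self) -> "synthetic_data.ObservationModel":
        return synthetic_data.ObservationModel(
            short=synthetic_data.KindObservation(
                self.obs_error_rate, self.obs_missing_rate, dict(self.obs_dropout_short)
            ),
            long=synthetic_data.KindObservation(
                self.obs_error_rate, self.obs_missing_rate, dict(self.obs_dropout_long)
            ),
        )


def _stamp(config: PipelineConfig) -> str:
    return f"# cfcomp config={config.digest()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj: dict, path: Path, config: PipelineConfig) -> None:
    payload = {"_config": config.digest(), "_seed": config.seed, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in workflow order and write the report bundle.

    Returns a dict of the in-memory results keyed by stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "config"
    t0 = time.time()
    try:
        config.to_yaml(outdir / "config.yaml")

        stage = "simulate_genome"
        log.info("stage %s", stage)
        genome = synthetic_data.generate_genome(
            config.genome_length,
            [tuple(r) for r in config.regions],
            bias=config.retention_bias,
        )
        synthetic_data.write_bed(genome, outdir / "regions.bed")
        results["genome"] = genome

        stage = "simulate_libraries"
        log.info("stage %s", stage)
        short_lib, long_lib = config.library_models()
        track_s, track_l, depth_log = library_sim.matched_depth_tracks(
            genome, short_lib, long_lib, config.target_raw_depth,
            seed=stage_seed(config.seed, "libraries"),
        )
        results["depth_log"] = depth_log
        _write_json({"depth_matching": depth_log}, outdir / "depth_matching.json", config)

        stage = "coverage"
        log.info("stage %s", stage)
        cov_s = coverage_metrics.coverage_at(track_s)
        cov_l = coverage_metrics.coverage_at(track_l)
        cross = coverage_metrics.crossover_compare(cov_s, cov_l)
        cov_table = pd.DataFrame(
            {
                "threshold": cov_s.thresholds,
                "fraction_short": cov_s.fractions,
                "fraction_long": cov_l.fractions,
                "difference": cross.differences,
            }
        )
        _write_tsv(cov_table, outdir / "coverage_summary.tsv", config)
        results["coverage"] = {"short": cov_s, "long": cov_l, "crossover": cross}

        stage = "window_outliers"
        log.info("stage %s", stage)
        wm_s = coverage_metrics.window_means(track_s, config.window_size)
        wm_l = coverage_metrics.window_means(track_l, config.window_size)
        coverage_metrics.write_window_means(wm_s, outdir / "window_means_short.tsv")
        coverage_metrics.write_window_means(wm_l, outdir / "window_means_long.tsv")
        table = window_outliers.flag_outliers(
            window_outliers.window_diff(wm_s, wm_l), sd_multiplier=config.sd_multiplier
        )
        regions_df = synthetic_data.read_bed(outdir / "regions.bed")
        annotated, summary = window_outliers.annotate(table, regions_df)
        _write_tsv(annotated, outdir / "window_outliers.tsv", config)
        _write_json(json.loads(summary.to_json()), outdir / "window_label_summary.json", config)
        results["windows"] = {"table": annotated, "summary": summary}

        stage = "simulate_cohort"
        log.info("stage %s", stage)
        truth = synthetic_data.generate_cohort(
            config.n_individuals,
            config.n_variants,
            ancestry_groups=config.ancestry_groups,
            seed=stage_seed(config.seed, "cohort"),
            genome=genome,
        )
        obs_model = config.observation_model()
        g_short = synthetic_data.observe_genotypes(
            truth, obs_model, genome, LibraryKind.SHORT_INSERT,
            seed=stage_seed(config.seed, "observe_short"),
        )
        g_long = synthetic_data.observe_genotypes(
            truth, obs_model, genome, LibraryKind.LONG_INSERT,
            seed=stage_seed(config.seed, "observe_long"),
        )
        synthetic_data.write_vcf(g_short, outdir / "short_insert.vcf", genome.length)
        synthetic_data.write_vcf(g_long, outdir / "long_insert.vcf", genome.length)
        results["truth"], results["g_short"], results["g_long"] = truth, g_short, g_long

        stage = "variant_compare"
        log.info("stage %s", stage)
        overlap = variant_compare.overlap_counts(g_short, g_long)
        _write_tsv(overlap.reset_index(names="metric"), outdir / "overlap_table.tsv", config)
        conc = variant_compare.concordance(g_short, g_long)
        bins = variant_compare.maf_bin_r2(g_short, g_long)
        pca = variant_compare.pca_compare(g_short, g_long)
        genotype_report = {
            "titv_short": variant_compare.titv(g_short),
            "titv_long": variant_compare.titv(g_long),
            "het_hom_mean_short": float(variant_compare.het_hom(g_short).mean()),
            "het_hom_mean_long": float(variant_compare.het_hom(g_long).mean()),
            "af_spectrum_r2": variant_compare.af_spectrum_r2(g_short, g_long),
            "concordance_mean": conc.mean,
            "concordance_min": conc.min,
            "concordance_max": conc.max,
            "maf_bin_mean_r2": bins.overall_mean,
            "pca_relative_displacement": pca.relative_displacement,
        }
        _write_json(genotype_report, outdir / "genotype_report.json", config)
        _write_tsv(bins.table, outdir / "maf_bin_r2.tsv", config)
        results["genotype_report"] = genotype_report
        results["concordance"] = conc

        stage = "gwas"
        log.info("stage %s", stage)
        causal = np.linspace(0, config.n_variants - 1, config.n_causal).astype(int)
        phenos = synthetic_data.generate_phenotypes(
            truth, causal, [config.causal_beta] * config.n_causal,
            config.heritability, config.n_phenotypes,
            seed=stage_seed(config.seed, "phenotypes"),
        )
        covs = synthetic_data.generate_covariates(
            config.n_individuals, truth.samples, seed=stage_seed(config.seed, "covariates")
        )
        phenos.to_csv(outdir / "phenotypes.tsv", sep="\t")
        covs.to_csv(outdir / "covariates.tsv", sep="\t")
        qs, _ = assoc_compare.qc_filter(g_short, config.maf_min, config.hwe_p_min, config.miss_max)
        ql, _ = assoc_compare.qc_filter(g_long, config.maf_min, config.hwe_p_min, config.miss_max)
        res_s = assoc_compare.gwas_linear(qs, phenos.iloc[:, 0], covs)
        res_l = assoc_compare.gwas_linear(ql, phenos.iloc[:, 0], covs)
        gw_agree = assoc_compare.agreement(res_s, res_l)
        _write_tsv(res_s.table, outdir / "gwas_short.tsv", config)
        _write_tsv(res_l.table, outdir / "gwas_long.tsv", config)
        _write_tsv(gw_agree.mirrored, outdir / "gwas_mirrored.tsv", config)
        _write_json(
            {
                "n_overlap": gw_agree.n_overlap,
                "n_a_unique": gw_agree.n_a_unique,
                "n_b_unique": gw_agree.n_b_unique,
                "r2_neglog10_p": gw_agree.r2_neglog10_p,
                "r2_beta": gw_agree.r2_beta,
            },
            outdir / "gwas_agreement.json",
            config,
        )
        results["gwas"] = {"short": res_s, "long": res_l, "agreement": gw_agree}

        stage = "eqtl"
        log.info("stage %s", stage)
        expression, gene_ann = synthetic_data.generate_expression(
            truth,
            synthetic_data.CisConfig(window=config.cis_window),
            config.n_genes,
            seed=stage_seed(config.seed, "expression"),
            genome_length=genome.length,
        )
        expression.to_csv(outdir / "expression.tsv", sep="\t")
        gene_ann.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)
        eq_s = assoc_compare.cis_eqtl(
            g_short, expression, gene_ann,
            window=config.cis_window, maf_min=config.eqtl_maf_min,
            n_perm=config.n_perm, fdr=config.fdr, covariates=covs,
            seed=stage_seed(config.seed, "eqtl_perm"),
        )
        eq_l = assoc_compare.cis_eqtl(
            g_long, expression, gene_ann,
            window=config.cis_window, maf_min=config.eqtl_maf_min,
            n_perm=config.n_perm, fdr=config.fdr, covariates=covs,
            seed=stage_seed(config.seed, "eqtl_perm"),
        )
        eq_agree = assoc_compare.agreement(eq_s, eq_l)
        _write_tsv(eq_s.genes, outdir / "eqtl_genes_short.tsv", config)
        _write_tsv(eq_l.genes, outdir / "eqtl_genes_long.tsv", config)
        _write_json(
            {
                "n_overlap": eq_agree.n_overlap,
                "r2_neglog10_p": eq_agree.r2_neglog10_p,
                "r2_beta": eq_agree.r2_beta,
                "n_egenes_short": int(eq_s.genes["significant"].sum()),
                "n_egenes_long": int(eq_l.genes["significant"].sum()),
            },
            outdir / "eqtl_agreement.json",
            config,
        )
        results["eqtl"] = {"short": eq_s, "long": eq_l, "agreement": eq_agree}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"pipeline stage '{stage}' failed: {exc}") from exc
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results
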