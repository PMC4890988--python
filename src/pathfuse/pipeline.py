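"""End-to-end orchestration of the three parallel pathway analyses.

Part I scores genes from the case-control genotypes (QC -> trend test ->
window mapping -> tagSNP selection -> min-p). Part II scores genes from the
expression matrix (optional probe collapse -> t-test). Part III combines the
two per gene with Fisher's method and runs the pathway permutation test in
all three modes (gwas / expression / integrated), ending in a significant-set
comparison.

Every run writes its resolved configuration next to the outputs and logs one
machine-parsable ``STAGE`` line per stage with the counts that matter.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

from .datatypes import ComparisonReport, QCThresholds
from .errors import PathfuseError, PipelineStageError
from . import expression as expr_mod
from . import genotypes as geno_mod
from . import integrate as int_mod
from . import io as pio
from . import pathways as path_mod

log = logging.getLogger("pathfuse")

MODES = ("gwas", "expression", "integrated")


@dataclass
class PipelineConfig:
    """All inputs, outputs and parameters of a full run.

    Defaults follow the published analysis settings: 50 kb mapping window,
    tagging at r² > 0.8, MAF ≥ 0.01, HWE p ≥ 0.001, genotype percent ≥ 0.25,
    pathways of 5-200 genes, 100,000 permutations, q < 0.05.
    """

    ped: str = ""
    map: str = ""
    panel: str = ""
    bed: str = ""
    expr: str = ""
    groups: str = ""
    gmt: str = ""
    outdir: str = "pathfuse_out"
    probe_map: str = ""  # optional probe -> gene TSV; empty = gene-level input

    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    call_rate_min: float = 0.25
    hwe_in: str = "controls"
    hwe_method: str = "chisq"
    window_bp: int = 50_000
    r2_threshold: float = 0.8
    min_pathway_genes: int = 5
    max_pathway_genes: int = 200
    n_perm: int = 100_000
    q_threshold: float = 0.05
    seed: int = 0
    tie_rule: str = "strict"
    fdr_method: str = "bh"
    ttest_variant: str = "student"
    collapse_rule: str = "median"
    n_workers: int = 1
    modes: tuple[str, ...] = MODES

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        return cls.from_dict(pio.read_yaml(path))

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
            call_rate_min=self.call_rate_min,
        )


def _stage(name: str, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("STAGE %s %s", name, kv)


def gwas_gene_scores(config: PipelineConfig):
    """Part I: genotype file pair + panel + annotation -> per-gene GWAS p."""
    try:
        dataset = pio.read_genotypes_plink_text(config.ped, config.map)
        _stage("read_genotypes", samples=dataset.n_samples, snps=dataset.n_snps)
        filtered, report = geno_mod.snp_qc(
            dataset,
            config.qc_thresholds(),
            hwe_in=config.hwe_in,
            hwe_method=config.hwe_method,
        )
        _stage("snp_qc", snps_in=report.n_input, snps_passed=report.n_passed)
        snp_stats = geno_mod.trend_test_all(filtered)
        annotation = pio.read_annotation_bed(config.bed)
        assignment = geno_mod.map_snps_to_genes(
            filtered.snps, annotation, window_bp=config.window_bp
        )
        _stage(
            "map_snps",
            pairs=len(assignment.pairs),
            genes_with_snps=assignment.pairs["gene_id"].nunique(),
            unmapped=len(assignment.unmapped),
        )
        panel = pio.read_panel(config.panel, study_snp_ids=filtered.snps["snp_id"].tolist())
        tagsets = geno_mod.select_tag_snps_all(
            assignment, panel, filtered.snps, r2_threshold=config.r2_threshold
        )
        # only tags with a defined trend p can contribute
        ok = snp_stats.dropna(subset=["p"])
        scores = geno_mod.gene_wise_association(assignment, ok, _prune(tagsets, ok))
        _stage("gwas_gene_scores", genes=len(scores))
        return scores
    except (PathfuseError, OSError) as exc:
        raise PipelineStageError("gwas_gene_scores", exc) from exc


def _prune(tagsets, snp_stats):
    """Drop tags lacking a defined p (degenerate trend); keep genes with >=1 tag."""
    have = set(snp_stats["snp_id"])
    out = {}
    for gid, ts in tagsets.items():
        kept = [t for t in ts.tags if t in have]
        if kept:
            ts.tags = kept
            out[gid] = ts
    return out


def expression_gene_scores(config: PipelineConfig):
    """Part II: expression matrix + groups -> per-gene DE p."""
    try:
        level = "probe" if config.probe_map else "gene"
        dataset = pio.read_expression(config.expr, config.groups, level=level)
        _stage(
            "read_expression",
            features=len(dataset.values),
            samples=dataset.values.shape[1],
        )
        if config.probe_map:
            import pandas as pd

            pmap = pd.read_csv(config.probe_map, sep="\t", index_col=0).iloc[:, 0]
            dataset = expr_mod.collapse_probes_to_genes(
                dataset, pmap, rule=config.collapse_rule
            )
            _stage("collapse_probes", genes=len(dataset.values))
        scores = expr_mod.differential_expression_ttest(
            dataset, variant=config.ttest_variant
        )
        _stage("expr_gene_scores", genes=len(scores))
        return scores
    except (PathfuseError, OSError) as exc:
        raise PipelineStageError("expression_gene_scores", exc) from exc


def run_full_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Run parts I-III and the three-mode comparison; write all artifacts."""
    os.makedirs(config.outdir, exist_ok=True)
    pio.write_yaml(config.to_dict(), os.path.join(config.outdir, "resolved_config.yaml"))

    gwas = gwas_gene_scores(config)
    expr = expression_gene_scores(config)

    try:
        table = int_mod.build_integrated_scores(gwas, expr)
        _stage("integrate", intersection=int_mod.intersection_size(table))
        pio.write_gene_scores(table, os.path.join(config.outdir, "gene_scores.tsv"))
    except (PathfuseError, OSError) as exc:
        raise PipelineStageError("integrate", exc) from exc

    try:
        pathways = pio.read_gmt(config.gmt)
        _stage("read_pathways", pathways=len(pathways))
        results = {}
        for mode in config.modes:
            res = path_mod.run_pathway_analysis(
                table,
                pathways,
                mode=mode,
                n_perm=config.n_perm,
                seed=config.seed,
                min_genes=config.min_pathway_genes,
                max_genes=config.max_pathway_genes,
                q_threshold=config.q_threshold,
                tie_rule=config.tie_rule,
                fdr_method=config.fdr_method,
                n_workers=config.n_workers,
            )
            results[mode] = res
            pio.write_results(res, os.path.join(config.outdir, f"results_{mode}.tsv"))
            _stage(
                f"pathway_test_{mode}",
                tested=len(res),
                significant=int(res["significant"].sum()),
            )
    except (PathfuseError, OSError) as exc:
        raise PipelineStageError("pathway_test", exc) from exc

    if not all(m in results for m in MODES):
        return None  # partial run: nothing to compare

    try:
        report = path_mod.compare_modes(
            results["gwas"],
            results["expression"],
            results["integrated"],
            q_threshold=config.q_threshold,
        )
        payload = {
            "counts": report.counts(),
            "significant": {m: sorted(s) for m, s in report.significant.items()},
            "integrated_only": sorted(report.integrated_only),
            "shared_gwas_expression": sorted(report.shared_gwas_expression),
        }
        with open(os.path.join(config.outdir, "comparison.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        _stage("compare_modes", **report.counts())
        return report
    except (PathfuseError, OSError) as exc:
        raise PipelineStageError("compare_modes", exc) from exc
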