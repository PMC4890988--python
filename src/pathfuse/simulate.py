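"""Synthetic cohort generator with planted, recoverable signal.

Emulates the study design the pipeline targets — a case-control GWAS arm, a
small two-group expression arm, and a pathway collection — at desk scale,
with known ground truth for recovery testing:

* Genotypes: per gene, an LD block whose MAF is drawn from ``maf_range`` and
  whose haplotypes descend from a founder allele via a copying process, so
  every within-gene SNP pair has allele correlation ``ld_block_rho`` (panel
  r^2 = ld_block_rho^2). Disease status
  follows a logistic model with per-allele log-odds ln(``genotype_odds_ratio``)
  at one causal SNP per causal gene; cases and controls are sampled
  retrospectively (by status) from a generated pool, matching the
  case-control design. An independent haplotype panel from the same process
  stands in for the external LD reference.
* Expression: gene x sample matrix of baseline + Gaussian noise; DE genes are
  shifted in cases by ``de_effect_size`` standard deviations. By default 70%
  of DE genes are also causal genes, so integration sees joint signal.
* Pathways: gene sets with sizes in ``pathway_size_range``; enriched pathways
  draw ``enrichment_fraction`` of their members from the planted
  (causal ∪ DE) genes.

Everything is driven by one integer seed; a fixed config reproduces the
bundle byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    GenotypeDataset,
    GeneAnnotation,
    GroundTruth,
    Pathway,
    PathwayCollection,
    ExpressionDataset,
    ReferencePanel,
)
from .errors import ConfigurationError

# stage constants for independent RNG substreams
_S_ANNOT, _S_GENO, _S_EXPR, _S_PATH = 11, 13, 17, 19


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions.

    The genotype arm defaults to 500 cases / 500 controls over 500 genes (a
    reduced analogue of a large case-control GWAS); the expression arm
    defaults to 33 cases vs 20 controls, the design of the pooled arthritis
    microarray series the pipeline emulates.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 500
    snps_per_gene: tuple[int, int] = (3, 8)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_rho: float = 0.8
    causal_gene_fraction: float = 0.1
    genotype_odds_ratio: float = 1.5
    de_gene_fraction: float = 0.1
    de_effect_size: float = 1.5
    de_causal_overlap: float = 0.7
    expr_noise_sd: float = 1.0
    n_expr_cases: int = 33
    n_expr_controls: int = 20
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (20, 80)
    n_enriched_pathways: int = 5
    enrichment_fraction: float = 0.5
    missing_rate: float = 0.01
    n_panel: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("counts must be positive")
        for name in (
            "causal_gene_fraction",
            "de_gene_fraction",
            "de_causal_overlap",
            "enrichment_fraction",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be inside (0, 0.5]")
        if not 0.0 <= self.ld_block_rho < 1.0:
            raise ConfigurationError("ld_block_rho must be in [0,1)")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ConfigurationError("snps_per_gene range is empty")
        if self.pathway_size_range[0] < 1 or (
            self.pathway_size_range[0] > self.pathway_size_range[1]
        ):
            raise ConfigurationError("pathway_size_range is empty")
        if self.genotype_odds_ratio < 1.0:
            raise ConfigurationError("genotype_odds_ratio must be >= 1")
        if self.expr_noise_sd <= 0:
            raise ConfigurationError("expr_noise_sd must be positive")
        if self.n_enriched_pathways > self.n_pathways:
            raise ConfigurationError("more enriched pathways than pathways")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SimulatedBundle:
    """Everything one simulated study comprises."""

    config: SimulationConfig
    annotation: GeneAnnotation
    genotypes: GenotypeDataset
    panel: ReferencePanel
    expression: ExpressionDataset
    pathways: PathwayCollection
    truth: GroundTruth


def generate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Non-overlapping 1-based gene intervals over a handful of chromosomes.

    Inter-gene gaps alternate between short (< 100 kb, so the ±50 kb mapping
    windows of neighbours overlap) and long (> 100 kb, so they do not); both
    regimes are present once there are ten or more genes.
    """
    config.validate()
    rng = config.rng(_S_ANNOT)
    n_chrom = min(5, config.n_genes)
    per_chrom = np.array_split(np.arange(config.n_genes), n_chrom)
    rows = []
    for ci, idx in enumerate(per_chrom, start=1):
        pos = 1 + int(rng.integers(0, 10_000))
        for k, gi in enumerate(idx):
            length = int(rng.integers(2_000, 50_000))
            start = pos
            end = start + length - 1
            rows.append(
                {
                    "gene_id": f"G{gi + 1:04d}",
                    "chrom": str(ci),
                    "start": start,
                    "end": end,
                }
            )
            # alternate window-overlapping and well-separated neighbours
            gap = int(rng.integers(10_000, 80_000)) if k % 2 == 0 else int(
                rng.integers(120_000, 300_000)
            )
            pos = end + 1 + gap
    return GeneAnnotation(table=pd.DataFrame(rows))


def _gene_haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """Founder-copying haplotypes: exact pairwise allele correlation rho.

    Every SNP of the gene shares the gene's minor-allele frequency p. Each
    haplotype carries a founder allele ~ Bernoulli(p); each SNP copies the
    founder state with probability sqrt(rho) and otherwise draws an
    independent Bernoulli(p). The marginal stays Bernoulli(p), and any SNP
    pair correlates through the founder with corr = sqrt(rho)^2 = rho, so the
    within-gene haplotype r^2 is rho^2 for every pair — one parameter tunes
    the whole block's LD.
    """
    m = len(mafs)
    p = float(mafs[0])
    founder = (rng.random(n_hap) < p).astype(np.int8)
    copy = rng.random((n_hap, m)) < np.sqrt(rho)
    noise = (rng.random((n_hap, m)) < p).astype(np.int8)
    return np.where(copy, founder[:, None], noise).astype(np.int8)


def simulate_genotypes(
    config: SimulationConfig, annotation: GeneAnnotation
) -> tuple[GenotypeDataset, ReferencePanel, GroundTruth]:
    """Case-control genotypes, an independent LD panel, and the causal truth."""
    config.validate()
    rng = config.rng(_S_GENO)
    genes = annotation.table
    n_causal = int(round(config.causal_gene_fraction * len(genes)))
    if config.genotype_odds_ratio <= 1.0:
        causal_genes: list[str] = []
    else:
        causal_genes = sorted(
            rng.choice(genes["gene_id"].to_numpy(), size=n_causal, replace=False)
        )
    causal_set = set(causal_genes)

    snp_rows = []
    mafs_all = []
    causal_snp_ids: set[str] = set()
    causal_cols: list[int] = []
    per_gene_cols: list[tuple[int, int]] = []
    col = 0
    for _, grow in genes.iterrows():
        m = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        # one MAF per gene, shared by its SNPs (an LD block of common descent)
        mafs = np.repeat(rng.uniform(config.maf_range[0], config.maf_range[1]), m)
        span = max(grow["end"] - grow["start"], m)
        offsets = np.sort(rng.choice(span, size=m, replace=False))
        for j in range(m):
            sid = f"rs{col + j + 1:06d}"
            snp_rows.append(
                {
                    "snp_id": sid,
                    "chrom": grow["chrom"],
                    "pos": int(grow["start"] + offsets[j]),
                    "allele_minor": "A",
                    "allele_major": "G",
                }
            )
        if grow["gene_id"] in causal_set:
            j_causal = m // 2
            causal_cols.append(col + j_causal)
            causal_snp_ids.add(snp_rows[col + j_causal]["snp_id"])
        mafs_all.append(mafs)
        per_gene_cols.append((col, col + m))
        col += m
    snps = pd.DataFrame(snp_rows)
    n_snps = col

    def draw_genotypes(n_ind: int, gen: np.random.Generator) -> np.ndarray:
        out = np.empty((2 * n_ind, n_snps), dtype=np.int8)
        for (a, b), mafs in zip(per_gene_cols, mafs_all):
            out[:, a:b] = _gene_haplotypes(gen, 2 * n_ind, mafs, config.ld_block_rho)
        return out[0::2] + out[1::2]

    # retrospective sampling: draw pools until both strata are filled
    beta = np.log(config.genotype_odds_ratio)
    need_cases, need_controls = config.n_cases, config.n_controls
    cases, controls = [], []
    batch = max(2 * (need_cases + need_controls), 200)
    guard = 0
    while (sum(len(c) for c in cases) < need_cases) or (
        sum(len(c) for c in controls) < need_controls
    ):
        guard += 1
        if guard > 50:
            raise ConfigurationError("case/control sampling failed to converge")
        geno = draw_genotypes(batch, rng)
        dose = geno[:, causal_cols].sum(axis=1) if causal_cols else np.zeros(batch)
        logit = beta * (dose - (dose.mean() if len(causal_cols) else 0.0))
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(batch) < p_case
        cases.append(geno[is_case])
        controls.append(geno[~is_case])
    case_mat = np.concatenate(cases)[:need_cases]
    control_mat = np.concatenate(controls)[:need_controls]
    calls = np.concatenate([case_mat, control_mat]).astype(np.int8)
    phenotypes = np.concatenate(
        [np.ones(need_cases, dtype=np.int8), np.zeros(need_controls, dtype=np.int8)]
    )
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = -1
    sample_ids = [f"S{i + 1:05d}" for i in range(need_cases + need_controls)]
    dataset = GenotypeDataset(
        sample_ids=sample_ids, phenotypes=phenotypes, snps=snps, calls=calls
    )

    panel_hap = np.empty((2 * config.n_panel, n_snps), dtype=np.int8)
    for (a, b), mafs in zip(per_gene_cols, mafs_all):
        panel_hap[:, a:b] = _gene_haplotypes(
            rng, 2 * config.n_panel, mafs, config.ld_block_rho
        )
    panel = ReferencePanel(
        snp_ids=snps["snp_id"].tolist(), haplotypes=panel_hap, phased=True
    )
    truth = GroundTruth(
        causal_snp_ids=causal_snp_ids, causal_gene_ids=set(causal_genes)
    )
    return dataset, panel, truth


def simulate_expression(
    config: SimulationConfig, annotation: GeneAnnotation, truth: GroundTruth
) -> tuple[ExpressionDataset, GroundTruth]:
    """Gene x sample matrix with planted differential expression.

    DE genes preferentially overlap the causal genes (``de_causal_overlap``
    of them are drawn from the causal set when possible).
    """
    config.validate()
    rng = config.rng(_S_EXPR)
    gene_ids = annotation.gene_ids
    n_de = int(round(config.de_gene_fraction * len(gene_ids)))
    if config.de_effect_size == 0:
        de_genes: list[str] = []
    else:
        causal = sorted(truth.causal_gene_ids)
        n_overlap = min(int(round(config.de_causal_overlap * n_de)), len(causal))
        from_causal = (
            list(rng.choice(causal, size=n_overlap, replace=False)) if n_overlap else []
        )
        others = sorted(set(gene_ids) - set(from_causal))
        n_rest = n_de - len(from_causal)
        from_rest = list(rng.choice(others, size=n_rest, replace=False))
        de_genes = sorted(from_causal + from_rest)
    de_set = set(de_genes)

    n_case, n_ctrl = config.n_expr_cases, config.n_expr_controls
    samples = [f"E{i + 1:03d}" for i in range(n_case + n_ctrl)]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_ctrl, index=samples, name="group"
    )
    baseline = rng.normal(8.0, 1.0, size=len(gene_ids))
    values = baseline[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(len(gene_ids), len(samples))
    )
    shift = config.de_effect_size * config.expr_noise_sd
    for i, g in enumerate(gene_ids):
        if g in de_set:
            values[i, :n_case] += shift
    expr = ExpressionDataset(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        groups=groups,
        level="gene",
    )
    truth.de_gene_ids = de_set
    return expr, truth


def generate_pathways(
    config: SimulationConfig, annotation: GeneAnnotation, truth: GroundTruth
) -> tuple[PathwayCollection, GroundTruth]:
    """Gene sets with planted enrichment in the causal/DE genes."""
    config.validate()
    if config.pathway_size_range[1] > config.n_genes:
        raise ConfigurationError(
            "requested pathway size exceeds the number of available genes"
        )
    rng = config.rng(_S_PATH)
    gene_ids = np.array(annotation.gene_ids)
    signal = sorted(truth.causal_gene_ids | truth.de_gene_ids)
    background = sorted(set(gene_ids) - set(signal))
    items: list[Pathway] = []
    enriched_ids: set[str] = set()
    lo, hi = config.pathway_size_range
    for k in range(config.n_pathways):
        pid = f"pw{k + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        enriched = k < config.n_enriched_pathways and config.enrichment_fraction > 0
        if enriched and signal:
            n_sig = min(int(round(config.enrichment_fraction * size)), len(signal))
            members = list(rng.choice(signal, size=n_sig, replace=False))
            pool = background if len(background) >= size - n_sig else sorted(
                set(gene_ids) - set(members)
            )
            members += list(rng.choice(pool, size=size - n_sig, replace=False))
            enriched_ids.add(pid)
        else:
            members = list(rng.choice(gene_ids, size=size, replace=False))
        items.append(
            Pathway(
                pathway_id=pid,
                name=f"synthetic pathway {k + 1}",
                genes=tuple(sorted(members)),
                function_class="enriched" if pid in enriched_ids else "background",
            )
        )
    truth.enriched_pathway_ids = enriched_ids
    return PathwayCollection.from_list(items), truth


def simulate_all(config: SimulationConfig) -> SimulatedBundle:
    """Run every generator stage and return the complete bundle."""
    annotation = generate_annotation(config)
    genotypes, panel, truth = simulate_genotypes(config, annotation)
    expression, truth = simulate_expression(config, annotation, truth)
    pathways, truth = generate_pathways(config, annotation, truth)
    return SimulatedBundle(
        config=config,
        annotation=annotation,
        genotypes=genotypes,
        panel=panel,
        expression=expression,
        pathways=pathways,
        truth=truth,
    )


def write_fixture_bundle(outdir: str, bundle: SimulatedBundle) -> list[str]:
    """Write the whole bundle as plain-text files; returns the manifest.

    Formats: PLINK text .ped/.map, phased VCF panel, BED annotation,
    expression and group TSVs, GMT pathways, truth TSV, and the config as
    YAML. Re-reading the bundle reproduces the in-memory objects.
    """
    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ped": os.path.join(outdir, "genotypes.ped"),
        "map": os.path.join(outdir, "genotypes.map"),
        "panel": os.path.join(outdir, "panel.vcf"),
        "bed": os.path.join(outdir, "genes.bed"),
        "expr": os.path.join(outdir, "expression.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "gmt": os.path.join(outdir, "pathways.gmt"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    pio.write_genotypes_plink_text(bundle.genotypes, paths["ped"], paths["map"])
    pio.write_panel_vcf(bundle.panel, bundle.genotypes.snps, paths["panel"])
    pio.write_annotation_bed(bundle.annotation, paths["bed"])
    pio.write_expression(bundle.expression, paths["expr"], paths["groups"])
    pio.write_gmt(bundle.pathways, paths["gmt"])
    pio.write_truth(bundle.truth, paths["truth"])
    pio.write_yaml(asdict(bundle.config), paths["config"])
    return sorted(paths.values())
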