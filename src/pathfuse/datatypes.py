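"""Core in-memory containers shared across the pipeline stages.

Tabular results (per-SNP statistics, per-gene scores, per-pathway results) are
plain :class:`pandas.DataFrame` objects with documented column sets; the
composite datasets below bundle the matrices with their metadata.

Genotype calls count minor-allele copies: 0/1/2, with -1 for missing.
Coordinates are 1-based inclusive throughout; BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # missing genotype code in call matrices

#: columns of the per-SNP metadata table
SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_minor", "allele_major"]


@dataclass
class GenotypeDataset:
    """Case-control genotypes: samples x SNPs minor-allele dosage matrix.

    ``phenotypes`` is an int array aligned with ``sample_ids``; 1 = case,
    0 = control. ``snps`` is a DataFrame with :data:`SNP_COLUMNS`.
    """

    sample_ids: list[str]
    phenotypes: np.ndarray
    snps: pd.DataFrame
    calls: np.ndarray  # shape (n_samples, n_snps), int8, -1 = missing

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        if not set(np.unique(self.phenotypes)) <= {0, 1}:
            raise ValueError("phenotypes must be binary 0/1")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        codes = np.unique(self.calls)
        if not set(codes.tolist()) <= {-1, 0, 1, 2}:
            raise ValueError("genotype codes restricted to {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        """Return a dataset restricted to the SNPs flagged in boolean ``keep``."""
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            phenotypes=self.phenotypes,
            snps=self.snps.loc[keep].reset_index(drop=True),
            calls=self.calls[:, np.asarray(keep, dtype=bool)],
        )


@dataclass
class ReferencePanel:
    """External haplotype (or genotype) panel used for LD estimation.

    Phased panels store one row per haplotype (2 per sample) of 0/1 minor
    allele indicators; unphased panels store one row per sample of 0/1/2
    dosages.
    """

    snp_ids: list[str]
    haplotypes: np.ndarray  # (n_rows, n_snps) int8
    phased: bool = True

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.haplotypes[:, self._index[snp_id]]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive: columns gene_id, chrom, start, end."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start must be <= end")

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class QCThresholds:
    """Per-SNP QC cutoffs.

    ``call_rate_min`` defaults to the literal published 0.25 ("genotype
    percent <0.25"); set 0.95 for conventional GWAS QC.
    """

    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    call_rate_min: float = 0.25

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    """Per-SNP QC metrics and pass/fail bookkeeping.

    ``table`` columns: snp_id, maf, hwe_p, call_rate, passed, reasons
    (comma-joined failure reasons, empty when passed).
    """

    table: pd.DataFrame
    n_input: int
    n_passed: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_passed


@dataclass
class SNPGeneAssignment:
    """Many-to-many SNP-to-gene window mapping.

    ``pairs`` columns: snp_id, gene_id. ``unmapped`` lists SNPs assigned to no
    gene. ``window_bp`` records the flank used.
    """

    pairs: pd.DataFrame
    unmapped: list[str]
    window_bp: int

    def genes_for(self, snp_id: str) -> list[str]:
        return self.pairs.loc[self.pairs["snp_id"] == snp_id, "gene_id"].tolist()

    def snps_for(self, gene_id: str) -> list[str]:
        return self.pairs.loc[self.pairs["gene_id"] == gene_id, "snp_id"].tolist()


@dataclass
class TagSet:
    """Greedy tagSNP selection for one gene.

    ``coverage`` maps every non-tag SNP to its covering tag and the panel r²;
    tags cover themselves implicitly. SNPs absent from the panel, or
    monomorphic in it, become their own tags.
    """

    gene_id: str
    tags: list[str]
    coverage: dict[str, tuple[str, float]]
    r2_threshold: float

    @property
    def n_tags(self) -> int:
        return len(self.tags)


@dataclass
class ExpressionDataset:
    """Normalized feature x sample expression matrix with binary groups.

    ``values`` index = feature ids, columns = sample ids. ``groups`` maps
    sample id -> 'case' | 'control'. ``level`` is 'probe' or 'gene'.
    """

    values: pd.DataFrame
    groups: pd.Series
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.groups.isna().any():
            raise ValueError("missing group labels")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing[:3]}")

    def sample_ids(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: tuple[str, ...]
    function_class: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"pathway {self.pathway_id} has no members")


@dataclass
class PathwayCollection:
    """Ordered collection of gene sets keyed by pathway id."""

    pathways: dict[str, Pathway]

    @classmethod
    def from_list(cls, items: list[Pathway]) -> "PathwayCollection":
        d: dict[str, Pathway] = {}
        for p in items:
            if p.pathway_id in d:
                raise ValueError(f"duplicate pathway id {p.pathway_id}")
            d[p.pathway_id] = p
        return cls(d)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self.pathways[pathway_id]

    def ids(self) -> list[str]:
        return list(self.pathways)


@dataclass
class GroundTruth:
    """Planted signal emitted by the simulator, for recovery testing."""

    causal_snp_ids: set[str] = field(default_factory=set)
    causal_gene_ids: set[str] = field(default_factory=set)
    de_gene_ids: set[str] = field(default_factory=set)
    enriched_pathway_ids: set[str] = field(default_factory=set)


@dataclass
class ComparisonReport:
    """Three-mode significant-set comparison (gwas / expression / integrated)."""

    significant: dict[str, set[str]]
    q_threshold: float

    @property
    def shared_gwas_expression(self) -> set[str]:
        return self.significant["gwas"] & self.significant["expression"]

    @property
    def shared_all(self) -> set[str]:
        return (
            self.significant["gwas"]
            & self.significant["expression"]
            & self.significant["integrated"]
        )

    @property
    def integrated_only(self) -> set[str]:
        """Pathways found only by the integrated analysis ("novel")."""
        return self.significant["integrated"] - (
            self.significant["gwas"] | self.significant["expression"]
        )

    def counts(self) -> dict[str, int]:
        return {
            "gwas": len(self.significant["gwas"]),
            "expression": len(self.significant["expression"]),
            "integrated": len(self.significant["integrated"]),
            "gwas_and_expression": len(self.shared_gwas_expression),
            "all_three": len(self.shared_all),
            "integrated_only": len(self.integrated_only),
        }
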