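"""Gene-wise association scores from case-control genotypes.

The chain is: per-SNP QC (MAF, Hardy-Weinberg, call rate) -> Cochran-Armitage
trend test per SNP -> window mapping of SNPs to genes (gene body +/- 50 kb)
-> tagSNP selection against a reference LD panel (greedy cover at r^2 >= 0.8)
-> per-gene score = the smallest trend-test p among the gene's tagSNPs.

Testing Hardy-Weinberg in controls only is the default (cases may deviate
through true association); pass ``hwe_in='all'`` to use every sample.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeDataset,
    GeneAnnotation,
    QCReport,
    QCThresholds,
    ReferencePanel,
    SNPGeneAssignment,
    TagSet,
)
from .errors import (
    ConsistencyError,
    EmptyAfterQCError,
    MonomorphicSNPError,
    ParseError,
    UndefinedStatisticError,
)

# ---------------------------------------------------------------------------
# Hardy-Weinberg

def hwe_test(genotype_counts: tuple[int, int, int], method: str = "chisq") -> tuple[float, bool]:
    """Hardy-Weinberg equilibrium p-value from (n_AA, n_Aa, n_aa) counts.

    Returns ``(p, monomorphic)``. The default is the 1-df chi-square
    goodness-of-fit test against the genotype proportions expected from the
    estimated allele frequency; ``method='exact'`` gives the conditional exact
    test (sum of heterozygote-count probabilities no larger than the
    observed one). A monomorphic SNP returns p = 1 with the flag set.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_ + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa_ + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0, True
    if method == "chisq":
        p_hat = n_a / (2 * n)
        expected = np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2]) * n
        observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
        stat = float(np.sum((observed - expected) ** 2 / expected))
        return float(stats.chi2.sf(stat, df=1)), False
    if method == "exact":
        return _hwe_exact(n_ab, n_a, n_b), False
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_het: int, n_a: int, n_b: int) -> float:
    """Conditional exact HWE test on the heterozygote count.

    P(het = h | allele counts) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^h; the p-value
    sums probabilities of all heterozygote counts at most as likely as the
    observed one.
    """
    rare = min(n_a, n_b)
    n = (n_a + n_b) // 2
    hets = range(rare % 2, rare + 1, 2)
    logprobs = []
    for h in hets:
        n_rr = (rare - h) // 2
        n_cc = n - n_rr - h
        lp = (
            h * math.log(2)
            - math.lgamma(n_rr + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_cc + 1)
        )
        logprobs.append(lp)
    logprobs = np.array(logprobs)
    probs = np.exp(logprobs - logprobs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test

def cochran_armitage_trend(
    case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]
) -> tuple[float, float]:
    """Cochran-Armitage test for trend with additive scores (0, 1, 2).

    ``case_counts`` / ``control_counts`` are genotype-class counts
    (n0, n1, n2) by minor-allele dosage. Returns ``(Z², p)`` with the
    two-sided p from the chi-square distribution with 1 df.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if r.sum() <= 0 or s.sum() <= 0:
        raise UndefinedStatisticError("each group needs a positive total")
    stat, p = _trend_vectorized(r[None, :], s[None, :])
    if np.isnan(stat[0]):
        raise UndefinedStatisticError(
            "trend statistic undefined: zero genotype-score variance"
        )
    return float(stat[0]), float(p[0])


def _trend_vectorized(r: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trend Z² and p for stacked (m, 3) case/control count arrays.

    Degenerate rows (zero variance) yield NaN rather than raising.
    """
    w = np.array([0.0, 1.0, 2.0])
    n_col = r + s
    big_r = r.sum(axis=1)
    big_n = n_col.sum(axis=1)
    t1 = n_col @ w          # sum w_i n_i
    t2 = n_col @ w**2       # sum w_i^2 n_i
    num = big_n * (r @ w) - big_r * t1
    var = big_r * (big_n - big_r) * (big_n * t2 - t1**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, big_n * num**2 / var, np.nan)
    p = stats.chi2.sf(stat, df=1)
    return stat, p


def trend_test_all(dataset: GenotypeDataset) -> pd.DataFrame:
    """Trend test for every SNP; returns snp_id, statistic, p (NaN when undefined).

    Missing calls are dropped per SNP before counting.
    """
    calls = dataset.calls
    is_case = dataset.phenotypes == 1
    r = np.zeros((dataset.n_snps, 3))
    s = np.zeros((dataset.n_snps, 3))
    for g in (0, 1, 2):
        r[:, g] = ((calls == g) & is_case[:, None]).sum(axis=0)
        s[:, g] = ((calls == g) & ~is_case[:, None]).sum(axis=0)
    stat, p = _trend_vectorized(r, s)
    return pd.DataFrame(
        {"snp_id": dataset.snps["snp_id"].to_numpy(), "statistic": stat, "p": p}
    )


# ---------------------------------------------------------------------------
# QC

def snp_qc(
    dataset: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    hwe_in: str = "controls",
    hwe_method: str = "chisq",
) -> tuple[GenotypeDataset, QCReport]:
    """Filter SNPs on MAF, Hardy-Weinberg and call rate.

    MAF and call rate use all samples; HWE uses controls only unless
    ``hwe_in='all'``. Raises :class:`EmptyAfterQCError` if nothing survives.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    if dataset.n_snps == 0:
        raise ValueError("dataset has no SNPs")
    calls = dataset.calls
    observed = calls >= 0
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / dataset.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_obs > 0, calls.clip(min=0).sum(axis=0) / (2 * n_obs), np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    hwe_rows = (dataset.phenotypes == 0) if hwe_in == "controls" else np.ones(
        dataset.n_samples, dtype=bool
    )
    sub = calls[hwe_rows]
    hwe_p = np.empty(dataset.n_snps)
    for j in range(dataset.n_snps):
        col = sub[:, j]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        if sum(counts) == 0:
            hwe_p[j] = 1.0
        else:
            hwe_p[j], _ = hwe_test(counts, method=hwe_method)

    reasons = []
    for j in range(dataset.n_snps):
        r = []
        if np.isnan(maf[j]) or maf[j] < thresholds.maf_min:
            r.append("low_maf")
        if hwe_p[j] < thresholds.hwe_p_min:
            r.append("hwe_fail")
        if call_rate[j] < thresholds.call_rate_min:
            r.append("low_call_rate")
        reasons.append(",".join(r))
    passed = np.array([not r for r in reasons])

    report = QCReport(
        table=pd.DataFrame(
            {
                "snp_id": dataset.snps["snp_id"].to_numpy(),
                "maf": maf,
                "hwe_p": hwe_p,
                "call_rate": call_rate,
                "passed": passed,
                "reasons": reasons,
            }
        ),
        n_input=dataset.n_snps,
        n_passed=int(passed.sum()),
    )
    if report.n_passed == 0:
        raise EmptyAfterQCError("no SNP passed quality control")
    return dataset.subset_snps(passed), report


# ---------------------------------------------------------------------------
# SNP -> gene window mapping

def map_snps_to_genes(
    snps: pd.DataFrame, annotation: GeneAnnotation, window_bp: int = 50_000
) -> SNPGeneAssignment:
    """Assign SNPs to genes within [start - window, end + window], inclusive.

    A SNP may map to several genes (overlapping windows); SNPs in no window
    are listed as unmapped. Raises :class:`ParseError` when the two inputs
    share no chromosome name at all (a naming-convention clash).
    """
    snp_chroms = set(snps["chrom"].astype(str))
    ann_chroms = set(annotation.table["chrom"].astype(str))
    if snp_chroms and ann_chroms and not (snp_chroms & ann_chroms):
        offender = sorted(snp_chroms)[0]
        raise ParseError(
            f"chromosome name mismatch between SNPs and annotation "
            f"(e.g. SNP chromosome {offender!r} absent from annotation)"
        )
    pairs: list[tuple[str, str]] = []
    mapped: set[str] = set()
    ann = annotation.table
    for chrom, genes in ann.groupby("chrom", sort=False):
        sub = snps[snps["chrom"].astype(str) == str(chrom)]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        for gene_id, start, end in zip(genes["gene_id"], genes["start"], genes["end"]):
            hit = (pos >= start - window_bp) & (pos <= end + window_bp)
            for sid in ids[hit]:
                pairs.append((sid, gene_id))
                mapped.add(sid)
    unmapped = [s for s in snps["snp_id"] if s not in mapped]
    return SNPGeneAssignment(
        pairs=pd.DataFrame(pairs, columns=["snp_id", "gene_id"]),
        unmapped=unmapped,
        window_bp=window_bp,
    )


# ---------------------------------------------------------------------------
# LD r² and tagSNP selection

def _r2_from_vectors(x: np.ndarray, y: np.ndarray) -> float:
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        raise MonomorphicSNPError("r² undefined for a monomorphic SNP")
    c = np.cov(x, y, bias=True)[0, 1]
    return float(c * c / (vx * vy))


def pairwise_r2(panel: ReferencePanel, snp_a: str, snp_b: str) -> float:
    """Panel LD r² between two SNPs.

    On a phased panel this is the haplotype-frequency r² = D²/(pA pa pB pb)
    (identical to the squared Pearson correlation of the 0/1 haplotype
    vectors); on an unphased panel it is the squared composite correlation of
    the 0/1/2 dosages.
    """
    for s in (snp_a, snp_b):
        if s not in panel:
            raise KeyError(f"SNP {s} not in panel")
    x = panel.column(snp_a).astype(float)
    y = panel.column(snp_b).astype(float)
    return _r2_from_vectors(x, y)


def _r2_matrix(panel: ReferencePanel, snp_ids: list[str]) -> np.ndarray:
    """All-pairs r² among panel SNPs; NaN rows/cols for monomorphic SNPs."""
    cols = np.stack([panel.column(s).astype(float) for s in snp_ids], axis=1)
    sd = cols.std(axis=0)
    poly = sd > 0
    r2 = np.full((len(snp_ids), len(snp_ids)), np.nan)
    if poly.sum() >= 1:
        sub = cols[:, poly]
        if sub.shape[1] == 1:
            corr = np.ones((1, 1))
        else:
            corr = np.corrcoef(sub, rowvar=False)
        idx = np.flatnonzero(poly)
        r2[np.ix_(idx, idx)] = corr**2
    np.fill_diagonal(r2, np.where(poly, 1.0, np.nan))
    return r2


def select_tag_snps(
    gene_id: str,
    gene_snp_ids: list[str],
    panel: ReferencePanel,
    r2_threshold: float = 0.8,
    positions: dict[str, int] | None = None,
) -> TagSet:
    """Greedy maximum-coverage tagSNP selection for one gene.

    Repeatedly picks the SNP covering (r² >= threshold) the most uncovered
    SNPs; ties broken by smaller genomic position, then lexicographic id.
    SNPs absent from the panel or monomorphic in it become their own tags.
    """
    if not gene_snp_ids:
        raise ValueError(f"gene {gene_id}: empty SNP list")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0,1]")
    positions = positions or {}
    in_panel = [s for s in gene_snp_ids if s in panel]
    orphan = [s for s in gene_snp_ids if s not in panel]

    tags: list[str] = []
    coverage: dict[str, tuple[str, float]] = {}
    if in_panel:
        r2 = _r2_matrix(panel, in_panel)
        mono = np.isnan(np.diag(r2))
        orphan.extend(s for s, m in zip(in_panel, mono) if m)
        poly_ids = [s for s, m in zip(in_panel, mono) if not m]
        if poly_ids:
            r2_poly = np.nan_to_num(_r2_matrix(panel, poly_ids), nan=0.0)
            cov = r2_poly >= r2_threshold
            np.fill_diagonal(cov, True)
            uncovered = np.ones(len(poly_ids), dtype=bool)
            order_key = {
                s: (positions.get(s, 0), s) for s in poly_ids
            }
            while uncovered.any():
                gains = (cov & uncovered[None, :]).sum(axis=1)
                best_gain = gains.max()
                candidates = [
                    i for i in range(len(poly_ids)) if gains[i] == best_gain
                ]
                best = min(candidates, key=lambda i: order_key[poly_ids[i]])
                tags.append(poly_ids[best])
                newly = cov[best] & uncovered
                for j in np.flatnonzero(newly):
                    if j != best:
                        coverage[poly_ids[j]] = (poly_ids[best], float(r2_poly[best, j]))
                uncovered &= ~cov[best]
    tags.extend(sorted(orphan, key=lambda s: (positions.get(s, 0), s)))
    return TagSet(gene_id=gene_id, tags=tags, coverage=coverage, r2_threshold=r2_threshold)


def select_tag_snps_all(
    assignment: SNPGeneAssignment,
    panel: ReferencePanel,
    snps: pd.DataFrame,
    r2_threshold: float = 0.8,
) -> dict[str, TagSet]:
    """Tag selection for every gene in the assignment; returns gene_id -> TagSet."""
    positions = dict(zip(snps["snp_id"], snps["pos"].astype(int)))
    out: dict[str, TagSet] = {}
    for gene_id, grp in assignment.pairs.groupby("gene_id", sort=True):
        ids = grp["snp_id"].tolist()
        out[gene_id] = select_tag_snps(gene_id, ids, panel, r2_threshold, positions)
    return out


# ---------------------------------------------------------------------------
# Gene-wise score

def gene_wise_association(
    assignment: SNPGeneAssignment,
    snp_pvalues: pd.DataFrame | dict,
    tagsets: dict[str, TagSet],
) -> pd.DataFrame:
    """Per-gene GWAS p-value: the minimum trend p over the gene's tagSNPs.

    Genes with zero mapped SNPs are simply absent (they are never in
    ``tagsets``). Returns columns gene_id, p, best_tag, n_snps, n_tags.
    """
    if isinstance(snp_pvalues, pd.DataFrame):
        pmap = dict(zip(snp_pvalues["snp_id"], snp_pvalues["p"]))
    else:
        pmap = dict(snp_pvalues)
    rows = []
    n_snps_per_gene = assignment.pairs.groupby("gene_id")["snp_id"].size()
    for gene_id in sorted(tagsets):
        ts = tagsets[gene_id]
        missing = [t for t in ts.tags if t not in pmap or not np.isfinite(pmap[t])]
        if missing:
            raise ConsistencyError(
                f"gene {gene_id}: tagSNP(s) without a p-value: {missing[:3]}"
            )
        ps = [(pmap[t], t) for t in ts.tags]
        best_p, best_tag = min(ps)
        rows.append(
            {
                "gene_id": gene_id,
                "p": float(best_p),
                "best_tag": best_tag,
                "n_snps": int(n_snps_per_gene.get(gene_id, 0)),
                "n_tags": ts.n_tags,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "p", "best_tag", "n_snps", "n_tags"])
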