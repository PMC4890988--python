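"""Pathway-level inference: Fisher scores, permutation null, FDR, comparison.

A pathway's score is S = -2 Σ ln p over its member genes that carry a gene
association p-value. Significance comes from a gene-resampling null: each
replicate draws the same number of scored genes, without replacement, from
the non-redundant universe of scored genes across all analyzed pathways and
recomputes the score (S_random). The permutation p-value counts replicates
with S_random strictly greater than S_true (the published counting rule;
``tie_rule='conservative'`` gives the +1-corrected variant). Benjamini-
Hochberg q-values at threshold 0.05 flag significant pathways.

Each pathway gets its own RNG substream derived from (seed, pathway id), so
results do not depend on evaluation order or on the worker count.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ComparisonReport, PathwayCollection
from .errors import ConfigurationError

_PERM_CHUNK = 1000  # replicates per vectorized draw


def filter_pathways_by_size(
    collection: PathwayCollection, min_genes: int = 5, max_genes: int = 200
) -> PathwayCollection:
    """Drop pathways whose full membership count lies outside [min, max]."""
    kept = [p for p in collection if min_genes <= len(p.genes) <= max_genes]
    return PathwayCollection.from_list(kept)


def pathway_association_score(member_gene_ps) -> float:
    """Fisher pathway score S = -2 Σ ln p over the scored members."""
    p = np.asarray(list(member_gene_ps), dtype=float)
    if p.size == 0:
        raise ValueError("pathway has no scored members")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("member p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def _pathway_rng(seed: int, pathway_id: str) -> np.random.Generator:
    """Deterministic per-pathway substream, independent of evaluation order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(pathway_id.encode())])
    )


def permutation_pvalue(
    s_true: float,
    n_scored: int,
    universe_log_weights: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    pathway_id: str = "",
    tie_rule: str = "strict",
) -> tuple[float, dict]:
    """Gene-resampling permutation p-value for one pathway.

    ``universe_log_weights`` holds -2 ln p per gene of the scored universe, so
    each replicate's S_random is a subset sum. The strict rule returns
    count(S_random > S_true)/n_perm; the conservative rule returns
    (count(S_random >= S_true) + 1)/(n_perm + 1).
    """
    w = np.asarray(universe_log_weights, dtype=float)
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if n_scored > w.size:
        raise ConfigurationError(
            f"pathway needs {n_scored} genes but the universe has {w.size}"
        )
    if tie_rule not in ("strict", "conservative"):
        raise ConfigurationError(f"unknown tie rule {tie_rule!r}")
    rng = _pathway_rng(seed, pathway_id)
    exceed = 0  # S_random > S_true
    ties = 0    # S_random == S_true (within float tolerance)
    done = 0
    tol = 1e-9 * max(1.0, abs(s_true))
    while done < n_perm:
        m = min(_PERM_CHUNK, n_perm - done)
        if n_scored == w.size:
            s_rand = np.full(m, w.sum())
        else:
            keys = rng.random((m, w.size))
            idx = np.argpartition(keys, n_scored - 1, axis=1)[:, :n_scored]
            s_rand = w[idx].sum(axis=1)
        exceed += int((s_rand > s_true + tol).sum())
        ties += int((np.abs(s_rand - s_true) <= tol).sum())
        done += m
    if tie_rule == "strict":
        p = exceed / n_perm
    else:
        p = (exceed + ties + 1) / (n_perm + 1)
    summary = {
        "n_perm": n_perm,
        "n_exceed": exceed,
        "n_ties": ties,
    }
    return float(p), summary


def adjust_fdr(p_values, method: str = "bh") -> np.ndarray:
    """FDR q-values: Benjamini-Hochberg step-up (default) or Storey's q-value.

    The Storey option uses the fixed-lambda (0.5) pi0 estimate.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        _, q, _, _ = multipletests(p, method="fdr_bh")
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, (p > lam).sum() / (p.size * (1 - lam)))
        pi0 = max(pi0, 1.0 / p.size)
        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        return np.minimum(pi0 * q_bh, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def run_pathway_analysis(
    gene_scores: pd.DataFrame,
    pathways: PathwayCollection,
    mode: str = "integrated",
    n_perm: int = 100_000,
    seed: int = 0,
    min_genes: int = 5,
    max_genes: int = 200,
    q_threshold: float = 0.05,
    tie_rule: str = "strict",
    fdr_method: str = "bh",
    n_workers: int = 1,
) -> pd.DataFrame:
    """Size filter -> Fisher scores -> permutation -> FDR -> significance.

    ``gene_scores`` is the integrated score table (columns gene_id, p_gwas,
    p_expr, p_combined, has_gwas, has_expr); the gene p-value column is picked
    by ``mode`` ('gwas' | 'expression' | 'integrated'). Returns one row per
    scored pathway, sorted by (p_perm, q, pathway_id), with columns
    pathway_id, name, n_members, n_scored, s_true, p_perm, q, significant.
    """
    col = {"gwas": "p_gwas", "expression": "p_expr", "integrated": "p_combined"}
    if mode not in col:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    scores = gene_scores.dropna(subset=[col[mode]])
    pmap = dict(zip(scores["gene_id"], scores[col[mode]].astype(float)))

    sized = filter_pathways_by_size(pathways, min_genes, max_genes)
    scored = []
    for pw in sized:
        members = [g for g in pw.genes if g in pmap]
        if not members:
            warnings.warn(f"pathway {pw.pathway_id}: no scored member; skipped")
            continue
        scored.append((pw, members))
    if not scored:
        raise ConfigurationError("no pathway has any scored member gene")

    # non-redundant union of scored genes across the analyzed pathways
    universe = sorted({g for _, members in scored for g in members})
    w = np.array([-2.0 * np.log(max(pmap[g], 1e-300)) for g in universe])
    widx = {g: i for i, g in enumerate(universe)}

    def one(pw, members):
        s_true = pathway_association_score([pmap[g] for g in members])
        p_perm, _ = permutation_pvalue(
            s_true,
            len(members),
            w,
            n_perm=n_perm,
            seed=seed,
            pathway_id=pw.pathway_id,
            tie_rule=tie_rule,
        )
        return {
            "pathway_id": pw.pathway_id,
            "name": pw.name,
            "n_members": len(pw.genes),
            "n_scored": len(members),
            "s_true": s_true,
            "p_perm": p_perm,
        }

    if n_workers > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_workers)(delayed(one)(pw, m) for pw, m in scored)
    else:
        rows = [one(pw, m) for pw, m in scored]
    out = pd.DataFrame(rows)
    out["q"] = adjust_fdr(out["p_perm"].to_numpy(), method=fdr_method)
    out["significant"] = out["q"] < q_threshold
    out = out.sort_values(["p_perm", "q", "pathway_id"]).reset_index(drop=True)
    return out


def compare_modes(
    results_gwas: pd.DataFrame,
    results_expr: pd.DataFrame,
    results_integrated: pd.DataFrame,
    q_threshold: float = 0.05,
) -> ComparisonReport:
    """Significant-set comparison of the three analysis modes."""
    frames = {
        "gwas": results_gwas,
        "expression": results_expr,
        "integrated": results_integrated,
    }
    universes = [frozenset(f["pathway_id"]) for f in frames.values()]
    if len(set(universes)) != 1:
        raise ConfigurationError("the three result lists cover different pathways")
    significant = {
        mode: set(f.loc[f["q"] < q_threshold, "pathway_id"]) for mode, f in frames.items()
    }
    return ComparisonReport(significant=significant, q_threshold=q_threshold)
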