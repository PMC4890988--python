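"""Fisher combination of the GWAS and expression gene p-values.

For gene *i* with GWAS p-value P_i1 and differential-expression p-value P_i2,
the combined score is

    g_i = -2 * (ln P_i1 + ln P_i2)

which under the null of no association in either source follows a chi-square
distribution with 2k degrees of freedom (k = 2 sources here); the combined
gene p-value P_i is the upper tail of that distribution at g_i.

Inputs are clamped to [1e-300, 1] before taking logs so that degenerate
upstream zeros keep g finite while preserving ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError

P_CLAMP = 1e-300


def fisher_combine_pvalues(p_values) -> tuple[float, float]:
    """Fisher's method for a list of k p-values.

    Returns ``(g, combined_p)`` where g = -2 Σ ln p_j and combined_p is the
    chi-square(2k) upper-tail probability at g.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, P_CLAMP, 1.0)
    g = float(-2.0 * np.log(p).sum())
    return g, float(stats.chi2.sf(g, df=2 * p.size))


def build_integrated_scores(
    gwas_scores: pd.DataFrame, expr_scores: pd.DataFrame
) -> pd.DataFrame:
    """Join the two per-gene score tables and combine with k = 2.

    Inputs carry gene_id and p columns (extra columns ignored). The output
    keeps the union of gene universes with evidence flags; the Fisher score
    g and combined p are filled only on the intersection. Columns: gene_id,
    p_gwas, p_expr, has_gwas, has_expr, g, p_combined.
    """
    g = gwas_scores[["gene_id", "p"]].rename(columns={"p": "p_gwas"})
    e = expr_scores[["gene_id", "p"]].rename(columns={"p": "p_expr"})
    for name, df in (("gwas", g), ("expression", e)):
        if df["gene_id"].duplicated().any():
            raise ConsistencyError(f"duplicate gene ids in {name} scores")
    table = g.merge(e, on="gene_id", how="outer").sort_values("gene_id")
    table["has_gwas"] = table["p_gwas"].notna()
    table["has_expr"] = table["p_expr"].notna()
    both = table["has_gwas"] & table["has_expr"]
    if not both.any():
        raise ConsistencyError(
            "empty intersection: no gene has both a GWAS and an expression p-value"
        )
    p1 = np.clip(table.loc[both, "p_gwas"].to_numpy(float), P_CLAMP, 1.0)
    p2 = np.clip(table.loc[both, "p_expr"].to_numpy(float), P_CLAMP, 1.0)
    gscore = -2.0 * (np.log(p1) + np.log(p2))
    table["g"] = np.nan
    table["p_combined"] = np.nan
    table.loc[both, "g"] = gscore
    table.loc[both, "p_combined"] = stats.chi2.sf(gscore, df=4)
    return table.reset_index(drop=True)


def intersection_size(table: pd.DataFrame) -> int:
    """Number of genes carrying both evidence sources (the analysis universe)."""
    return int((table["has_gwas"] & table["has_expr"]).sum())
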