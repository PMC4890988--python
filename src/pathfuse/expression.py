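"""Differential-expression gene scores from a normalized matrix.

The module consumes an already-normalized intensity matrix (normalization of
raw array data is upstream and out of scope), optionally collapses probes to
genes, and assigns each gene a two-sided two-sample t-test p-value comparing
cases with controls. The equal-variance (Student) test is the default;
Welch's correction is available via ``variant='welch'``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset

#: flag values in the output table
FLAG_OK = ""
FLAG_DEGENERATE_EQUAL = "degenerate_equal_means"
FLAG_DEGENERATE_SEPARATED = "degenerate_zero_variance"


def collapse_probes_to_genes(
    dataset: ExpressionDataset,
    probe_gene_map: dict[str, str] | pd.Series,
    rule: str = "median",
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    ``rule`` is 'median' (default), 'mean', or 'max-mean-probe' (keep the
    probe with the largest across-sample mean). Probes absent from the map
    are dropped. Gene-level input is returned unchanged with a warning.
    """
    if dataset.level == "gene":
        warnings.warn("dataset already gene-level; collapse is a no-op")
        return dataset
    pmap = pd.Series(probe_gene_map)
    if pmap.empty:
        raise ValueError("empty probe-to-gene map")
    vals = dataset.values
    present = [p for p in vals.index if p in pmap.index]
    if not present:
        raise ValueError("no probe in the matrix is covered by the map")
    sub = vals.loc[present]
    genes = pmap.loc[present]
    if rule == "median":
        out = sub.groupby(genes.to_numpy()).median()
    elif rule == "mean":
        out = sub.groupby(genes.to_numpy()).mean()
    elif rule == "max-mean-probe":
        probe_means = sub.mean(axis=1)
        best = probe_means.groupby(genes.to_numpy()).idxmax()
        out = sub.loc[best]
        out.index = best.index
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    out = out.sort_index()
    out.index.name = vals.index.name
    return ExpressionDataset(values=out, groups=dataset.groups, level="gene")


def differential_expression_ttest(
    dataset: ExpressionDataset, variant: str = "student"
) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene; cases vs controls.

    Returns columns gene_id, t, p, mean_case, mean_control, flag. Rows with
    zero variance in both groups get p = 1 when means agree, or the smallest
    positive float when they differ, with a flag either way.
    """
    if dataset.level != "gene":
        raise ValueError("t-test expects a gene-level matrix; collapse probes first")
    cases = dataset.sample_ids("case")
    controls = dataset.sample_ids("control")
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 samples per group")
    a = dataset.values[cases].to_numpy(dtype=float)
    b = dataset.values[controls].to_numpy(dtype=float)
    equal_var = variant == "student"
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    flags = np.full(len(t), FLAG_OK, dtype=object)
    degenerate = ~np.isfinite(t)
    equal = degenerate & np.isclose(mean_a, mean_b)
    separated = degenerate & ~np.isclose(mean_a, mean_b)
    t = np.where(degenerate, 0.0, t)
    p = np.where(equal, 1.0, p)
    p = np.where(separated, np.finfo(float).tiny, p)
    flags[equal] = FLAG_DEGENERATE_EQUAL
    flags[separated] = FLAG_DEGENERATE_SEPARATED
    return pd.DataFrame(
        {
            "gene_id": dataset.values.index.to_numpy(),
            "t": t,
            "p": p,
            "mean_case": mean_a,
            "mean_control": mean_b,
            "flag": flags,
        }
    )
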