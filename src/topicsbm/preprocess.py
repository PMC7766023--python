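"""Gene filtering and the log transform applied before graph construction.

Two selection strategies are supported: a tissue-specific effect-size
score (mean shift of a gene in the tissue of interest relative to all
other samples, scaled by the in-tissue standard deviation) and the
standard highly-variable-gene selection by mean-binned normalized
dispersion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def tissue_specific_scores(expr: ExpressionMatrix, in_group) -> pd.DataFrame:
    """Per-gene tissue-specificity scores.

    For each gene g and the sample subset T given by the boolean mask
    ``in_group``::

        m_in  = mean of gene g over T
        m_out = mean of gene g over the complement of T
        v_in  = population variance of gene g over T (divisor |T|)
        d     = (m_in - m_out) / sqrt(v_in)

    Genes with zero in-group variance get d = NaN (undefined).  Returns a
    DataFrame indexed by gene id with columns m_in, m_out, v_in, d.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.size != expr.n_samples:
        raise ValueError("mask length does not match sample count")
    if mask.sum() == 0 or mask.sum() == mask.size:
        raise ValueError("in-group must be a non-empty strict subset of samples")

    x_in = expr.values[:, mask]
    x_out = expr.values[:, ~mask]
    m_in = x_in.mean(axis=1)
    m_out = x_out.mean(axis=1)
    v_in = x_in.var(axis=1)  # population convention, divisor |T|
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m_in - m_out) / np.sqrt(v_in)
    d = np.where(v_in > 0, d, np.nan)
    return pd.DataFrame({"m_in": m_in, "m_out": m_out, "v_in": v_in, "d": d},
                        index=pd.Index(expr.genes, name="gene_id"))


def select_tissue_specific(scores: pd.DataFrame, n_genes: int,
                           whitelist=None, denominator: str = "sqrt") -> list[str]:
    """Top genes by tissue-specificity score.

    ``denominator='variance'`` rescales d to use v instead of sqrt(v)
    before ranking.  Genes with undefined score are excluded.  Ties are
    broken by gene id; a whitelist (e.g. an eQTL quality-filter list)
    restricts the candidates.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    d = scores["d"].copy()
    if denominator == "variance":
        d = d / np.sqrt(scores["v_in"])
    elif denominator != "sqrt":
        raise ValueError("denominator must be 'sqrt' or 'variance'")
    table = d.dropna()
    if whitelist is not None:
        keep = table.index.intersection(pd.Index(list(whitelist)))
        if len(keep) == 0:
            warnings.warn("whitelist shares no genes with the matrix")
        table = table.loc[keep]
    if n_genes > len(table):
        if n_genes > len(scores):
            warnings.warn(f"requested {n_genes} genes but only {len(table)} scoreable")
        n_genes = len(table)
    order = table.sort_values(ascending=False, kind="mergesort")
    # stable sort + index tie-break: sort by (-d, gene_id)
    ranked = sorted(order.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n_genes]]


def select_highly_variable(expr: ExpressionMatrix, n_genes: int = 3000,
                           n_bins: int = 20) -> list[str]:
    """Highly-variable genes by mean-binned normalized dispersion.

    Works on log1p-transformed values: dispersion = variance / mean,
    z-scored within ``n_bins`` equal-width bins of the mean expression so
    that the ranking is not driven by the mean-variance trend.  Ties break
    by gene id.  Returns all genes when ``n_genes`` exceeds the gene count.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    logged = np.log1p(expr.values)
    mean = logged.mean(axis=1)
    var = logged.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    if expr.n_genes < n_bins:
        warnings.warn("fewer genes than bins; ranking by raw dispersion")
        z = disp.astype(float)
    else:
        bins = pd.cut(mean, bins=n_bins, labels=False, include_lowest=True)
        z = np.zeros(expr.n_genes)
        global_mu = disp.mean()
        global_sd = disp.std(ddof=1) if expr.n_genes > 1 else 1.0
        for b in np.unique(bins):
            members = bins == b
            if members.sum() < 2:
                # singleton bin: z-score against the global dispersion spread
                z[members] = ((disp[members] - global_mu) / global_sd
                              if global_sd > 0 else 0.0)
                continue
            mu, sd = disp[members].mean(), disp[members].std(ddof=1)
            z[members] = (disp[members] - mu) / sd if sd > 0 else 0.0

    ranked = sorted(zip(expr.genes, z), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[: min(n_genes, expr.n_genes)]]


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise log2(x + 1); sparsifies the graph built downstream."""
    if np.any(expr.values < 0):
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(np.log2(expr.values + 1.0), list(expr.genes),
                            list(expr.samples))


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="gene_id")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
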