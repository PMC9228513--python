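"""Methylation-expression integration.

Gene-level methylation (mean CPM of a gene's assigned sites per sample)
is correlated against per-sample expression with Pearson's test; genes
with r < 0 and p < alpha are the negatively-correlated class that the
repression hypothesis predicts.  When only group fold changes are
available, a sign-concordance mode compares methylation and expression
log2FC directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sites import CountMatrix

log = logging.getLogger(__name__)

CLASS_NEGATIVE = "negative"
CLASS_POSITIVE = "positive"
CLASS_NONE = "none"


def gene_methylation_levels(
    matrix: CountMatrix,
    assignments: pd.DataFrame,
    promoter_only: bool = False,
) -> pd.DataFrame:
    """Genes x samples mean CPM over each gene's assigned sites."""
    links = assignments[assignments.promoter_flag] if promoter_only else assignments
    cpm = matrix.counts / matrix.library_sizes * 1e6
    cpm = cpm.reset_index()
    merged = links[["contig", "pos", "strand", "gene_id"]].merge(
        cpm, on=["contig", "pos", "strand"], how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=matrix.samples)
    return merged.groupby("gene_id")[matrix.samples].mean()


def match_deg_dmg(
    expression: pd.DataFrame,
    methylation_genes: pd.Series | list,
    fdr_column: str = "FDR",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Inner join of significant DEGs with genes holding >= 1 methylation
    site.  ``expression`` must carry a unique ``gene_id`` column; rows with
    ``FDR < alpha`` count as DEGs.  Unmatched ids are logged."""
    if expression["gene_id"].duplicated().any():
        dups = expression["gene_id"][expression["gene_id"].duplicated()].tolist()
        raise ValueError(f"ambiguous join: duplicate gene rows {dups[:5]}")
    degs = expression[expression[fdr_column] < alpha]
    meth_ids = set(methylation_genes)
    matched = degs[degs["gene_id"].isin(meth_ids)].reset_index(drop=True)
    n_unmatched = len(degs) - len(matched)
    if len(matched) == 0:
        log.warning("no DEG/methylation gene overlap (%d DEGs)", len(degs))
    elif n_unmatched:
        log.info("%d significant DEGs had no methylation sites", n_unmatched)
    return matched


def correlate(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of matched per-sample values.

    Both frames are genes x samples; only shared genes and samples are
    tested (>= 3 paired observations required).  Zero variance in either
    vector leaves r undefined (class ``none``, flagged).
    """
    genes = methylation.index.intersection(expression.index)
    samples = [s for s in methylation.columns if s in expression.columns]
    if len(samples) < 3:
        raise ValueError("need >= 3 paired samples")
    rows = []
    for gene in genes:
        x = methylation.loc[gene, samples].to_numpy(dtype=float)
        y = expression.loc[gene, samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gene, np.nan, np.nan, CLASS_NONE, True))
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha:
            cls = CLASS_NEGATIVE if r < 0 else CLASS_POSITIVE
        else:
            cls = CLASS_NONE
        rows.append((gene, float(r), float(p), cls, False))
    return pd.DataFrame(
        rows, columns=["gene_id", "r", "p_value", "classification", "degenerate"]
    )


def sign_concordance(
    pairs: pd.DataFrame,
    meth_logfc: pd.Series,
    logfc_column: str = "log2FC",
) -> pd.DataFrame:
    """Fallback integration mode when only fold changes exist: a gene is
    ``negative`` when methylation and expression log2FC have opposite
    signs, ``positive`` when the same, ``none`` when either is zero."""
    out = pairs.copy()
    m = out["gene_id"].map(meth_logfc)
    prod = m * out[logfc_column]
    out["meth_log2FC"] = m
    out["classification"] = np.select(
        [prod < 0, prod > 0], [CLASS_NEGATIVE, CLASS_POSITIVE], default=CLASS_NONE
    )
    return out


def fold_change_comparison(
    correlations: pd.DataFrame,
    meth_logfc: pd.Series,
    expr_logfc: pd.Series,
) -> pd.DataFrame:
    """Per-gene table for the methylation-vs-expression heatmap: both
    log2FCs, r and classification, ordered by r (NaNs last)."""
    out = correlations.copy()
    out["meth_log2FC"] = out["gene_id"].map(meth_logfc)
    out["expr_log2FC"] = out["gene_id"].map(expr_logfc)
    out = out.sort_values(["r", "gene_id"], kind="mergesort", na_position="last")
    cols = ["gene_id", "meth_log2FC", "expr_log2FC", "r", "p_value",
            "classification"]
    return out[cols].reset_index(drop=True)
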