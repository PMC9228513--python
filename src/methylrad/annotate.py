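"""Assign methylation sites to genes under the gene-body +/- 2 kb rule.

A site belongs to gene G when its cytosine coordinate falls within
``[start - flank, end + flank]``.  The zone (body / upstream_2kb /
downstream_2kb) is resolved strand-aware — upstream means 5' of the gene
per its strand — and the promoter flag marks the 2 kb window strictly
upstream of the TSS.  A site inside two genes yields two assignment
records (no nearest-gene collapse).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneModel

ASSIGNMENT_COLUMNS = [
    "contig", "pos", "strand", "gene_id", "zone", "promoter_flag",
]


def assign_sites_to_genes(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 2000,
) -> pd.DataFrame:
    """All (site, gene) links within gene body +/- ``flank`` bp.

    ``sites`` needs columns contig, pos, strand.  Results are ordered by
    (contig, pos, strand, gene_id) and identical to the all-pairs interval
    test; the per-contig sorted-interval index only changes the cost.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    rows = []
    for contig, contig_sites in sites.groupby("contig", sort=False):
        glist = by_contig.get(contig, [])
        if not glist:
            continue
        starts = np.array([g.start - flank for g in glist])
        ends = np.array([g.end + flank for g in glist])
        order = np.argsort(starts, kind="mergesort")
        starts_sorted = starts[order]
        max_span = int((ends - starts).max()) if len(glist) else 0
        pos_arr = contig_sites["pos"].to_numpy()
        strand_arr = contig_sites["strand"].to_numpy()
        for pos, strand in zip(pos_arr, strand_arr):
            # candidate genes: window start within (pos - max_span, pos]
            lo = np.searchsorted(starts_sorted, pos - max_span, side="left")
            hi = np.searchsorted(starts_sorted, pos, side="right")
            for idx in order[lo:hi]:
                g = glist[idx]
                if not (g.start - flank <= pos <= g.end + flank):
                    continue
                if g.start <= pos <= g.end:
                    zone = "body"
                elif (pos < g.start) == (g.strand == "+"):
                    zone = "upstream_2kb"
                else:
                    zone = "downstream_2kb"
                if g.strand == "+":
                    promoter = g.start - flank <= pos <= g.start - 1
                else:
                    promoter = g.end + 1 <= pos <= g.end + flank
                rows.append((contig, int(pos), strand, g.gene_id, zone, promoter))
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return out.sort_values(
        ["contig", "pos", "strand", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def promoter_site_stats(
    assignments: pd.DataFrame, genes: list[GeneModel]
) -> tuple[pd.Series, dict]:
    """Per-gene promoter methylcytosine counts, with zero rows for genes
    without promoter sites, plus a median/quartile summary."""
    counts = (
        assignments[assignments.promoter_flag]
        .groupby("gene_id")
        .size()
        .reindex([g.gene_id for g in genes], fill_value=0)
        .astype(int)
    )
    if len(counts):
        summary = {
            "median": float(np.median(counts)),
            "q1": float(np.percentile(counts, 25)),
            "q3": float(np.percentile(counts, 75)),
        }
    else:
        summary = {"median": 0.0, "q1": 0.0, "q3": 0.0}
    return counts, summary


def aggregate_dmgs(
    dms: pd.DataFrame,
    assignments: pd.DataFrame,
    top_n: int = 100,
) -> pd.DataFrame:
    """Differentially methylated genes: per-gene DMS tallies plus the
    share of the top-N largest-|logFC| DMSs falling in each gene.

    ``dms`` needs columns contig, pos, strand, logFC.  Ranking ties on
    |logFC| break by site key order, so the output is deterministic.
    Genes are reported in descending n_dms (ties by gene_id).
    """
    merged = dms.merge(assignments, on=["contig", "pos", "strand"], how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["gene_id", "n_dms", "n_top"])
    ranked = dms.assign(abs_logfc=dms["logFC"].abs()).sort_values(
        ["abs_logfc", "contig", "pos", "strand"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    top = ranked.head(top_n)[["contig", "pos", "strand"]]
    top_hits = top.merge(assignments, on=["contig", "pos", "strand"], how="inner")

    n_dms = merged.groupby("gene_id").size()
    n_top = top_hits.groupby("gene_id").size()
    out = pd.DataFrame({"n_dms": n_dms}).fillna(0)
    out["n_top"] = n_top.reindex(out.index, fill_value=0).astype(int)
    out = out.reset_index().sort_values(
        ["n_dms", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def chromosome_density(
    sites: pd.DataFrame,
    dms: pd.DataFrame,
    contig_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-contig methylated-site and DMS counts and densities per Mb."""
    unknown = set(sites["contig"]) - set(contig_lengths)
    if unknown:
        raise KeyError(f"sites on unknown contigs: {sorted(unknown)}")
    rows = []
    for contig, length in contig_lengths.items():
        n_ms = int((sites["contig"] == contig).sum())
        n_dms = int((dms["contig"] == contig).sum()) if len(dms) else 0
        mb = length / 1e6
        rows.append((contig, length, n_ms, n_ms / mb, n_dms, n_dms / mb))
    return pd.DataFrame(
        rows,
        columns=["contig", "length", "n_ms", "ms_per_mb", "n_dms", "dms_per_mb"],
    )
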