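"""Shared fixtures and brute-force oracles.

The oracles here re-derive expectations by naive enumeration (per-position
window tests, all-pairs interval containment) and stay independent of the
implementation paths they check.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylrad.io import Genome
from methylrad._util import revcomp

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T",
         "W": "AT", "D": "AGT", "S": "CG", "H": "ACT"}


def window_matches(seq: str, i: int, pattern: str) -> bool:
    """Does ``pattern`` (IUPAC) start at 0-based ``i`` of ``seq``?"""
    if i < 0 or i + len(pattern) > len(seq):
        return False
    return all(seq[i + k] in IUPAC[p] for k, p in enumerate(pattern))


def oracle_scan(seq: str) -> set[tuple[int, str, str]]:
    """Naive both-strand recognition-site scan.

    Plus strand directly; minus strand by scanning the reverse complement
    and mapping coordinates back.  Returns (pos_1based, strand, class).
    """
    out = set()
    for i in range(len(seq)):
        if window_matches(seq, i - 1, "CC"):
            out.add((i + 1, "+", "CmC"))        # mC = second C
        if window_matches(seq, i, "CDS"):
            out.add((i + 1, "+", "mCDS"))
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n):
        if window_matches(rc, i - 1, "CC"):
            out.add((n - i, "-", "CmC"))
        if window_matches(rc, i, "CDS"):
            out.add((n - i, "-", "mCDS"))
    return out


def oracle_motif_counts(seq: str) -> tuple[int, int]:
    """Overlap-counting CCGG / CCWGG occurrences by naive windowing."""
    ccgg = sum(window_matches(seq, i, "CCGG") for i in range(len(seq)))
    ccwgg = sum(window_matches(seq, i, "CCWGG") for i in range(len(seq)))
    return ccgg, ccwgg


def oracle_context_coverage(seq: str) -> tuple[float | None, float | None]:
    """Per-cytosine context classification on both strands, coverage by
    naive occurrence span lists."""
    n = len(seq)
    ccgg_spans = [(i, i + 3) for i in range(n) if window_matches(seq, i, "CCGG")]
    ccwgg_spans = [(i, i + 4) for i in range(n) if window_matches(seq, i, "CCWGG")]

    def covered(pos0, spans):
        return any(a <= pos0 <= b for a, b in spans)

    rc = revcomp(seq)
    cg, cg_in, chg, chg_in = 0, 0, 0, 0
    # cytosines on + strand
    for i in range(n):
        if seq[i] != "C":
            continue
        if window_matches(seq, i, "CG"):
            cg += 1
            cg_in += covered(i, ccgg_spans)
        elif window_matches(seq, i, "CHG"):
            chg += 1
            chg_in += covered(i, ccwgg_spans)
    # cytosines on - strand: classify on the reverse complement
    for i in range(n):
        if rc[i] != "C":
            continue
        pos0 = n - 1 - i  # genome coordinate of this cytosine
        if window_matches(rc, i, "CG"):
            cg += 1
            cg_in += covered(pos0, ccgg_spans)
        elif window_matches(rc, i, "CHG"):
            chg += 1
            chg_in += covered(pos0, ccwgg_spans)
    return (cg_in / cg if cg else None, chg_in / chg if chg else None)


def random_sequence(rng: np.random.Generator, length: int, with_n=False) -> str:
    alphabet = list("ACGTN") if with_n else list("ACGT")
    probs = [0.23, 0.25, 0.25, 0.23, 0.04] if with_n else None
    return "".join(rng.choice(alphabet, size=length, p=probs))


def oracle_gene_assignment(sites, genes, flank=2000):
    """All-pairs interval containment with strand-aware zones."""
    rows = []
    for _, s in sites.iterrows():
        for g in genes:
            if g.contig != s.contig:
                continue
            if not (g.start - flank <= s.pos <= g.end + flank):
                continue
            if g.start <= s.pos <= g.end:
                zone = "body"
            elif s.pos < g.start:
                zone = "upstream_2kb" if g.strand == "+" else "downstream_2kb"
            else:
                zone = "downstream_2kb" if g.strand == "+" else "upstream_2kb"
            if g.strand == "+":
                promoter = g.start - flank <= s.pos < g.start
            else:
                promoter = g.end < s.pos <= g.end + flank
            rows.append((s.contig, int(s.pos), s.strand, g.gene_id, zone, promoter))
    return sorted(rows)


# ---------------------------------------------------------------------------
# shared synthetic pipeline (session-scoped: several suites reuse it)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tag_pipeline():
    """A full simulate -> filter -> call -> matrix run on a 20 kb genome."""
    from methylrad.digest import scan_recognition_sites
    from methylrad.simulate import (
        SimConfig, assign_methylation_states, simulate_genome, simulate_tags,
        tags_to_alignments,
    )
    from methylrad.sites import (
        GeometryIndex, build_count_matrix, call_sites, coverage_filter,
        filter_tags,
    )

    cfg = SimConfig(seed=3, genome_length=20_000, n_planted_ccgg=30,
                    n_planted_ccwgg=30)
    genome, planted = simulate_genome(cfg)
    catalog = scan_recognition_sites(genome)
    truth = assign_methylation_states(catalog, cfg)
    tags = simulate_tags(truth, genome, cfg)
    alignments = tags_to_alignments(tags)
    index = GeometryIndex(catalog)
    kept, fstats = filter_tags(alignments, index)
    calls = call_sites(kept, catalog, index=index)
    matrix = build_count_matrix(calls, cfg.sample_sheet(), catalog)
    filtered = coverage_filter(matrix)
    return dict(
        cfg=cfg, genome=genome, planted=planted, catalog=catalog, truth=truth,
        tags=tags, alignments=alignments, index=index, kept=kept,
        fstats=fstats, calls=calls, matrix=matrix, filtered=filtered,
    )
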