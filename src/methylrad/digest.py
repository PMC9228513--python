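"""In silico FspEI digestion: recognition-site catalogue, cut geometry,
fragment prediction and genome context statistics.

The enzyme model
----------------
FspEI is a Type IIS methylation-dependent restriction enzyme.  It
recognises a modified cytosine in two sequence contexts on either strand:

* ``CmC``  — the methylated cytosine is the *second* C of a CC dinucleotide;
* ``mCDS`` — the methylated cytosine is followed by D = [A/G/T] and then
  S = [C/G].

Having bound a methylcytosine, the enzyme cuts at a fixed distance on the
3' side of the mC: ``D1`` nucleotides away on the mC's own strand and
``D2 = D1 + 4`` on the opposite strand, leaving 4-nt 5' overhangs.  The
offsets are calibrated constants (see :data:`DEFAULT_GEOMETRY`): they are
chosen so that double digestion of a CCGG site methylated on both strands
releases a 32 nt top-strand fragment, the single geometric anchor the
protocol reports.  The same arithmetic makes the CCWGG fragment 31 nt
(the bottom-strand mC of CCWGG sits one base further 3', which moves the
left-hand cut 1 bp to the right).

Self-reverse-complementary motifs CCGG and CC[A/T]GG are the two contexts
in which symmetric (both-strand) methylation is detectable; their internal
cytosines carry a ``symmetric_context`` annotation in the catalogue.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Genome
from ._util import truncate

MOTIF_CMC = "CmC"
MOTIF_MCDS = "mCDS"

#: IUPAC degeneracies used by the recognition model.
IUPAC = {"W": "AT", "D": "AGT", "S": "CG", "H": "ACT"}

# Lookahead regexes (lookahead so that overlapping occurrences all count).
# Minus-strand patterns are the reverse complements projected onto the top
# strand; the captured coordinate is that of the recognisable cytosine.
_RE_CMC_PLUS = re.compile(r"(?=CC)")          # mC = second C, at match+1 (0-based)
_RE_CMC_MINUS = re.compile(r"(?=GG)")         # bottom-strand CC; mC at match+0
_RE_MCDS_PLUS = re.compile(r"(?=C[AGT][CG])")   # mC at match+0
_RE_MCDS_MINUS = re.compile(r"(?=[CG][ACT]G)")  # bottom-strand CDS; mC at match+2
_RE_CCGG = re.compile(r"(?=CCGG)")
_RE_CCWGG = re.compile(r"(?=CC[AT]GG)")
_RE_CG = re.compile(r"(?=CG)")
_RE_CHG_PLUS = re.compile(r"(?=C[ACT]G)")
_RE_CHG_MINUS = re.compile(r"(?=C[AGT]G)")    # revcomp of CHG is CDG


@dataclass(frozen=True)
class CutGeometry:
    """FspEI cut offsets, in nt 3' of the methylcytosine.

    ``top_offset`` (D1) is the distance to the cut on the mC's own strand,
    ``bottom_offset`` (D2) on the opposite strand; D2 - D1 = 4 is the
    Type IIS 4-nt stagger.
    """

    top_offset: int = 14
    bottom_offset: int = 18

    def __post_init__(self) -> None:
        if self.bottom_offset - self.top_offset != 4:
            raise ValueError("cut geometry must satisfy D2 - D1 = 4")

    @property
    def symmetric_fragment_lengths(self) -> tuple[int, int]:
        """Top-strand fragment lengths for double-digested CCGG and CCWGG.

        mC motif offsets (0-based): CCGG +1/-2, CCWGG +1/-3; length =
        D1 + D2 + (offset_plus - offset_minus) + 1.
        """
        d = self.top_offset + self.bottom_offset
        return (d, d - 1)  # CCGG, CCWGG


#: Calibrated so the symmetric CCGG fragment is exactly 32 nt:
#: 14 + 18 + (1 - 2) + 1 = 32.
DEFAULT_GEOMETRY = CutGeometry(top_offset=14, bottom_offset=18)

CATALOG_COLUMNS = ["contig", "pos", "strand", "motif_class", "symmetric_context"]


# ---------------------------------------------------------------------------
# recognition-site scan
# ---------------------------------------------------------------------------

def symmetric_occurrences(genome: Genome) -> pd.DataFrame:
    """All forward-strand CCGG / CCWGG occurrences with their paired mCs.

    Both motifs equal their own reverse complement, so scanning the top
    strand counts each double-stranded site exactly once.  Columns:
    contig, start (1-based first C), motif, plus_pos, minus_pos.
    """
    rows = []
    for contig, seq in genome.contigs.items():
        for m in _RE_CCGG.finditer(seq):
            j = m.start()  # 0-based
            rows.append((contig, j + 1, "CCGG", j + 2, j + 3))
        for m in _RE_CCWGG.finditer(seq):
            j = m.start()
            rows.append((contig, j + 1, "CCWGG", j + 2, j + 4))
    return pd.DataFrame(
        rows, columns=["contig", "start", "motif", "plus_pos", "minus_pos"]
    )


def scan_recognition_sites(genome: Genome) -> pd.DataFrame:
    """Catalogue every FspEI-recognisable cytosine of a genome.

    Returns one row per (contig, pos, strand, motif_class); a cytosine
    matching both classes yields one row per class.  ``pos`` is the 1-based
    top-strand coordinate of the recognisable cytosine (for minus-strand
    sites, of the G that pairs with it).  ``symmetric_context`` is CCGG or
    CCWGG for the two internal methylatable cytosines of each such
    occurrence (CCGG wins in the rare overlap), otherwise ``none``.
    """
    frames = []
    for contig, seq in genome.contigs.items():
        recs: list[tuple[int, str, str]] = []
        recs += [(m.start() + 2, "+", MOTIF_CMC) for m in _RE_CMC_PLUS.finditer(seq)]
        recs += [(m.start() + 1, "-", MOTIF_CMC) for m in _RE_CMC_MINUS.finditer(seq)]
        recs += [(m.start() + 1, "+", MOTIF_MCDS) for m in _RE_MCDS_PLUS.finditer(seq)]
        recs += [(m.start() + 3, "-", MOTIF_MCDS) for m in _RE_MCDS_MINUS.finditer(seq)]
        if not recs:
            continue
        df = pd.DataFrame(recs, columns=["pos", "strand", "motif_class"])
        df.insert(0, "contig", contig)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=CATALOG_COLUMNS)
    catalog = pd.concat(frames, ignore_index=True)

    context = {}
    occ = symmetric_occurrences(genome)
    # CCWGG first so that CCGG overwrites on (theoretical) overlap
    for motif in ("CCWGG", "CCGG"):
        for row in occ[occ.motif == motif].itertuples():
            context[(row.contig, row.plus_pos, "+")] = motif
            context[(row.contig, row.minus_pos, "-")] = motif
    keys = list(zip(catalog.contig, catalog.pos, catalog.strand))
    catalog["symmetric_context"] = [context.get(k, "none") for k in keys]
    catalog = catalog.sort_values(
        ["contig", "pos", "strand", "motif_class"], kind="mergesort"
    ).reset_index(drop=True)
    return catalog[CATALOG_COLUMNS]


def catalog_site_keys(catalog: pd.DataFrame) -> pd.DataFrame:
    """Distinct (contig, pos, strand) site keys of a catalogue, with the
    motif class (CmC preferred when a cytosine matches both) and context."""
    if catalog.empty:
        return pd.DataFrame(columns=CATALOG_COLUMNS)
    # CmC sorts before mCDS, so 'first' keeps CmC for dual-class cytosines
    dedup = (
        catalog.sort_values(["contig", "pos", "strand", "motif_class"], kind="mergesort")
        .drop_duplicates(["contig", "pos", "strand"], keep="first")
        .reset_index(drop=True)
    )
    return dedup[CATALOG_COLUMNS]


# ---------------------------------------------------------------------------
# genome context statistics
# ---------------------------------------------------------------------------

def site_density(total_length: int, n_sites: int) -> float | None:
    """Genome length / site count, truncated to 2 decimals (``None`` for
    an empty catalogue) — the convention for genome-wide site densities."""
    return truncate(total_length / n_sites, 2) if n_sites else None


def motif_density(total_length: int, n_motifs: int) -> int | None:
    """Genome length / motif count, truncated to integer bp."""
    return truncate(total_length / n_motifs) if n_motifs else None


def count_potential_sites(catalog: pd.DataFrame, genome: Genome) -> dict:
    """Number of distinct recognisable cytosine positions and their density
    (``density_bp`` = genome length / n_sites; ``None`` when empty)."""
    n_sites = len(catalog.drop_duplicates(["contig", "pos", "strand"]))
    return {"n_sites": n_sites, "density_bp": site_density(genome.total_length, n_sites)}


def count_symmetric_motifs(genome: Genome) -> dict:
    """Forward-strand CCGG / CCWGG occurrence counts and bp densities.

    Each motif equals its reverse complement, so forward counting counts
    each double-stranded site once; overlapping occurrences all count.
    Densities are genome length / count truncated to integer bp.
    """
    n_ccgg = n_ccwgg = 0
    for seq in genome.contigs.values():
        n_ccgg += sum(1 for _ in _RE_CCGG.finditer(seq))
        n_ccwgg += sum(1 for _ in _RE_CCWGG.finditer(seq))
    total = genome.total_length
    return {
        "n_CCGG": n_ccgg,
        "n_CCWGG": n_ccwgg,
        "density_CCGG": motif_density(total, n_ccgg),
        "density_CCWGG": motif_density(total, n_ccwgg),
    }


def context_coverage(genome: Genome) -> dict:
    """Fraction of CG-context cytosines inside CCGG occurrences, and of
    CHG-context cytosines inside CCWGG occurrences (both strands).

    A cytosine is "inside" an occurrence when its coordinate falls within
    the occurrence span.  Fractions are in [0, 1]; ``None`` when the
    genome has no cytosine in that context.
    """
    cg_total = cg_cov = chg_total = chg_cov = 0
    for seq in genome.contigs.values():
        n = len(seq)
        in_ccgg = np.zeros(n, dtype=bool)
        for m in _RE_CCGG.finditer(seq):
            in_ccgg[m.start() : m.start() + 4] = True
        in_ccwgg = np.zeros(n, dtype=bool)
        for m in _RE_CCWGG.finditer(seq):
            in_ccwgg[m.start() : m.start() + 5] = True

        # CG context: the C (+ strand) and the paired G (- strand cytosine)
        for m in _RE_CG.finditer(seq):
            j = m.start()
            for pos in (j, j + 1):
                cg_total += 1
                cg_cov += bool(in_ccgg[pos])
        # CHG context: + strand C at j (CHG), - strand cytosine at the G of CDG
        for m in _RE_CHG_PLUS.finditer(seq):
            chg_total += 1
            chg_cov += bool(in_ccwgg[m.start()])
        for m in _RE_CHG_MINUS.finditer(seq):
            chg_total += 1
            chg_cov += bool(in_ccwgg[m.start() + 2])
    return {
        "frac_CG_in_CCGG": cg_cov / cg_total if cg_total else None,
        "frac_CHG_in_CCWGG": chg_cov / chg_total if chg_total else None,
    }


# ---------------------------------------------------------------------------
# fragment prediction
# ---------------------------------------------------------------------------

FRAGMENT_COLUMNS = ["contig", "start", "end", "length", "symmetric"]


def cut_position(pos: int, strand: str, geometry: CutGeometry) -> int:
    """Top-strand coordinate after which this site's double-strand break
    falls (overhangs are ignored for length bookkeeping; a break after
    position c separates fragments ``[.., c]`` and ``[c+1, ..]``)."""
    if strand == "+":
        return pos + geometry.top_offset
    return pos - geometry.bottom_offset - 1


def predict_fragments(
    genome: Genome,
    catalog: pd.DataFrame,
    methylated: set | dict,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Digest the genome at every methylated catalogue site.

    ``methylated`` holds (contig, pos, strand) keys (a dict is read as
    key -> bool).  Each methylated site contributes one double-strand
    break; fragments are the maximal uncut intervals.  A fragment is
    flagged ``symmetric`` when its two flanking breaks are the pair of one
    CCGG/CCWGG occurrence methylated on both strands.
    """
    if isinstance(methylated, dict):
        methylated = {k for k, v in methylated.items() if v}
    else:
        methylated = set(methylated)
    known = set(
        zip(catalog.contig, catalog.pos, catalog.strand)
    )
    unknown = methylated - known
    if unknown:
        raise KeyError(f"methylation state for unknown sites: {sorted(unknown)[:3]}")

    # expected symmetric spans: both members of an occurrence methylated
    occ = symmetric_occurrences(genome)
    symmetric_spans = set()
    for row in occ.itertuples():
        if (row.contig, row.plus_pos, "+") in methylated and (
            row.contig, row.minus_pos, "-") in methylated:
            start = cut_position(row.minus_pos, "-", geometry) + 1
            end = cut_position(row.plus_pos, "+", geometry)
            symmetric_spans.add((row.contig, start, end))

    rows = []
    for contig, seq in genome.contigs.items():
        length = len(seq)
        cuts = sorted(
            {
                c
                for (ctg, pos, strand) in methylated
                if ctg == contig
                for c in (cut_position(pos, strand, geometry),)
                if 1 <= c < length
            }
        )
        bounds = [0] + cuts + [length]
        for left, right in zip(bounds[:-1], bounds[1:]):
            start, end = left + 1, right
            rows.append(
                (
                    contig,
                    start,
                    end,
                    end - start + 1,
                    (contig, start, end) in symmetric_spans,
                )
            )
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
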