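"""Methylation-site calling: turn tag alignments into a per-cytosine
count matrix.

A sequenced MethylRAD tag carries the enzyme's cut at one end (both ends
for symmetric-length tags).  A tag end is *validated* when it sits at a
geometry-consistent offset from a catalogued cytosine; validated ends
increment that cytosine's count.  Counting convention: counts are tag-end
increments, not fragment increments — one symmetric fragment contributes
to both of its flanking sites.

Attribution when an end validates more than one catalogue cytosine:
prefer the candidate whose cytosine lies on the tag, then the nearest
offset, and count once.  Orientation bookkeeping follows the front/end
dichotomy of the tag-type QC: ``front`` when the validating cut is at the
tag's 5' end, ``end`` when at its 3' end.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import CutGeometry, DEFAULT_GEOMETRY, catalog_site_keys
from .io import SampleSheet, TagAlignment

SITE_INDEX = ["contig", "pos", "strand"]


# ---------------------------------------------------------------------------
# count matrix container
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Methylation sites x samples tag-count table.

    ``counts`` is indexed by (contig, pos, strand) with one integer column
    per sample; ``groups`` maps sample -> female/male; ``site_info`` keeps
    the motif class and symmetric context of each row.
    """

    counts: pd.DataFrame
    groups: pd.Series
    site_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise KeyError(f"samples without group label: {missing}")
        self.counts = self.counts.rename_axis(columns=None)
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def site_keys(self) -> pd.Index:
        """Table-style ``contig_pos`` keys (one per row)."""
        return pd.Index(
            [f"{c}_{p}" for c, p, _ in self.counts.index], name="site"
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.reset_index()
        if self.site_info is not None:
            info = self.site_info.reset_index(drop=True)
            cols = [c for c in ("motif_class", "symmetric_context")
                    if c in info.columns]
            out = pd.concat([out[SITE_INDEX], info[cols], out[self.samples]],
                            axis=1)
        return out

    def to_tsv(self, path) -> None:
        from .io import write_table

        write_table(self.to_frame(), path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: pd.Series) -> "CountMatrix":
        samples = [c for c in df.columns if c in groups.index]
        info_cols = [c for c in ("motif_class", "symmetric_context") if c in df.columns]
        counts = df.set_index(SITE_INDEX)[samples].astype(int)
        info = df[SITE_INDEX + info_cols].set_index(SITE_INDEX) if info_cols else None
        return cls(counts=counts, groups=groups, site_info=info)

    @classmethod
    def from_tsv(cls, path, sheet: SampleSheet) -> "CountMatrix":
        from .io import read_table

        return cls.from_frame(read_table(path), sheet.groups)


# ---------------------------------------------------------------------------
# geometry-consistent end validation
# ---------------------------------------------------------------------------

@dataclass
class _Candidate:
    key: tuple
    offset: int


class GeometryIndex:
    """Lookup from a tag-end coordinate to the catalogue cytosines whose
    break geometry is consistent with a cut at that end.

    For a + strand mC at m the break falls after ``m + D1`` (top strand):
    a tag ending at ``m + D1`` or starting at ``m + D1 + 1`` abuts it.
    For a - strand mC at m the break falls after ``m - D2 - 1``: a tag
    starting at ``m - D2`` or ending at ``m - D2 - 1`` abuts it.
    """

    def __init__(self, catalog: pd.DataFrame, geometry: CutGeometry = DEFAULT_GEOMETRY):
        self.geometry = geometry
        sites = catalog_site_keys(catalog)
        self._by_right: dict[str, dict[int, list[_Candidate]]] = {}
        self._by_left: dict[str, dict[int, list[_Candidate]]] = {}
        d1, d2 = geometry.top_offset, geometry.bottom_offset
        for row in sites.itertuples():
            key = (row.contig, row.pos, row.strand)
            right = self._by_right.setdefault(row.contig, {})
            left = self._by_left.setdefault(row.contig, {})
            if row.strand == "+":
                right.setdefault(row.pos + d1, []).append(_Candidate(key, d1))
                left.setdefault(row.pos + d1 + 1, []).append(_Candidate(key, d1 + 1))
            else:
                left.setdefault(row.pos - d2, []).append(_Candidate(key, d2))
                right.setdefault(row.pos - d2 - 1, []).append(_Candidate(key, d2 + 1))

    def candidates(self, contig: str, coord: int, which: str) -> list[_Candidate]:
        table = self._by_right if which == "right" else self._by_left
        return table.get(contig, {}).get(coord, [])

    def end_validates(self, tag: TagAlignment) -> bool:
        return bool(
            self.candidates(tag.contig, tag.start, "left")
            or self.candidates(tag.contig, tag.end, "right")
        )

    def resolve(self, tag: TagAlignment, which: str) -> tuple | None:
        """Best site for the cut at one physical tag end, or None."""
        coord = tag.start if which == "left" else tag.end
        cands = self.candidates(tag.contig, coord, which)
        if not cands:
            return None
        def rank(c: _Candidate):
            on_tag = tag.start <= c.key[1] <= tag.end
            return (not on_tag, c.offset, c.key)
        return min(cands, key=rank).key


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

@dataclass
class FilterStats:
    per_sample: pd.DataFrame  # raw, kept, filtering_ratio

    @property
    def overall_ratio(self) -> float:
        raw = self.per_sample["raw"].sum()
        return float(self.per_sample["kept"].sum() / raw) if raw else float("nan")


def filter_tags(
    alignments: list[TagAlignment],
    index: GeometryIndex,
) -> tuple[list[TagAlignment], FilterStats]:
    """Remove tags without a restriction-site context.

    A tag is kept iff at least one of its ends abuts a geometry-consistent
    break of a catalogued cytosine.  The per-sample filtering ratio
    (kept / raw * 100) mirrors the library QC convention.
    """
    kept: list[TagAlignment] = []
    raw_n: dict[str, int] = {}
    kept_n: dict[str, int] = {}
    for tag in alignments:
        raw_n[tag.sample_id] = raw_n.get(tag.sample_id, 0) + 1
        if index.end_validates(tag):
            kept.append(tag)
            kept_n[tag.sample_id] = kept_n.get(tag.sample_id, 0) + 1
    samples = sorted(raw_n)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "raw": [raw_n[s] for s in samples],
            "kept": [kept_n.get(s, 0) for s in samples],
        }
    )
    df["filtering_ratio"] = 100.0 * df["kept"] / df["raw"]
    return kept, FilterStats(per_sample=df)


def call_sites(
    alignments: list[TagAlignment],
    catalog: pd.DataFrame,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
    index: GeometryIndex | None = None,
) -> pd.DataFrame:
    """Per-(site, sample) tag-end counts from filtered alignments.

    Symmetric-length tags (the full double-digestion fragment) have cuts at
    both ends and increment both flanking sites; longer tags carry the cut
    at their 5' end only.  Returns a long-format frame with columns
    contig, pos, strand, sample_id, orientation, count; tag ends that
    validate no catalogue site are dropped (counted in attrs['n_dropped']).
    """
    if index is None:
        index = GeometryIndex(catalog, geometry)
    sym_lengths = set(index.geometry.symmetric_fragment_lengths)
    counts: dict[tuple, int] = {}
    dropped = 0
    for tag in alignments:
        if tag.length in sym_lengths:
            ends = ["left", "right"]
        else:
            ends = ["left" if tag.strand == "+" else "right"]
        hit_any = False
        for which in ends:
            key = index.resolve(tag, which)
            if key is None:
                continue
            hit_any = True
            five_prime = (which == "left") == (tag.strand == "+")
            orientation = "front" if five_prime else "end"
            k = key + (tag.sample_id, orientation)
            counts[k] = counts.get(k, 0) + 1
        if not hit_any:
            dropped += 1
    rows = [
        (ctg, pos, strand, sample, orient, n)
        for (ctg, pos, strand, sample, orient), n in counts.items()
    ]
    out = pd.DataFrame(
        rows,
        columns=["contig", "pos", "strand", "sample_id", "orientation", "count"],
    ).sort_values(["contig", "pos", "strand", "sample_id", "orientation"],
                  kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def build_count_matrix(
    calls: pd.DataFrame,
    sheet: SampleSheet,
    catalog: pd.DataFrame | None = None,
) -> CountMatrix:
    """Pivot per-(site, sample) calls into a :class:`CountMatrix`.

    Site rows are the union of called sites over samples (missing
    observations are 0), ordered by (contig, pos, strand); columns follow
    the sample sheet.  When the catalogue is supplied, motif class and
    symmetric context are attached to each row.
    """
    unknown = set(calls.sample_id.unique()) - set(sheet.samples)
    if unknown:
        raise KeyError(f"samples absent from sample sheet: {sorted(unknown)}")
    if calls.empty:
        counts = pd.DataFrame(
            columns=sheet.samples,
            index=pd.MultiIndex.from_arrays([[], [], []], names=SITE_INDEX),
        )
        return CountMatrix(counts=counts.astype(int), groups=sheet.groups)
    wide = (
        calls.groupby(SITE_INDEX + ["sample_id"], sort=True)["count"]
        .sum()
        .unstack("sample_id", fill_value=0)
        .reindex(columns=sheet.samples, fill_value=0)
        .astype(int)
    )
    wide = wide.sort_index()
    info = None
    if catalog is not None:
        sites = catalog_site_keys(catalog).set_index(SITE_INDEX)
        info = sites.reindex(wide.index)
    return CountMatrix(counts=wide, groups=sheet.groups, site_info=info)


def coverage_filter(
    matrix: CountMatrix, min_reads: int = 3, min_samples: int = 3
) -> CountMatrix:
    """Retain sites detected with >= ``min_reads`` reads in at least
    ``min_samples`` samples (counted over all samples, before the group
    comparison).  Row order is preserved."""
    if min_reads < 1 or min_samples < 1:
        raise ValueError("thresholds must be >= 1")
    ok = (matrix.counts >= min_reads).sum(axis=1) >= min_samples
    info = matrix.site_info[ok.values] if matrix.site_info is not None else None
    return CountMatrix(
        counts=matrix.counts[ok.values], groups=matrix.groups, site_info=info
    )


# ---------------------------------------------------------------------------
# QC distributions
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Tag-length and site-type distributions plus per-sample tallies."""

    per_sample: pd.DataFrame
    length_hist: pd.Series
    symmetric_length_fraction: float
    class_orientation: pd.DataFrame  # motif_class x orientation fractions
    symmetric_site_fraction: float
    pca: pd.DataFrame | None = None


def qc_distributions(
    alignments: list[TagAlignment],
    calls: pd.DataFrame,
    matrix: CountMatrix,
    stats: FilterStats,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> QCReport:
    lengths = pd.Series([t.length for t in alignments], dtype=int)
    hist = lengths.value_counts().sort_index()
    sym = set(geometry.symmetric_fragment_lengths)
    sym_frac = float(lengths.isin(sym).mean()) if len(lengths) else 0.0

    if len(calls) and matrix.site_info is not None:
        info = matrix.site_info.reset_index()
        merged = calls.merge(info, on=SITE_INDEX, how="left")
        tab = (
            merged.groupby(["motif_class", "orientation"])["count"].sum().unstack(
                fill_value=0
            )
        )
        frac = tab / tab.values.sum()
    else:
        frac = pd.DataFrame()

    if matrix.n_sites and matrix.site_info is not None:
        site_sym = float((matrix.site_info["symmetric_context"] != "none").mean())
    else:
        site_sym = 0.0

    return QCReport(
        per_sample=stats.per_sample,
        length_hist=hist,
        symmetric_length_fraction=sym_frac,
        class_orientation=frac,
        symmetric_site_fraction=site_sym,
    )
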