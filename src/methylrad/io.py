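"""Readers and writers for the standard formats the pipeline touches.

Coordinate contract
-------------------
All coordinates inside the package are **1-based and inclusive** on both
ends, matching the ``contig_position`` site keys the pipeline reports.
Conversions to and from 0-based half-open conventions (BED, pysam) happen
only inside the readers/writers in this module, never downstream.

Formats handled here: FASTA (genome), GFF3/BED (gene models), SAM/BAM or a
plain TSV dialect (tag alignments), the sample sheet, and generic TSV
tables for every internal record type.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

_VALID_BASES = re.compile(r"[^ACGTN]")
GROUP_LABELS = ("female", "male")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """An in-memory reference genome: ordered map contig id -> sequence.

    Sequences are uppercase over {A, C, G, T, N}; N bases are retained but
    never take part in motif matches.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = _VALID_BASES.search(seq)
            if bad:
                raise FormatError(
                    f"contig {name!r}: illegal character {bad.group()!r} "
                    f"at position {bad.start() + 1}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class GeneModel:
    """A gene span: 1-based inclusive coordinates, stranded."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class TagAlignment:
    """A mapped sequencing tag: 1-based inclusive span on the top strand."""

    sample_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"tag {self.sample_id}:{self.contig}: end < start")
        if self.strand not in ("+", "-"):
            raise FormatError(f"tag: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleSheet:
    """Per-sample group labels (female/male) and optional tissue label."""

    groups: "pd.Series"  # sample_id -> group label
    tissue: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.groups.index.duplicated().any():
            dups = self.groups.index[self.groups.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        bad = set(self.groups) - set(GROUP_LABELS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        for label in GROUP_LABELS:
            if (self.groups == label).sum() < 1:
                raise FormatError(f"no samples in group {label!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.groups.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# coordinate conversion (format boundaries only)
# ---------------------------------------------------------------------------

def zero_to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """BED-style half-open 0-based -> internal 1-based inclusive."""
    return start0 + 1, end0


def one_to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED-style half-open 0-based."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Lowercase input is folded to uppercase; multi-line records are joined.
    Structural errors are reported with their line number.  This reader is
    deliberately strict (line-numbered diagnostics, {ACGTN} alphabet), which
    is why it is bespoke rather than delegated.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is not None:
            contigs[name] = "".join(chunks)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()
                if not header:
                    raise FormatError(f"{path.name} line {lineno}: empty FASTA header")
                _flush()
                name = header[0]
                if name in contigs:
                    raise FormatError(
                        f"{path.name} line {lineno}: duplicate contig id {name!r}"
                    )
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path.name} line {lineno}: sequence before first '>' header"
                    )
                chunks.append(line.upper())
    _flush()
    if not contigs:
        raise FormatError(f"{path.name} line 1: empty FASTA file")
    return Genome(contigs)  # Genome validates the alphabet


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(tags: pd.DataFrame, path: str | Path) -> None:
    """Write simulated tags (columns read_id, seq) as FASTQ, quality 'I'."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = (
        SeqRecord(
            Seq(row.seq),
            id=str(row.read_id),
            description="",
            letter_annotations={"phred_quality": [40] * len(row.seq)},
        )
        for row in tags.itertuples()
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, dialect: str) -> list[GeneModel]:
    """Read gene models from GFF3 or BED.

    GFF3 coordinates are already 1-based inclusive and only records of type
    ``gene`` are retained.  BED half-open 0-based coordinates are converted;
    BED files with fewer than 6 columns default to the + strand.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3_genes(path)
    if dialect == "bed12":
        return _read_bed_genes(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r} (expected gff3/bed12)")


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise FormatError(f"gene {feat.id}: end < start in {path.name}")
        name = feat.attributes.get("Name", [None])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
                name=name,
            )
        )
    return genes


def _read_bed_genes(path: Path) -> list[GeneModel]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise FormatError(f"{path.name}: BED requires at least 3 columns")
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        start0, end0 = int(row[1]), int(row[2])
        if end0 <= start0:
            raise FormatError(f"{path.name} record {i + 1}: end <= start")
        start, end = zero_to_one_based(start0, end0)
        gene_id = str(row[3]) if df.shape[1] > 3 else f"gene{i + 1}"
        strand = str(row[5]) if df.shape[1] > 5 else "+"
        genes.append(
            GeneModel(gene_id=gene_id, contig=str(row[0]), start=start, end=end,
                      strand=strand)
        )
    return genes


# ---------------------------------------------------------------------------
# tag alignments
# ---------------------------------------------------------------------------

TAG_TSV_COLUMNS = ["sample_id", "contig", "start", "end", "strand"]


def read_tag_alignments(
    path: str | Path,
    dialect: str,
    sample_id: str | None = None,
) -> tuple[list[TagAlignment], int]:
    """Read mapped tags; returns ``(alignments, n_skipped)``.

    For SAM/BAM, unmapped/secondary/supplementary records are skipped and
    counted.  ``sample_id`` overrides the read-group SM tag (falls back to
    the file stem).  The TSV dialect carries its own sample_id column:
    ``sample_id  contig  start  end  strand`` with 1-based inclusive spans.
    """
    path = Path(path)
    if dialect in ("sam", "bam"):
        return _read_sam(path, dialect, sample_id)
    if dialect == "tsv":
        return _read_tag_tsv(path)
    raise ValueError(f"unknown alignment dialect {dialect!r} (expected sam/bam/tsv)")


def _read_sam(path: Path, dialect: str, sample_id: str | None) -> tuple[list[TagAlignment], int]:
    import pysam

    mode = "rb" if dialect == "bam" else "r"
    skipped = 0
    out: list[TagAlignment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if sample_id is None:
            rgs = fh.header.to_dict().get("RG", [])
            sample_id = rgs[0].get("SM", path.stem) if rgs else path.stem
        for i, read in enumerate(fh):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped += 1
                continue
            try:
                start = read.reference_start + 1          # 0-based -> 1-based
                end = read.reference_end                  # half-open -> inclusive
                out.append(
                    TagAlignment(
                        sample_id=sample_id,
                        contig=read.reference_name,
                        start=start,
                        end=end,
                        strand="-" if read.is_reverse else "+",
                    )
                )
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path.name} record {i + 1}: {exc}") from exc
    return out, skipped


def _read_tag_tsv(path: Path) -> tuple[list[TagAlignment], int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TAG_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                TagAlignment(
                    sample_id=str(row.sample_id),
                    contig=str(row.contig),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path.name} record {i + 1}: {exc}") from exc
    return out, 0


def alignments_to_frame(alignments: Iterable[TagAlignment]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(a.sample_id, a.contig, a.start, a.end, a.strand) for a in alignments],
        columns=TAG_TSV_COLUMNS,
    )
    return df


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Sample sheet TSV: columns ``sample_id``, ``group`` [, ``tissue``]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    groups = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    tissue = (
        dict(zip(df["sample_id"], df["tissue"])) if "tissue" in df.columns else {}
    )
    return SampleSheet(groups=groups, tissue=tissue)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": sheet.samples,
            "group": sheet.groups.values,
            "tissue": [sheet.tissue.get(s, "synthetic") for s in sheet.samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

_SORT_CANDIDATES = ("contig", "pos", "position", "start", "end", "strand",
                    "site", "gene_id", "sample_id")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as TSV: header row, UTF-8, deterministic order.

    Rows are sorted by the genomic columns present (contig, position,
    strand, ...) so that writing the same records twice — in any input
    order — produces byte-identical files.
    """
    keys = [c for c in _SORT_CANDIDATES if c in df.columns]
    out = df.sort_values(keys, kind="mergesort") if keys else df
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
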