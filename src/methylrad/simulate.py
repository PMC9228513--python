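"""Synthetic genomes, methylomes, tag sets and count matrices.

The generator emulates the statistical structure the analysis assumes: a
genome with planted CCGG/CCWGG motifs, two groups of three samples, and
per-site tag counts that are negative-binomially distributed with the
methylation level acting linearly on expected coverage (MethylRAD counts
are methylation-level proxies; no bisulfite-style per-read conversion is
modelled).

Determinism: every operation draws from its own pseudo-random stream
derived from the master seed by a fixed offset, so regenerating one
artifact never perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import (
    CutGeometry,
    DEFAULT_GEOMETRY,
    catalog_site_keys,
    cut_position,
    symmetric_occurrences,
)
from .io import Genome, GeneModel, SampleSheet
from .sites import CountMatrix, SITE_INDEX
from ._util import revcomp

_STREAM = {"genome": 11, "methylome": 23, "counts": 37, "tags": 53,
           "genes": 67, "expression": 79}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation conditions.

    Defaults mirror the study design: 2 groups x 3 samples, ~20,000
    catalogue sites (100 kb at GC 0.42), mean coverage mu=20 tags per
    fully methylated site, NB dispersion phi=0.15, 5% differential sites
    at |log2 fold change| = 2, Beta(2, 2) baseline methylation.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_contigs: int = 2
    gc_content: float = 0.42
    n_planted_ccgg: int = 100
    n_planted_ccwgg: int = 100
    n_samples_per_group: int = 3
    mean_coverage: float = 20.0
    dispersion: float = 0.15
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    frac_differential: float = 0.05
    effect_log2fc: float = 2.0
    library_size_factors: tuple[float, ...] | None = None
    decoy_fraction: float = 0.1
    hemi_tag_length: int = 150

    def __post_init__(self) -> None:
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must be in [0, 1]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.hemi_tag_length <= 40:
            # must not collide with symmetric fragment lengths (31/32 nt)
            raise ValueError("hemi_tag_length must be > 40")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    def sample_ids(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"M{i + 1}" for i in range(n)] + [f"F{i + 1}" for i in range(n)]

    def sample_sheet(self) -> SampleSheet:
        n = self.n_samples_per_group
        groups = pd.Series(
            ["male"] * n + ["female"] * n, index=self.sample_ids(), name="group"
        )
        return SampleSheet(groups=groups)

    def size_factors(self) -> np.ndarray:
        if self.library_size_factors is not None:
            f = np.asarray(self.library_size_factors, dtype=float)
            if len(f) != self.n_samples:
                raise ValueError("library_size_factors length != number of samples")
            return f
        return np.linspace(0.85, 1.15, self.n_samples)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[Genome, pd.DataFrame]:
    """I.i.d. bases at the configured GC content with exact CCGG/CCWGG
    motifs planted at recorded, non-overlapping positions.

    Returns the genome and a table of planted motifs (contig, start,
    motif) with 1-based starts.
    """
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = _rng(config, "genome")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))

    contig_len = config.genome_length // config.n_contigs
    names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    plant_total = config.n_planted_ccgg + config.n_planted_ccwgg
    if plant_total * 10 > config.genome_length:
        raise ValueError("too many planted motifs for this genome length")

    contigs: dict[str, str] = {}
    planted_rows = []
    # spread plants round-robin over contigs
    plants = ["CCGG"] * config.n_planted_ccgg + ["CCWGG"] * config.n_planted_ccwgg
    per_contig: dict[str, list[str]] = {n: [] for n in names}
    for i, motif in enumerate(plants):
        per_contig[names[i % len(names)]].append(motif)

    for name in names:
        seq = rng.choice(bases, size=contig_len, p=probs)
        taken: list[tuple[int, int]] = []
        for motif in per_contig[name]:
            word = motif if motif == "CCGG" else "CC" + rng.choice(["A", "T"]) + "GG"
            placed = False
            for _ in range(1000):
                start0 = int(rng.integers(50, contig_len - 50 - len(word)))
                if all(start0 + len(word) + 2 <= a or start0 >= b + 2 for a, b in taken):
                    seq[start0 : start0 + len(word)] = list(word)
                    taken.append((start0, start0 + len(word)))
                    planted_rows.append((name, start0 + 1, motif))
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place planted motifs without overlap")
        contigs[name] = "".join(seq)
    planted = pd.DataFrame(planted_rows, columns=["contig", "start", "motif"])
    return Genome(contigs), planted


# ---------------------------------------------------------------------------
# methylome truth
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = SITE_INDEX + [
    "symmetric_context", "unit", "m_female", "m_male", "differential",
    "true_direction",
]


def assign_methylation_states(catalog: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth methylome for every catalogue site.

    Baseline level ~ Beta(a, b), shared by the groups.  A seeded fraction
    of *units* is differential: the lower group's level is the baseline
    divided by ``2**effect_log2fc`` (direction Bernoulli(0.5)), so the
    true |log2 ratio| equals the configured effect except where the
    [0.01, 0.99] clip binds.  The two strand-cytosines of one CCGG/CCWGG
    occurrence form a single unit and share their state, since symmetric
    methylation is what releases their common fragment.
    """
    if catalog.empty:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    rng = _rng(config, "methylome")
    sites = catalog_site_keys(catalog).copy()

    # unit = symmetric occurrence for paired cytosines, else the site itself
    unit_of: dict[tuple, str] = {}
    for row in sites.itertuples():
        key = (row.contig, row.pos, row.strand)
        unit_of[key] = f"{row.contig}:{row.pos}:{row.strand}"
    ctx = sites.set_index(SITE_INDEX)["symmetric_context"]
    sym_keys = set(ctx.index[ctx != "none"])
    # resolve pairs from context annotation: CCGG pairs sit 1 bp apart,
    # CCWGG pairs 2 bp apart (plus member first)
    plus_keys = sorted(k for k in sym_keys if k[2] == "+")
    minus_keys = set(k for k in sym_keys if k[2] == "-")
    for contig, pos, _ in plus_keys:
        for delta, motif in ((1, "CCGG"), (2, "CCWGG")):
            mk = (contig, pos + delta, "-")
            if mk in minus_keys and ctx.get((contig, pos, "+")) == ctx.get(mk):
                unit = f"{contig}:occ{pos}"
                unit_of[(contig, pos, "+")] = unit
                unit_of[mk] = unit
                break

    sites["unit"] = [unit_of[(r.contig, r.pos, r.strand)] for r in sites.itertuples()]
    units = sites["unit"].unique()
    a, b = config.baseline_beta
    base = np.clip(rng.beta(a, b, size=len(units)), 0.01, 0.99)
    diff = rng.random(len(units)) < config.frac_differential
    if config.effect_log2fc == 0:
        diff[:] = False
    female_high = rng.random(len(units)) < 0.5

    # the high group keeps the baseline, the low group is divided by the
    # fold change; when the 0.01 floor binds, both levels are lifted so the
    # exact |log2 ratio| = effect invariant always holds
    factor = 2.0 ** (-config.effect_log2fc)
    low = np.maximum(base * factor, 0.01)
    high = low / factor
    m_f = np.where(diff & female_high, high, np.where(diff, low, base))
    m_m = np.where(diff & ~female_high, high, np.where(diff, low, base))
    diff = diff & (m_f != m_m)
    direction = np.where(
        ~diff, "none", np.where(female_high, "higher-in-female", "higher-in-male")
    )

    lut = pd.DataFrame(
        {"unit": units, "m_female": m_f, "m_male": m_m, "differential": diff,
         "true_direction": direction}
    )
    truth = sites.merge(lut, on="unit", how="left")
    return truth[TRUTH_COLUMNS]


def abstract_catalog(n_sites: int, contig: str = "chr1") -> pd.DataFrame:
    """A catalogue of ``n_sites`` stand-alone CmC sites at spaced positions.

    For count-model studies that need no genome sequence (dispersion
    recovery, null calibration): every site is its own unit, no symmetric
    context."""
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": 10 * (np.arange(n_sites) + 1),
            "strand": "+",
            "motif_class": "CmC",
            "symmetric_context": "none",
        }
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draws(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) draws; phi=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if phi <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        size = 1.0 / phi
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(truth: pd.DataFrame, config: SimConfig) -> CountMatrix:
    """Per-site per-sample NB tag counts from the truth methylome.

    count(site s, sample j of group g) ~ NB(mean = factor_j * mu * m_g(s),
    dispersion phi), independent across sites and samples.
    """
    rng = _rng(config, "counts")
    sheet = config.sample_sheet()
    factors = config.size_factors()
    levels = {
        "male": truth["m_male"].to_numpy(float),
        "female": truth["m_female"].to_numpy(float),
    }
    cols = {}
    for j, sample in enumerate(sheet.samples):
        g = sheet.groups[sample]
        mean = factors[j] * config.mean_coverage * levels[g]
        cols[sample] = _nb_draws(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.MultiIndex.from_frame(truth[SITE_INDEX]))
    info = truth[SITE_INDEX + ["symmetric_context"]].set_index(SITE_INDEX)
    return CountMatrix(counts=counts, groups=sheet.groups, site_info=info)


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

TAG_COLUMNS = ["read_id", "sample_id", "contig", "start", "end", "strand",
               "seq", "is_decoy", "source"]


def _site_label(contig: str, pos: int, strand: str) -> str:
    return f"{contig}:{pos}:{strand}"


def simulate_tags(
    truth: pd.DataFrame,
    genome: Genome,
    config: SimConfig,
    geometry: CutGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Emit sequencing tags for a truth methylome.

    Symmetric units (both-strand methylated CCGG/CCWGG) emit NB-distributed
    copies of their exact 32/31 nt double-digestion fragment; hemi sites
    emit 150 nt single-cut tags on the methylcytosine side of the break.
    A configurable fraction of decoy tags is drawn from positions without
    any restriction-site context, to exercise the read filter.
    """
    rng = _rng(config, "tags")
    sheet = config.sample_sheet()
    factors = config.size_factors()
    d1, d2 = geometry.top_offset, geometry.bottom_offset
    occ = symmetric_occurrences(genome)
    pair_of = {}
    for row in occ.itertuples():
        pair_of[(row.contig, row.plus_pos, "+")] = (row.contig, row.minus_pos, "-")

    rows = []
    rid = 0

    def emit(sample, contig, start, end, strand, source="", decoy=False):
        nonlocal rid
        rid += 1
        seq = genome.contigs[contig][start - 1 : end]
        if strand == "-":
            seq = revcomp(seq)
        rows.append(
            (f"tag{rid}", sample, contig, start, end, strand, seq, decoy, source)
        )

    truth_idx = truth.set_index(SITE_INDEX)
    done_pairs = set()
    for row in truth.itertuples():
        key = (row.contig, row.pos, row.strand)
        contig_len = len(genome.contigs[row.contig])
        level = {"male": row.m_male, "female": row.m_female}
        if row.symmetric_context != "none":
            if key in done_pairs:
                continue
            mate = pair_of.get(key)
            if mate is None:  # minus member; handled via its plus partner
                continue
            done_pairs.add(key)
            done_pairs.add(mate)
            start = cut_position(mate[1], "-", geometry) + 1
            end = cut_position(row.pos, "+", geometry)
            if start < 1 or end > contig_len:
                continue
            source = (
                _site_label(row.contig, row.pos, "+")
                + ","
                + _site_label(*mate)
            )
            for j, sample in enumerate(sheet.samples):
                g = sheet.groups[sample]
                n = _nb_draws(
                    rng,
                    np.array([factors[j] * config.mean_coverage * level[g]]),
                    config.dispersion,
                )[0]
                for _ in range(n):
                    strand = "+" if rng.random() < 0.5 else "-"
                    emit(sample, row.contig, start, end, strand, source)
        else:
            cut = cut_position(row.pos, row.strand, geometry)
            L = config.hemi_tag_length
            # tag on the methylcytosine side of the break; sites whose tag
            # would run off the contig are not sequenced
            if row.strand == "+":
                start, end, strand = cut - L + 1, cut, "-"
            else:
                start, end, strand = cut + 1, cut + L, "+"
            if start < 1 or end > contig_len:
                continue
            source = _site_label(row.contig, row.pos, row.strand)
            for j, sample in enumerate(sheet.samples):
                g = sheet.groups[sample]
                n = _nb_draws(
                    rng,
                    np.array([factors[j] * config.mean_coverage * level[g]]),
                    config.dispersion,
                )[0]
                for _ in range(n):
                    emit(sample, row.contig, start, end, strand, source)

    # decoys: random spans whose ends validate no catalogue break
    n_real = len(rows)
    f = config.decoy_fraction
    if f > 0 and n_real:
        from .sites import GeometryIndex
        from .digest import scan_recognition_sites

        index = GeometryIndex(scan_recognition_sites(genome), geometry)
        n_decoys = int(round(n_real * f / (1 - f)))
        contigs = list(genome.contigs)
        samples = sheet.samples
        made = 0
        attempts = 0
        while made < n_decoys and attempts < 200 * n_decoys:
            attempts += 1
            contig = contigs[int(rng.integers(len(contigs)))]
            clen = len(genome.contigs[contig])
            start = int(rng.integers(1, clen - config.hemi_tag_length))
            end = start + config.hemi_tag_length - 1
            from .io import TagAlignment

            probe = TagAlignment(
                sample_id="x", contig=contig, start=start, end=end, strand="+"
            )
            if index.end_validates(probe):
                continue
            sample = samples[int(rng.integers(len(samples)))]
            strand = "+" if rng.random() < 0.5 else "-"
            emit(sample, contig, start, end, strand, decoy=True)
            made += 1

    return pd.DataFrame(rows, columns=TAG_COLUMNS)


def tags_to_alignments(tags: pd.DataFrame) -> list:
    """Truth tag table -> TagAlignment list (what a mapper would return)."""
    from .io import TagAlignment

    return [
        TagAlignment(
            sample_id=row.sample_id, contig=row.contig, start=int(row.start),
            end=int(row.end), strand=row.strand,
        )
        for row in tags.itertuples()
    ]


# ---------------------------------------------------------------------------
# gene models and expression (for the annotation/integration stages)
# ---------------------------------------------------------------------------

def simulate_gene_models(
    genome: Genome, config: SimConfig, n_genes: int = 40,
    gene_length: tuple[int, int] = (1000, 4000),
) -> list[GeneModel]:
    """Non-overlapping stranded gene spans scattered over the genome."""
    rng = _rng(config, "genes")
    genes: list[GeneModel] = []
    gid = 0
    per_contig = max(1, n_genes // max(1, len(genome.contigs)))
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        margin = min(2100, max(10, clen // 10))
        hi = max(50, min(gene_length[1], clen - 2 * margin - 1))
        lo = min(gene_length[0], hi - 1)
        taken: list[tuple[int, int]] = []
        for _ in range(per_contig):
            for _ in range(200):
                length = int(rng.integers(lo, hi))
                if clen < length + 2 * margin + 2:
                    break
                start = int(rng.integers(margin, clen - length - margin))
                end = start + length - 1
                if all(end + 100 < a or start - 100 > b for a, b in taken):
                    taken.append((start, end))
                    gid += 1
                    genes.append(
                        GeneModel(
                            gene_id=f"g{gid:04d}", contig=contig, start=start,
                            end=end, strand="+" if rng.random() < 0.5 else "-",
                        )
                    )
                    break
    return genes


def simulate_expression(
    gene_methylation: pd.DataFrame,
    config: SimConfig,
    frac_anticorrelated: float = 0.6,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Per-sample expression for genes with methylation levels.

    A fraction of genes is anti-correlated with methylation (expression =
    -standardised methylation + noise, on a log scale); the rest are
    independent noise.  Returns genes x samples log-expression plus a DEG
    summary (log2FC female/male and a BH-style FDR from a two-sample
    t-test), mimicking the differential-expression table the integration
    stage consumes.
    """
    from scipy import stats as sps

    rng = _rng(config, "expression")
    meth = gene_methylation
    z = meth.sub(meth.mean(axis=1), axis=0)
    sd = meth.std(axis=1).replace(0, 1.0)
    z = z.div(sd, axis=0)
    anti = rng.random(len(meth)) < frac_anticorrelated
    noise = rng.normal(0.0, noise_sd, size=meth.shape)
    expr = pd.DataFrame(
        np.where(anti[:, None], -z.values, 0.0) + noise,
        index=meth.index, columns=meth.columns,
    )
    expr.attrs["anticorrelated"] = pd.Series(anti, index=meth.index)
    return expr
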