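"""Site calling: tag filtering, end attribution, count matrix, coverage
filter and QC distributions."""
import numpy as np
import pandas as pd
import pytest

from methylrad.digest import scan_recognition_sites, symmetric_occurrences
from methylrad.io import Genome, SampleSheet, TagAlignment
from methylrad.sites import (
    CountMatrix,
    GeometryIndex,
    build_count_matrix,
    call_sites,
    coverage_filter,
    filter_tags,
    qc_distributions,
)


def toy_sheet():
    return SampleSheet(
        groups=pd.Series(
            ["male", "male", "male", "female", "female", "female"],
            index=["M1", "M2", "M3", "F1", "F2", "F3"],
        )
    )


def toy_matrix(rows, sites=None):
    sheet = toy_sheet()
    idx = pd.MultiIndex.from_tuples(
        sites or [("c1", 10 * (i + 1), "+") for i in range(len(rows))],
        names=["contig", "pos", "strand"],
    )
    counts = pd.DataFrame(rows, index=idx, columns=sheet.samples)
    return CountMatrix(counts=counts, groups=sheet.groups)


class TestFilterTags:
    def test_construction_tags_kept_decoys_removed(self, tag_pipeline):
        tags = tag_pipeline["tags"]
        kept_ids = {(t.sample_id, t.contig, t.start, t.end) for t in tag_pipeline["kept"]}
        for row in tags.head(500).itertuples():
            key = (row.sample_id, row.contig, row.start, row.end)
            assert (key in kept_ids) == (not row.is_decoy)

    def test_filtering_ratio_matches_decoy_fraction(self, tag_pipeline):
        stats = tag_pipeline["fstats"]
        cfg = tag_pipeline["cfg"]
        assert stats.overall_ratio == pytest.approx(1 - cfg.decoy_fraction,
                                                    abs=0.02)

    def test_random_at_rich_tag_removed(self):
        genome = Genome({"c1": "AT" * 300})
        index = GeometryIndex(scan_recognition_sites(genome))
        tag = TagAlignment("S1", "c1", 100, 249, "+")
        kept, stats = filter_tags([tag], index)
        assert kept == [] and stats.per_sample.kept.sum() == 0


class TestCallSites:
    def test_symmetric_tag_increments_both_flanking_sites(self):
        genome = Genome({"c1": "A" * 60 + "CCGG" + "T" * 60})
        catalog = scan_recognition_sites(genome)
        (occ,) = symmetric_occurrences(genome).itertuples()
        # the released 32-mer spans the two cuts
        start = occ.minus_pos - 18
        tag = TagAlignment("M1", "c1", start, start + 31, "+")
        calls = call_sites([tag], catalog)
        got = set(zip(calls.pos, calls.strand, calls["count"]))
        assert got == {(occ.plus_pos, "+", 1), (occ.minus_pos, "-", 1)}
        assert set(calls.orientation) == {"front", "end"}

    def test_empty_alignments_empty_calls(self, tag_pipeline):
        calls = call_sites([], tag_pipeline["catalog"],
                           index=tag_pipeline["index"])
        assert calls.empty

    def test_noiseless_attribution_equals_emitted_counts(self, tag_pipeline):
        """Every counted tag end lands on its true source site: the count
        matrix equals the per-source tally of emitted tags (100% exact-
        position recovery, no misattribution)."""
        tags = tag_pipeline["tags"]
        real = tags[~tags.is_decoy]
        expected = {}
        for row in real.itertuples():
            for label in row.source.split(","):
                contig, pos, strand = label.split(":")
                key = (contig, int(pos), strand, row.sample_id)
                expected[key] = expected.get(key, 0) + 1
        counts = tag_pipeline["matrix"].counts
        observed = {
            (c, p, s, sample): int(counts.at[(c, p, s), sample])
            for (c, p, s) in counts.index
            for sample in counts.columns
            if counts.at[(c, p, s), sample]
        }
        assert observed == expected

    def test_no_unvalidated_ends_after_filter(self, tag_pipeline):
        assert tag_pipeline["calls"].attrs["n_dropped"] == 0


class TestBuildMatrix:
    def test_missing_combination_is_zero(self):
        calls = pd.DataFrame(
            {
                "contig": ["c1", "c1", "c1"],
                "pos": [5, 5, 9],
                "strand": ["+", "+", "+"],
                "sample_id": ["M1", "F1", "M1"],
                "orientation": ["front"] * 3,
                "count": [2, 1, 4],
            }
        )
        m = build_count_matrix(calls, toy_sheet())
        assert m.counts.loc[("c1", 9, "+"), "F1"] == 0
        assert m.counts.loc[("c1", 5, "+"), "M1"] == 2

    def test_column_sums_conserve_increments(self, tag_pipeline):
        calls = tag_pipeline["calls"]
        matrix = tag_pipeline["matrix"]
        per_sample = calls.groupby("sample_id")["count"].sum()
        assert matrix.library_sizes.astype(int).to_dict() == per_sample.to_dict()

    def test_input_order_irrelevant(self, tag_pipeline):
        calls = tag_pipeline["calls"]
        shuffled = calls.sample(frac=1.0, random_state=1)
        m1 = build_count_matrix(calls, tag_pipeline["cfg"].sample_sheet())
        m2 = build_count_matrix(shuffled, tag_pipeline["cfg"].sample_sheet())
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_unknown_sample_rejected(self):
        calls = pd.DataFrame(
            {"contig": ["c1"], "pos": [5], "strand": ["+"],
             "sample_id": ["NOPE"], "orientation": ["front"], "count": [1]}
        )
        with pytest.raises(KeyError, match="NOPE"):
            build_count_matrix(calls, toy_sheet())


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([3, 3, 3, 0, 0, 0], True),
            ([2, 2, 2, 2, 2, 2], False),
            ([3, 3, 0, 0, 0, 0], False),
        ],
    )
    def test_canonical_rows(self, row, kept):
        m = coverage_filter(toy_matrix([row]))
        assert (m.n_sites == 1) is kept

    def test_monotone_in_thresholds(self, tag_pipeline):
        matrix = tag_pipeline["matrix"]
        base = set(coverage_filter(matrix, 3, 3).counts.index)
        assert set(coverage_filter(matrix, 4, 3).counts.index) <= base
        assert set(coverage_filter(matrix, 3, 4).counts.index) <= base

    def test_unit_thresholds_keep_all_nonzero(self, tag_pipeline):
        matrix = tag_pipeline["matrix"]
        kept = coverage_filter(matrix, 1, 1)
        nonzero = matrix.counts.sum(axis=1) > 0
        assert kept.n_sites == int(nonzero.sum())

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            coverage_filter(toy_matrix([[1] * 6]), min_reads=0)


class TestQC:
    def test_fractions_sum_to_one(self, tag_pipeline):
        report = qc_distributions(
            tag_pipeline["kept"], tag_pipeline["calls"], tag_pipeline["matrix"],
            tag_pipeline["fstats"],
        )
        assert report.class_orientation.values.sum() == pytest.approx(1.0)
        assert 0.0 <= report.symmetric_length_fraction <= 1.0
        assert 0.0 <= report.symmetric_site_fraction <= 1.0
        assert report.length_hist.sum() == len(tag_pipeline["kept"])

    def test_symmetric_only_tags_fraction_one(self):
        genome = Genome({"c1": "A" * 60 + "CCGG" + "T" * 60})
        catalog = scan_recognition_sites(genome)
        (occ,) = symmetric_occurrences(genome).itertuples()
        start = occ.minus_pos - 18
        tags = [TagAlignment("M1", "c1", start, start + 31, "+")]
        index = GeometryIndex(catalog)
        kept, stats = filter_tags(tags, index)
        calls = call_sites(kept, catalog, index=index)
        sheet = toy_sheet()
        matrix = build_count_matrix(calls, sheet, catalog)
        report = qc_distributions(kept, calls, matrix, stats)
        assert report.symmetric_length_fraction == 1.0
        assert report.symmetric_site_fraction == 1.0


def test_count_matrix_roundtrip(tmp_path, tag_pipeline):
    matrix = tag_pipeline["filtered"]
    p = tmp_path / "counts.tsv"
    matrix.to_tsv(p)
    back = CountMatrix.from_tsv(p, tag_pipeline["cfg"].sample_sheet())
    pd.testing.assert_frame_equal(back.counts, matrix.counts)


def test_count_matrix_rejects_negative():
    with pytest.raises(ValueError):
        toy_matrix([[-1, 0, 0, 0, 0, 0]])
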