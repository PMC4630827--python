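import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from multicnv.targets_io import (DepthMatrix, ExonTarget, ValidationError,
                                 build_flanked_targets, gene_to_targets,
                                 load_depth_matrix, load_exon_annotation,
                                 write_targets_bed)

import pandas as pd


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


class TestLoadExonAnnotation:
    def test_bed_row_is_taken_verbatim(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr8\t1000\t1100\tDEFB4\n")
        (exon,) = load_exon_annotation(p, "bed")
        assert exon == ExonTarget("chr8", 1000, 1100, "DEFB4")

    def test_one_based_input_converted_to_half_open(self, tmp_path):
        p = _write(tmp_path, "a.tsv",
                   "chrom\tstart\tend\tgene\tone_based\n"
                   "chr8\t1001\t1100\tDEFB4\tTrue\n")
        (exon,) = load_exon_annotation(p, "tsv")
        assert (exon.start, exon.end) == (1000, 1100)

    def test_degenerate_interval_rejected_with_line_number(self, tmp_path):
        p = _write(tmp_path, "a.bed", "chr8\t1000\t1100\tA\nchr8\t5\t5\tB\n")
        with pytest.raises(ValidationError, match=":2"):
            load_exon_annotation(p, "bed")

    def test_identical_intervals_deduplicated(self, tmp_path):
        p = _write(tmp_path, "a.bed",
                   "chr8\t1000\t1100\tDEFB4\nchr8\t1000\t1100\tDEFB4\n")
        assert len(load_exon_annotation(p, "bed")) == 1


class TestBuildFlankedTargets:
    def test_single_exon_gets_flanks(self):
        (r,) = build_flanked_targets([ExonTarget("chr8", 1000, 1100, "A")])
        assert (r.start, r.end) == (700, 1400)
        assert r.length_bp == 700

    def test_gap_below_threshold_merges_with_gene_union(self):
        regions = build_flanked_targets([
            ExonTarget("chr8", 1000, 1100, "A"),
            ExonTarget("chr8", 1650, 1750, "B")])  # gap 550 < 600
        (r,) = regions
        assert (r.start, r.end) == (700, 2050)
        assert r.genes == {"A", "B"}

    def test_gap_exactly_at_threshold_stays_split(self):
        regions = build_flanked_targets([
            ExonTarget("chr8", 1000, 1100, "A"),
            ExonTarget("chr8", 1700, 1800, "B")])  # gap 600, strict rule
        assert [(r.start, r.end) for r in regions] == [(700, 1400),
                                                       (1400, 2100)]

    def test_flank_clips_at_origin(self):
        (r,) = build_flanked_targets([ExonTarget("chr8", 100, 200, "A")])
        assert r.start == 0

    def test_different_chromosomes_never_merge(self):
        regions = build_flanked_targets([
            ExonTarget("chr7", 1000, 1100, "A"),
            ExonTarget("chr8", 1000, 1100, "B")])
        assert len(regions) == 2

    def test_idempotent_on_own_output(self):
        exons = [ExonTarget("chr8", s, s + 100, f"G{i}")
                 for i, s in enumerate([1000, 1450, 3000, 9000])]
        first = build_flanked_targets(exons)
        again = build_flanked_targets(
            [ExonTarget(r.chrom, r.start, r.end, ";".join(sorted(r.genes)))
             for r in first], flank=0, merge_gap=0)
        assert [(r.start, r.end) for r in again] == \
            [(r.start, r.end) for r in first]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 3000), st.integers(1, 400)),
        min_size=1, max_size=8))
    def test_equals_interval_union_of_flanked_exons(self, raw):
        """With flank=300/merge_gap=600 the output must equal the
        per-base union of all exons extended by 300 bp (brute force)."""
        exons = [ExonTarget("chr8", s, s + w, f"G{i}")
                 for i, (s, w) in enumerate(raw)]
        regions = build_flanked_targets(exons)
        covered = set()
        for e in exons:
            covered.update(range(max(0, e.start - 300), e.end + 300))
        from_regions = set()
        for r in regions:
            span = set(range(r.start, r.end))
            assert not (span & from_regions), "regions overlap"
            from_regions |= span
        assert from_regions == covered
        # every exon fully covered by a single region
        for e in exons:
            assert any(r.start <= e.start and r.end >= e.end for r in regions)


class TestDepthMatrixIO:
    def _cohort_files(self, tmp_path):
        regions = build_flanked_targets([
            ExonTarget("chr8", 1000, 1100, "A"),
            ExonTarget("chr8", 5000, 5100, "B"),
            ExonTarget("chr8", 9000, 9100, "C")])
        ids = [r.region_id for r in regions]
        _write(tmp_path, "counts.tsv",
               "target_id\ts1\ts2\n"
               f"{ids[0]}\t10\t20\n{ids[1]}\t30\t40\n{ids[2]}\t50\t60\n")
        _write(tmp_path, "meta.tsv",
               "sample_id\tpopulation\tcontinental_group\tcentre\n"
               "s1\tCEU\tEUR\tBGI\ns2\tCEU\tEUR\tBGI\n")
        _write(tmp_path, "totals.tsv",
               "sample_id\ttotal_mapped_reads\ns1\t1000000\ns2\t2000000\n")
        return regions, tmp_path

    def test_well_formed_tables_round_trip(self, tmp_path):
        regions, d = self._cohort_files(tmp_path)
        dm = load_depth_matrix(d / "counts.tsv", d / "meta.tsv",
                               d / "totals.tsv", regions)
        assert dm.counts.shape == (3, 2)
        assert dm.samples[0].batch_id == "BGI:EUR"

    def test_sample_missing_from_metadata_named_in_error(self, tmp_path):
        regions, d = self._cohort_files(tmp_path)
        (d / "meta.tsv").write_text(
            "sample_id\tpopulation\tcontinental_group\tcentre\n"
            "s1\tCEU\tEUR\tBGI\n")
        with pytest.raises(ValidationError, match="s2"):
            load_depth_matrix(d / "counts.tsv", d / "meta.tsv",
                              d / "totals.tsv", regions)

    def test_negative_count_rejected(self, tmp_path):
        regions, d = self._cohort_files(tmp_path)
        text = (d / "counts.tsv").read_text().replace("\t30\t", "\t-5\t")
        (d / "counts.tsv").write_text(text)
        with pytest.raises(ValidationError, match="negative"):
            load_depth_matrix(d / "counts.tsv", d / "meta.tsv",
                              d / "totals.tsv", regions)

    def test_duplicate_sample_ids_rejected(self):
        regions = build_flanked_targets([ExonTarget("chr8", 1000, 1100, "A")])
        from multicnv.targets_io import SampleMeta
        meta = [SampleMeta("s1", "CEU", "EUR", "BGI")] * 2
        counts = pd.DataFrame([[1.0, 2.0]], index=[regions[0].region_id],
                              columns=["s1", "s1"])
        with pytest.raises(ValidationError, match="duplicate"):
            DepthMatrix(regions, meta, counts,
                        pd.Series({"s1": 100.0}))

    def test_bed_writer_round_trips_through_loader(self, tmp_path):
        regions = build_flanked_targets([
            ExonTarget("chr8", 1000, 1100, "A"),
            ExonTarget("chr8", 1200, 1300, "B")])  # merges, genes joined
        write_targets_bed(regions, tmp_path / "out.bed")
        reread = load_exon_annotation(tmp_path / "out.bed", "bed")
        assert [(e.start, e.end) for e in reread] == \
            [(r.start, r.end) for r in regions]
        assert reread[0].gene == "A;B"

    def test_gene_to_targets_maps_merged_regions_to_both_genes(self):
        regions = build_flanked_targets([
            ExonTarget("chr8", 1000, 1100, "A"),
            ExonTarget("chr8", 1200, 1300, "B")])
        assert gene_to_targets(regions) == {"A": [0], "B": [0]}
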