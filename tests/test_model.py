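"""Readers, catalogs, region annotation and matrix construction."""

import math

import numpy as np
import pytest

from inosinome import (
    EditingMatrix,
    GenomicSite,
    RegionSet,
    SNPMask,
    annotate_site_class,
    build_editing_matrix,
    merge_catalogs,
    read_reditools_table,
    write_reditools_table,
)
from inosinome.model import (
    SiteCatalog,
    SiteMeasurement,
    TableFormatError,
    read_clinical_table,
)

from conftest import meas, site, toy_matrix


class TestReditoolsReader:
    HEADER = ("Region\tPosition\tReference\tStrand\tCoverage\tMeanQ\t"
              "BaseCount[A,C,G,T]\tAllSubs\tFrequency\n")

    def test_hand_crafted_row_parses_to_expected_counts(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(self.HEADER +
                     "chr1\t1000\tA\t+\t20\t35\t[18, 0, 2, 0]\tAG\t0.10\n")
        res = read_reditools_table(p)
        (m,) = res.measurements
        assert m.counts == (18, 0, 2, 0)
        assert m.coverage == 20
        assert m.editing_frequency == pytest.approx(0.10)
        assert m.site.key == ("chr1", 1000, "+")

    def test_non_adenosine_reference_rows_are_skipped_and_counted(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(self.HEADER +
                     "chr1\t1000\tC\t+\t20\t35\t[18, 0, 2, 0]\t-\t0.0\n"
                     "chr1\t2000\tA\t-\t10\t35\t[9, 0, 1, 0]\tAG\t0.1\n")
        res = read_reditools_table(p)
        assert res.n_skipped_non_a == 1
        assert len(res.measurements) == 1
        assert res.measurements[0].site.strand == "-"

    def test_low_mean_quality_rows_are_gated(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(self.HEADER +
                     "chr1\t1000\tA\t+\t20\t12\t[18, 0, 2, 0]\tAG\t0.10\n")
        res = read_reditools_table(p, min_baseq=30)
        assert res.measurements == [] and res.n_skipped_quality == 1
        # mapping quality is not carried by the table: recorded, not applied
        assert "min_mapq" in res.unenforced_filters

    def test_malformed_basecount_reports_line_number(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(self.HEADER + "chr1\t1000\tA\t+\t20\t35\t[18, 0]\tAG\t0.1\n")
        with pytest.raises(TableFormatError, match=":2:"):
            read_reditools_table(p)

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("Region\tPosition\tReference\n" + "chr1\t1\tA\n")
        with pytest.raises(TableFormatError, match="missing mandatory"):
            read_reditools_table(p)

    def test_write_read_round_trip_preserves_measurements(self, tmp_path):
        original = [meas(100, 18, 1, 2, 0), meas(200, 9, 0, 1, 0, strand="-"),
                    meas(300, 0, 5, 0, 0)]
        p = tmp_path / "rt.tsv"
        write_reditools_table(original, p, header_comment="fixture")
        back = read_reditools_table(p).measurements
        assert [(m.site.key, m.counts) for m in back] == \
            [(m.site.key, m.counts) for m in original]


class TestSiteAndCatalog:
    def test_site_invariants_rejected(self):
        with pytest.raises(ValueError):
            GenomicSite(chrom="chr1", pos=0)
        with pytest.raises(ValueError):
            GenomicSite(chrom="chr1", pos=5, strand="x")

    def test_catalog_rejects_duplicates_and_sorts(self):
        with pytest.raises(ValueError, match="duplicate"):
            SiteCatalog([site(10), site(10)])
        cat = SiteCatalog([site(30), site(10, chrom="chr2"), site(20)])
        assert [s.pos for s in cat.sites] == [20, 30, 10]

    def test_merge_is_set_union_on_genomic_key(self):
        c1 = SiteCatalog([site(1), site(2)], provenance=["a"])
        c2 = SiteCatalog([site(2), site(3)], provenance=["b"])
        merged = merge_catalogs([c1, c2])
        assert len(merged) == 3
        assert merged.provenance == ["a", "b"]

    def test_merge_single_catalog_is_identity(self):
        c = SiteCatalog([site(1, recoding=True, aa_change="I/V"), site(5)])
        merged = merge_catalogs([c])
        assert [s.key for s in merged] == [s.key for s in c]
        assert merged.sites[0].aa_change == "I/V"

    def test_recoding_flag_is_or_across_sources(self):
        c1 = SiteCatalog([site(1, recoding=False)])
        c2 = SiteCatalog([site(1, recoding=True, aa_change="Q/R")])
        merged = merge_catalogs([c1, c2])
        assert merged.sites[0].recoding is True
        assert merged.sites[0].aa_change == "Q/R"  # filled from second source

    def test_conflicting_aa_change_first_source_wins_and_is_counted(self):
        c1 = SiteCatalog([site(1, recoding=True, aa_change="I/V")])
        c2 = SiteCatalog([site(1, recoding=True, aa_change="K/R")])
        merged = merge_catalogs([c1, c2])
        assert merged.sites[0].aa_change == "I/V"
        assert merged.annotation_conflicts == 1

    def test_merge_idempotent_and_order_insensitive_on_site_set(self):
        c1 = SiteCatalog([site(1), site(2)])
        c2 = SiteCatalog([site(2), site(3, strand="-")])
        ab = {s.key for s in merge_catalogs([c1, c2])}
        ba = {s.key for s in merge_catalogs([c2, c1])}
        twice = {s.key for s in merge_catalogs([c1, c2, c1])}
        assert ab == ba == twice

    def test_catalog_tsv_round_trip(self, tmp_path):
        cat = SiteCatalog([site(1, recoding=True, aa_change="I/V", gene="COG3",
                                feature="exon", region_class="NONREP"),
                           site(99, strand="-", region_class="ALU")])
        p = tmp_path / "cat.tsv"
        cat.to_tsv(p)
        back = SiteCatalog.from_tsv(p)
        assert [(s.key, s.region_class, s.recoding, s.aa_change, s.gene, s.feature)
                for s in back.sites] == \
               [(s.key, s.region_class, s.recoding, s.aa_change, s.gene, s.feature)
                for s in cat.sites]


class TestRegionAnnotation:
    @pytest.fixture
    def regions(self):
        rs = RegionSet()
        rs.add("ALU", "chr1", 1000, 2000)
        rs.add("REP", "chr1", 1500, 3000)  # overlaps the Alu interval
        rs.add("REP", "chr2", 0, 100)
        return rs

    def test_containment_and_complement(self, regions):
        cat = annotate_site_class(SiteCatalog([site(1500), site(5000)]), regions)
        assert [s.region_class for s in cat.sites] == ["ALU", "NONREP"]

    def test_alu_takes_precedence_over_other_repeats(self, regions):
        cat = annotate_site_class(SiteCatalog([site(1800)]), regions)
        assert cat.sites[0].region_class == "ALU"
        # outside Alu but inside the LINE-like interval
        cat2 = annotate_site_class(SiteCatalog([site(2500)]), regions)
        assert cat2.sites[0].region_class == "REP"

    def test_unknown_chromosome_falls_back_to_nonrep(self, regions):
        cat = annotate_site_class(SiteCatalog([site(10, chrom="chrZ")]), regions)
        assert cat.sites[0].region_class == "NONREP"

    def test_annotation_is_a_partition(self, regions, rng):
        sites = [site(int(p), chrom=rng.choice(["chr1", "chr2"]))
                 for p in rng.integers(1, 4000, size=80)]
        cat = annotate_site_class(SiteCatalog(list(set(sites))), regions)
        counts = cat.class_counts()
        assert sum(counts.values()) == len(cat)

    def test_bed_coordinates_are_half_open(self):
        rs = RegionSet()
        rs.add("ALU", "chr1", 10, 20)  # 0-based half-open = 1-based 11..20
        assert not rs.contains("ALU", "chr1", 10)
        assert rs.contains("ALU", "chr1", 11)
        assert rs.contains("ALU", "chr1", 20)
        assert not rs.contains("ALU", "chr1", 21)

    def test_bed_round_trip(self, regions, tmp_path):
        p = tmp_path / "alu.bed"
        regions.to_bed(p, "ALU")
        rs = RegionSet.from_beds(alu_bed=p)
        assert rs.contains("ALU", "chr1", 1500)
        assert not rs.contains("ALU", "chr1", 2500)


class TestSNPMask:
    def test_membership_and_round_trip(self, tmp_path):
        mask = SNPMask([("chr1", 5), ("chr2", 9)])
        assert ("chr1", 5) in mask and ("chr1", 6) not in mask
        p = tmp_path / "snps.tsv"
        mask.to_tsv(p)
        back = SNPMask.from_tsv(p)
        assert ("chr2", 9) in back and len(back) == 2


class TestEditingMatrix:
    def test_construction_marks_absent_cells_missing(self):
        cat = SiteCatalog([site(100), site(200), site(300)])
        mm = {"s1": [meas(100, 9, 0, 1, 0), meas(200, 5, 0, 5, 0),
                     meas(300, 8, 0, 2, 0)],
              "s2": [meas(100, 7, 0, 3, 0), meas(300, 6, 0, 4, 0)]}
        matrix = build_editing_matrix(mm, cat)
        assert matrix.freq.isna().sum().sum() == 1
        assert math.isnan(matrix.freq.loc["s2", "chr1:200:+"])
        assert matrix.freq.loc["s1", "chr1:200:+"] == pytest.approx(0.5)

    def test_empty_measurements_give_all_missing_matrix(self):
        cat = SiteCatalog([site(100), site(200)])
        matrix = build_editing_matrix({"s1": [], "s2": []}, cat)
        assert matrix.freq.shape == (2, 2)
        assert matrix.freq.isna().all().all()

    def test_duplicate_sample_site_rows_are_fatal(self):
        cat = SiteCatalog([site(100)])
        with pytest.raises(ValueError, match="duplicate measurement"):
            build_editing_matrix({"s1": [meas(100, 9, 0, 1, 0),
                                         meas(100, 8, 0, 2, 0)]}, cat)

    def test_off_catalog_measurements_dropped_with_count(self):
        cat = SiteCatalog([site(100)])
        matrix = build_editing_matrix(
            {"s1": [meas(100, 9, 0, 1, 0), meas(999, 1, 0, 1, 0)]}, cat)
        assert matrix.n_dropped_off_catalog == 1

    def test_zero_ag_depth_cell_has_coverage_but_no_frequency(self):
        cat = SiteCatalog([site(100)])
        matrix = build_editing_matrix({"s1": [meas(100, 0, 10, 0, 2)]}, cat)
        assert matrix.cov.loc["s1"].iloc[0] == 12
        assert math.isnan(matrix.freq.loc["s1"].iloc[0])

    def test_matrix_write_read_round_trip(self, tmp_path):
        matrix = toy_matrix([[0.1, np.nan, 0.4], [0.2, 0.3, np.nan]],
                            [[10, 20, 10], [10, 10, np.nan]])
        cat = SiteCatalog(matrix.sites)
        matrix.write(tmp_path / "f.tsv", tmp_path / "c.tsv")
        back = EditingMatrix.read(tmp_path / "f.tsv", tmp_path / "c.tsv", cat)
        assert np.allclose(back.freq, matrix.freq, equal_nan=True)
        assert np.allclose(back.cov, matrix.cov, equal_nan=True)


class TestClinicalTable:
    def test_contract_violations_are_fatal(self, tmp_path):
        p = tmp_path / "clin.tsv"
        p.write_text("sample_id\tcondition\tsex\tage\tos_time\tos_event\tsubtype\n"
                     "s1\ttumor\tmale\t60\t-5\t1\tCL\n")
        with pytest.raises(TableFormatError, match="negative os_time"):
            read_clinical_table(p)
        p.write_text("sample_id\tcondition\tsex\tage\tos_time\tos_event\tsubtype\n"
                     "s1\ttumor\tmale\t60\t100\t2\tCL\n")
        with pytest.raises(TableFormatError, match="os_event"):
            read_clinical_table(p)
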