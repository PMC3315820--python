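"""BED / bedGraph / WIG / GFF3 conversion, the tabular importer and the
representation-size estimator."""

import itertools

import pytest

from gtrack import convert as cv
from gtrack.io import parse_document, write_document
from gtrack.issues import GTrackParseError
from gtrack.track_model import TrackType


class TestBed:
    BED6 = "chr1\t0\t100\tgeneA\t250\t+\nchr1\t150\t300\tgeneB\t900\t-\n"
    BED12 = "chr1\t100\t500\tg1\t0\t+\t100\t500\t0\t2\t50,60\t0,340\n"

    def test_bed3_equals_direct_gtrack_parse(self):
        text = "chr1\t0\t100\nchr2\t50\t80\n"
        via_converter = cv.bed_to_gtrack(cv.read_bed(text))
        direct = parse_document(text)
        assert list(via_converter.elements()) == list(direct.elements())
        assert via_converter.track_type is direct.track_type is TrackType.S

    def test_bed6_scores_become_values(self):
        doc = cv.bed_to_gtrack(cv.read_bed(self.BED6))
        assert doc.track_type is TrackType.VS
        assert [e.value for e in doc.elements()] == [250.0, 900.0]
        assert [e.strand for e in doc.elements()] == ["+", "-"]

    def test_bed12_linked_expansion(self):
        doc = cv.bed_to_gtrack(cv.read_bed(self.BED12), mode="linked")
        els = list(doc.elements())
        assert len(els) == 3  # 1 parent + 2 exon children
        parent, c1, c2 = els
        assert parent.id == "g1" and parent.edges == ()
        assert (c1.start, c1.end) == (100, 150)
        assert (c2.start, c2.end) == (440, 500)
        assert [e.target_id for e in c1.edges] == ["g1"]
        assert [e.target_id for e in c2.edges] == ["g1"]

    def test_coordinate_round_trip(self):
        records = cv.read_bed(self.BED6)
        back = cv.gtrack_to_bed(cv.bed_to_gtrack(records))
        assert [(r.chrom, r.start, r.end, r.score, r.strand) for r in back] == [
            (r.chrom, r.start, r.end, r.score, r.strand) for r in records
        ]

    def test_points_become_length_one_intervals(self):
        doc = parse_document("##Track type: points\n###seqid\tstart\nchr1\t100\n")
        (rec,) = cv.gtrack_to_bed(doc)
        assert (rec.start, rec.end) == (100, 101)

    def test_dense_types_have_no_bed_form(self, all_docs):
        with pytest.raises(cv.UnsupportedConversion):
            cv.gtrack_to_bed(all_docs[TrackType.F])

    def test_bed_field_count_ladder(self):
        text = cv.write_bed(cv.read_bed(self.BED12))
        for line in text.splitlines():
            assert 3 <= len(line.split("\t")) <= 12

    def test_inconsistent_blocks_rejected(self):
        with pytest.raises(ValueError):
            cv.read_bed("chr1\t0\t100\tx\t0\t+\t0\t100\t0\t3\t10,10\t0,50\n")


class TestBedGraph:
    BG = "chr1\t0\t100\t0.5\nchr1\t100\t250\t0.7\n"

    def test_round_trip_exact(self):
        doc = cv.bedgraph_to_gtrack(cv.read_bedgraph(self.BG))
        assert doc.track_type is TrackType.VS
        assert cv.write_bedgraph(cv.gtrack_to_bedgraph(doc)) == self.BG

    def test_step_function_flattens_to_contiguous_records(self, all_docs):
        doc = all_docs[TrackType.SF]
        records = cv.gtrack_to_bedgraph(doc)
        by_chrom: dict = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            for a, b in zip(rs, rs[1:]):
                assert a.end == b.start

    def test_valued_points_map_to_unit_intervals(self, all_docs):
        doc = all_docs[TrackType.VP]
        for el, rec in zip(doc.elements(), cv.gtrack_to_bedgraph(doc)):
            assert (rec.start, rec.end) == (el.start, el.start + 1)

    def test_every_line_has_four_fields(self, all_docs):
        text = cv.write_bedgraph(cv.gtrack_to_bedgraph(all_docs[TrackType.VS]))
        assert all(len(l.split("\t")) == 4 for l in text.splitlines())


class TestWigTyping:
    def test_variable_step_span1_is_valued_points(self):
        doc = cv.wig_to_gtrack(
            cv.read_wig("variableStep chrom=chr1\n10\t0.5\n20\t0.7\n")
        )
        assert doc.track_type is TrackType.VP
        assert [(e.start, e.value) for e in doc.elements()] == [(9, 0.5), (19, 0.7)]

    def test_variable_step_wide_span_is_valued_segments(self):
        doc = cv.wig_to_gtrack(
            cv.read_wig("variableStep chrom=chr1 span=5\n11\t1\n21\t2\n")
        )
        assert doc.track_type is TrackType.VS
        assert [(e.start, e.end) for e in doc.elements()] == [(10, 15), (20, 25)]

    def test_fixed_step_equal_span_is_step_function(self):
        doc = cv.wig_to_gtrack(
            cv.read_wig("fixedStep chrom=chr3 start=1 step=300 span=300\n1.5\n2.5\n")
        )
        assert doc.track_type is TrackType.SF
        assert [(e.start, e.end, e.value) for e in doc.elements()] == [
            (0, 300, 1.5),
            (300, 600, 2.5),
        ]
        (region,) = doc.regions
        assert (region.start, region.end) == (0, 600)

    def test_fixed_step_sparse_uses_fixed_geometry_headers(self):
        doc = cv.wig_to_gtrack(
            cv.read_wig("fixedStep chrom=chr1 start=1 step=100 span=25\n1\n2\n")
        )
        assert doc.track_type is TrackType.VS
        assert doc.headers.fixed_length == 25
        assert doc.headers.fixed_gap_size == 75
        assert [(e.start, e.end) for e in doc.elements()] == [(0, 25), (100, 125)]
        assert parse_document(write_document(doc)) == doc

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError):
            cv.wig_to_gtrack(
                cv.read_wig("variableStep chrom=chr1 span=10\n1\t1\n5\t2\n")
            )


class TestWigExport:
    def test_valued_points_export_as_variable_step(self, all_docs):
        blocks = cv.gtrack_to_wig(all_docs[TrackType.VP])
        assert all(b.mode == "variableStep" and b.span == 1 for b in blocks)

    def test_function_exports_as_unit_fixed_step(self, all_docs):
        blocks = cv.gtrack_to_wig(all_docs[TrackType.F])
        assert all(b.mode == "fixedStep" and b.span == b.step == 1 for b in blocks)

    def test_round_trip_positions_and_values(self):
        wig = "fixedStep chrom=chr1 start=1 step=10 span=10\n1\n2\n3\n"
        doc = cv.wig_to_gtrack(cv.read_wig(wig))
        assert cv.write_wig(cv.gtrack_to_wig(doc)) == (
            "fixedStep chrom=chr1 start=1 step=10 span=10\n1\n2\n3\n"
        )

    def test_varying_lengths_error_names_bedgraph(self, make_doc):
        doc = make_doc("VS")
        lengths = {el.length for el in doc.elements()}
        assert len(lengths) > 1
        with pytest.raises(cv.UnsupportedConversion, match="bedGraph"):
            cv.gtrack_to_wig(doc)


class TestGff:
    GFF = (
        "##gff-version 3\n"
        "ctg123\t.\tgene\t1000\t9000\t.\t+\t.\tID=gene1\n"
        "ctg123\t.\texon\t1300\t1500\t.\t+\t.\tID=exon1;Parent=gene1\n"
    )

    def test_attribute_keys_union_with_period_fill(self):
        doc = cv.gff_to_gtrack(cv.read_gff(self.GFF))
        assert "ID" in doc.columns.names and "Parent" in doc.columns.names
        gene, exon = doc.elements()
        assert gene.extra("Parent") == "."
        assert exon.extra("Parent") == "gene1"

    def test_union_is_order_independent(self):
        records = cv.read_gff(self.GFF)
        for perm in itertools.permutations(records):
            doc = cv.gff_to_gtrack(list(perm))
            assert set(doc.columns.names) == set(
                cv.gff_to_gtrack(records).columns.names
            )

    def test_link_parents_builds_linked_track(self):
        doc = cv.gff_to_gtrack(cv.read_gff(self.GFF), link_parents=True)
        assert doc.track_type is TrackType.LS
        gene, exon = doc.elements()
        assert gene.id == "gene1"
        assert [e.target_id for e in exon.edges] == ["gene1"]

    def test_coordinate_convention_conversion(self):
        doc = parse_document("chr1\t0\t100\n")
        (rec,) = cv.gtrack_to_gff(doc)
        assert (rec.start, rec.end) == (1, 100)

    def test_export_always_nine_fields(self, make_doc):
        doc = make_doc("LVS", edge_density=0.5)
        text = cv.write_gff(cv.gtrack_to_gff(doc))
        for line in text.splitlines():
            if line.startswith("#"):
                continue
            assert len(line.split("\t")) == 9

    def test_extras_serialize_into_attributes(self):
        doc = parse_document(
            "###seqid\tstart\tend\tgene_id\nchr1\t0\t100\tg1\n"
        )
        (rec,) = cv.gtrack_to_gff(doc)
        assert rec.attr("gene_id") == ("g1",)

    def test_dense_rejected_as_impractical(self, all_docs):
        with pytest.raises(cv.UnsupportedConversion, match="impractical"):
            cv.gtrack_to_gff(all_docs[TrackType.F])

    def test_round_trip_coordinates(self):
        records = cv.read_gff(self.GFF)
        back = cv.gtrack_to_gff(cv.gff_to_gtrack(records))
        assert [(r.seqid, r.start, r.end) for r in back] == [
            (r.seqid, r.start, r.end) for r in records
        ]

    def test_malformed_field_count_rejected(self):
        with pytest.raises(ValueError):
            cv.read_gff("chr1\tsrc\tgene\t1\t10\t.\t+\n")


class TestTabularImport:
    def test_named_columns_give_valued_segments(self):
        doc = cv.tabular_to_gtrack(
            "chr1\t0\t100\t3.5\nchr1\t200\t300\t4.5\n",
            ("seqid", "start", "end", "value"),
        )
        assert doc.track_type is TrackType.VS

    def test_bed3_names_equal_direct_parse(self):
        text = "chr1\t0\t100\n"
        assert cv.tabular_to_gtrack(text, ("seqid", "start", "end")) == parse_document(
            text
        )

    def test_missing_core_columns_propagate_empty_type_error(self):
        with pytest.raises(GTrackParseError):
            cv.tabular_to_gtrack("chr1\tx\n", ("seqid", "name"))


class TestSizeEstimates:
    HUMAN = 3_100_000_000

    def test_wig_estimate_around_20_gb(self):
        size = cv.estimate_representation_size(self.HUMAN, "wig")
        assert 15e9 < size < 25e9

    def test_bedgraph_estimate_around_100_gb(self):
        size = cv.estimate_representation_size(self.HUMAN, "bedgraph")
        assert 80e9 < size < 120e9

    def test_bedgraph_much_larger_than_wig(self):
        wig = cv.estimate_representation_size(self.HUMAN, "wig")
        bg = cv.estimate_representation_size(self.HUMAN, "bedgraph")
        assert bg / wig > 4

    def test_empty_genome_costs_nothing(self):
        assert cv.estimate_representation_size(0, "wig") == 0
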