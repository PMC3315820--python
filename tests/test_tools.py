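"""Sort, standardize-to-LVS and complement-columns tools."""

import dataclasses
import random

import pytest

from gtrack.io import parse_document, write_document
from gtrack.issues import RuleCode, Severity
from gtrack.tools import complement_columns, sort_gtrack, standardize_gtrack
from gtrack.track_model import TrackType
from gtrack.validate import validate


def _errors(issues):
    return [i for i in issues if i.severity is Severity.ERROR]


def _shuffled(doc, seed=0):
    rng = random.Random(seed)
    groups = []
    for region, elements in doc.groups:
        els = elements[:]
        rng.shuffle(els)
        groups.append((region, els))
    rng.shuffle(groups)
    return dataclasses.replace(
        doc, headers=doc.headers.replace(sorted_elements=False), groups=groups
    )


class TestSort:
    def test_shuffled_document_passes_sortedness_rule(self, make_doc):
        doc = _shuffled(make_doc("VS"))
        sorted_doc = sort_gtrack(doc)
        assert sorted_doc.headers.sorted_elements
        issues = validate(write_document(sorted_doc))
        assert RuleCode.R7 not in {i.code for i in issues}

    def test_idempotent(self, make_doc):
        doc = sort_gtrack(_shuffled(make_doc("VS")))
        assert sort_gtrack(doc) == doc

    def test_is_a_permutation(self, make_doc):
        doc = make_doc("VS")
        before = sorted(
            (e.seqid, e.start, e.end, str(e.value)) for e in doc.elements()
        )
        after = sorted(
            (e.seqid, e.start, e.end, str(e.value))
            for e in sort_gtrack(_shuffled(doc)).elements()
        )
        assert before == after

    def test_dense_element_order_untouched(self, all_docs):
        doc = all_docs[TrackType.SF]
        assert list(sort_gtrack(doc).elements()) == list(doc.elements())

    def test_regions_ordered(self, make_doc):
        doc = _shuffled(make_doc("S"), seed=3)
        regions = sort_gtrack(doc).regions
        keys = [(r.genome or "", r.seqid, r.start) for r in regions]
        assert keys == sorted(keys)


class TestStandardize:
    @pytest.mark.parametrize("type_name", [t.name for t in TrackType])
    def test_always_yields_valid_lvs(self, all_docs, type_name):
        doc = all_docs[TrackType[type_name]]
        std = standardize_gtrack(doc)
        assert std.track_type is TrackType.LVS
        assert std.columns.implied_track_type(std.headers) is TrackType.LVS
        assert _errors(validate(write_document(std))) == []

    def test_point_becomes_length_one_segment(self):
        doc = parse_document("##Track type: points\n###seqid\tstart\nchr1\t100\n")
        (el,) = standardize_gtrack(doc).elements()
        assert (el.start, el.end) == (100, 101)
        assert el.value is None
        assert el.edges == ()
        assert el.id == "chr1:100-101"

    def test_existing_ids_and_edges_preserved(self, all_docs):
        doc = all_docs[TrackType.LGP]
        std = standardize_gtrack(doc)
        assert [e.id for e in std.elements()] == [e.id for e in doc.elements()]
        assert [e.edges for e in std.elements()] == [e.edges for e in doc.elements()]
        assert [(e.start, e.end) for e in std.elements()] == [
            (e.start, e.end) for e in doc.elements()
        ]

    def test_lvs_document_unchanged_modulo_headers(self, all_docs):
        doc = all_docs[TrackType.LVS]
        std = standardize_gtrack(doc)
        assert list(std.elements()) == list(doc.elements())

    def test_element_count_preserved(self, all_docs):
        for t, doc in all_docs.items():
            assert standardize_gtrack(doc).n_elements == doc.n_elements, t

    def test_default_id_collisions_get_suffixes(self):
        doc = parse_document("chr1\t0\t10\nchr1\t0\t10\n")
        ids = [e.id for e in standardize_gtrack(doc).elements()]
        assert ids == ["chr1:0-10", "chr1:0-10.1"]


class TestComplement:
    TARGET = "chr1\t0\t100\nchr1\t200\t300\n"
    SOURCE = "###seqid\tstart\tend\tvalue\nchr1\t0\t100\t3.5\nchr1\t500\t600\t9.9\n"

    def test_target_gains_value_column_by_position(self):
        target = parse_document(self.TARGET)
        source = parse_document(self.SOURCE)
        out = complement_columns(target, source, key="position")
        assert out.track_type is TrackType.VS
        values = [e.value for e in out.elements()]
        assert values == [3.5, None]  # second row has no match -> "."

    def test_row_count_and_existing_cells_unchanged(self):
        target = parse_document(self.SOURCE)
        source = parse_document(
            "###seqid\tstart\tend\tvalue\tnote\n"
            "chr1\t0\t100\t111\thello\n"
        )
        out = complement_columns(target, source, key="position")
        assert out.n_elements == target.n_elements
        assert [e.value for e in out.elements()] == [3.5, 9.9]
        assert next(out.elements()).extra("note") == "hello"

    def test_no_matches_fill_with_periods(self):
        target = parse_document("chr2\t0\t10\n")
        source = parse_document(self.SOURCE)
        out = complement_columns(target, source, key="position")
        assert [e.value for e in out.elements()] == [None]

    def test_duplicate_source_key_rejected(self):
        target = parse_document(self.TARGET)
        source = parse_document(
            "###seqid\tstart\tend\tvalue\nchr1\t0\t100\t1\nchr1\t0\t100\t2\n"
        )
        with pytest.raises(ValueError, match="ambiguous"):
            complement_columns(target, source, key="position")

    def test_id_key_join(self, make_doc):
        target = parse_document(
            "##Track type: linked segments\n"
            "###seqid\tstart\tend\tid\tedges\n"
            "chr1\t0\t10\ta\t.\n"
        )
        source = parse_document(
            "###seqid\tstart\tend\tid\tnote\nchr2\t5\t9\ta\tkept\n"
        )
        out = complement_columns(target, source, key="id")
        assert next(out.elements()).extra("note") == "kept"
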