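"""Validator soundness, per-rule sensitivity and the header-assertion
contract."""

import pytest

from gtrack.io import parse_document, write_document
from gtrack.issues import RuleCode, Severity
from gtrack.synth import FixtureParams, RuleNotApplicable, corrupt, generate
from gtrack.track_model import TrackType
from gtrack.validate import assert_structure, validate

# Which fixture type exhibits each rule violation.
RULE_FIXTURES = {
    RuleCode.R1: "S",
    RuleCode.R2: "LS",
    RuleCode.R3: "S",
    RuleCode.R4: "LS",
    RuleCode.R5: "LS",
    RuleCode.R6: "LVS",
    RuleCode.R7: "S",
    RuleCode.R8: "S",
    RuleCode.R9: "SF",
    RuleCode.R10: "VS",
    RuleCode.R11: "S",
    RuleCode.R12: "S",
    RuleCode.R13: "S",
    RuleCode.R14: "S",
    RuleCode.R15: "S",
}


def _errors(issues):
    return [i for i in issues if i.severity is Severity.ERROR]


class TestSoundness:
    def test_all_fixture_types_validate_cleanly(self, all_docs):
        for t, doc in all_docs.items():
            assert _errors(validate(write_document(doc))) == [], t

    def test_validation_is_idempotent(self, make_doc):
        text = corrupt(make_doc("LS", edge_density=0.5), RuleCode.R5)
        assert validate(text) == validate(text)

    def test_raw_and_parsed_validation_agree_on_clean_docs(self, make_doc):
        doc = make_doc("VS")
        assert _errors(validate(doc)) == _errors(validate(write_document(doc)))


class TestSensitivity:
    @pytest.mark.parametrize("code", list(RULE_FIXTURES))
    def test_each_rule_detected_and_attributed(self, genome, code):
        t = TrackType[RULE_FIXTURES[code]]
        doc = generate(
            FixtureParams(
                track_type=t,
                edge_density=0.5,
                undirected=(code is RuleCode.R6),
                edge_weights=(code is RuleCode.R6),
            ),
            genome,
        )
        issues = validate(corrupt(doc, code))
        assert code in {i.code for i in issues}
        if code is not RuleCode.R15:
            error_codes = {i.code for i in _errors(issues)}
            assert error_codes == {code}

    def test_length_one_segment_is_a_warning_not_error(self, make_doc):
        issues = validate(corrupt(make_doc("S"), RuleCode.R15))
        r15 = [i for i in issues if i.code is RuleCode.R15]
        assert r15 and all(i.severity is Severity.WARNING for i in r15)

    def test_rule_not_applicable_raises(self, make_doc):
        with pytest.raises(RuleNotApplicable):
            corrupt(make_doc("S"), RuleCode.R2)  # no edges column on segments

    def test_edges_without_id_column(self):
        text = (
            "##Track type: linked points\n"
            "###seqid\tstart\tedges\n"
            "chr1\t5\t.\n"
        )
        issues = validate(text)
        assert RuleCode.R2 in {i.code for i in issues}

    def test_overlap_promise_broken(self):
        text = (
            "##No overlapping elements: true\n"
            "chr1\t0\t100\nchr1\t50\t150\n"
        )
        codes = {i.code for i in validate(text)}
        assert RuleCode.R8 in codes

    def test_issue_ordering_by_line_then_code(self, make_doc):
        doc = make_doc("LS", edge_density=0.5)
        issues = validate(corrupt(doc, RuleCode.R5))
        keys = [i.sort_key for i in issues]
        assert keys == sorted(keys)


class TestAssertStructure:
    def test_quick_script_scenario(self):
        doc = parse_document(
            "##No overlapping elements: true\nchr1\t0\t10\nchr1\t20\t30\n"
        )
        assert assert_structure(
            doc, track_type="segments", no_overlapping_elements=True
        )

    def test_wrong_type_fails(self, make_doc):
        assert not assert_structure(make_doc("VP"), track_type=TrackType.S)

    def test_empty_requirement_is_vacuous(self, make_doc):
        assert assert_structure(make_doc("VP"))

    def test_unknown_header_name_rejected(self, make_doc):
        with pytest.raises(ValueError):
            assert_structure(make_doc("S"), not_a_header=True)
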