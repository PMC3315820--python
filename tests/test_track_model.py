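"""The track-type lattice, the discrete coordinate metric and analysis
applicability."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtrack.track_model import (
    ANALYSIS_REGISTRY,
    CORE_COLUMNS,
    RESERVED_COLUMNS,
    CoreProperties,
    EmptyTypeError,
    Point,
    Segment,
    TrackType,
    analysis_applicable,
    columns_for_type,
    is_basic,
    is_dense,
    is_linked,
    metric_distance,
    point_in_segment,
    properties_to_type,
    segment_length,
    segments_overlap,
    type_from_columns,
    type_to_properties,
)

ALL_COMBOS = [
    CoreProperties(gaps=g, lengths=l, values=v, interconnections=i)
    for g, l, v, i in itertools.product([False, True], repeat=4)
]


class TestTypeLattice:
    def test_sixteen_combinations_one_empty_fifteen_types(self):
        assert len(ALL_COMBOS) == 16
        types = []
        errors = 0
        for props in ALL_COMBOS:
            try:
                types.append(properties_to_type(props))
            except EmptyTypeError:
                errors += 1
        assert errors == 1
        assert len(types) == 15
        assert len(set(types)) == 15
        assert set(types) == set(TrackType)

    def test_properties_type_bijection(self):
        for t in TrackType:
            assert properties_to_type(type_to_properties(t)) is t

    def test_partition_counts(self):
        basic = [t for t in TrackType if is_basic(t)]
        linked = [t for t in TrackType if is_linked(t)]
        dense = [t for t in TrackType if is_dense(t)]
        sparse = [t for t in TrackType if not is_dense(t)]
        assert len(basic) == 7
        assert len(linked) == 8
        assert len(dense) == 7
        assert len(sparse) == 8
        assert set(basic) | set(linked) == set(TrackType)
        assert set(dense) & set(sparse) == set()

    @pytest.mark.parametrize(
        "names, expected",
        [
            (frozenset({"start"}), TrackType.P),
            (frozenset({"start", "end"}), TrackType.S),
            (frozenset({"end"}), TrackType.GP),
            (frozenset({"end", "value"}), TrackType.SF),
            (frozenset({"value"}), TrackType.F),
            (frozenset({"start", "value"}), TrackType.VP),
            (frozenset({"edges"}), TrackType.LBP),
            (frozenset({"value", "edges"}), TrackType.LF),
            (frozenset({"end", "edges"}), TrackType.LGP),
            (frozenset({"start", "end", "value", "edges"}), TrackType.LVS),
        ],
    )
    def test_type_from_columns(self, names, expected):
        assert type_from_columns(names) is expected

    def test_columns_round_trip(self):
        for t in TrackType:
            assert type_from_columns(columns_for_type(t)) is t

    def test_linked_types_require_id(self):
        for t in TrackType:
            cols = columns_for_type(t, include_id=True)
            assert ("id" in cols) == is_linked(t)

    def test_empty_column_set_rejected(self):
        with pytest.raises(EmptyTypeError):
            type_from_columns(set())
        with pytest.raises(EmptyTypeError):
            properties_to_type(CoreProperties())

    def test_full_combination_is_lvs(self):
        assert (
            properties_to_type(
                CoreProperties(gaps=True, lengths=True, values=True, interconnections=True)
            )
            is TrackType.LVS
        )

    def test_representative_property_sets(self):
        assert type_to_properties(TrackType.F) == CoreProperties(values=True)
        assert type_to_properties(TrackType.GP) == CoreProperties(lengths=True)
        assert type_to_properties(TrackType.LBP) == CoreProperties(
            interconnections=True
        )

    def test_reserved_and_core_column_lists(self):
        assert len(RESERVED_COLUMNS) == 8
        assert set(CORE_COLUMNS) < set(RESERVED_COLUMNS)
        assert len(CORE_COLUMNS) == 4


class TestMetric:
    def test_worked_example(self):
        assert metric_distance(1, 3) == 3

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 100), st.integers(1, 100))
    def test_metric_equals_enumerated_interval_size(self, a, b):
        assert metric_distance(a, b) == metric_distance(b, a)
        assert metric_distance(a, b) == len(set(range(min(a, b), max(a, b) + 1)))

    def test_segment_length_matches_metric(self):
        # 1-based inclusive (1, 3) maps to canonical [0, 3)
        assert segment_length(Segment("chr", 0, 3)) == metric_distance(1, 3)
        assert segment_length(Segment("chr", 10, 11)) == 1

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            Segment("chr", 7, 7)
        with pytest.raises(ValueError):
            Segment("chr", 5, 3)


class TestGeometryOracles:
    """Containment and overlap agree with brute-force set arithmetic."""

    def test_point_in_segment_examples(self):
        seg = Segment("chr", 0, 3)  # 1-based inclusive (1, 3) = {1, 2, 3}
        assert point_in_segment(Point("chr", 1), seg)
        assert point_in_segment(Point("chr", 2), seg)
        assert not point_in_segment(Point("chr", 3), seg)
        assert not point_in_segment(Point("other", 1), seg)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 49), st.data())
    def test_point_in_segment_is_subset_relation(self, pos, data):
        start = data.draw(st.integers(0, 48))
        end = data.draw(st.integers(start + 1, 50))
        seg = Segment("chr", start, end)
        assert point_in_segment(Point("chr", pos), seg) == (
            {pos} <= set(range(start, end))
        )

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_overlap_is_nonempty_intersection(self, data):
        s1 = data.draw(st.integers(0, 48))
        e1 = data.draw(st.integers(s1 + 1, 50))
        s2 = data.draw(st.integers(0, 48))
        e2 = data.draw(st.integers(s2 + 1, 50))
        a, b = Segment("chr", s1, e1), Segment("chr", s2, e2)
        assert segments_overlap(a, b) == bool(
            set(range(s1, e1)) & set(range(s2, e2))
        )

    def test_half_open_adjacency_does_not_overlap(self):
        assert not segments_overlap(Segment("c", 0, 10), Segment("c", 10, 20))
        assert segments_overlap(Segment("c", 0, 10), Segment("c", 2, 4))


class TestAnalysisApplicability:
    LOCATED_INSIDE = (
        CoreProperties(gaps=True),
        CoreProperties(gaps=True, lengths=True),
    )

    def test_points_inside_segments(self):
        assert analysis_applicable(self.LOCATED_INSIDE, [TrackType.P, TrackType.S])

    def test_generalizes_to_valued_operands(self):
        assert analysis_applicable(self.LOCATED_INSIDE, [TrackType.VP, TrackType.VS])

    def test_not_applicable_to_function(self):
        # points inside a melting-temperature function is meaningless
        assert not analysis_applicable(self.LOCATED_INSIDE, [TrackType.P, TrackType.F])

    def test_symmetry_tries_both_operand_orders(self):
        assert analysis_applicable(self.LOCATED_INSIDE, [TrackType.S, TrackType.P])
        assert not analysis_applicable(
            self.LOCATED_INSIDE, [TrackType.S, TrackType.P], symmetric=False
        )

    def test_registry_covers_pairwise_combinations(self):
        five = [TrackType.P, TrackType.S, TrackType.F, TrackType.VP, TrackType.VS]
        pairs = list(itertools.combinations_with_replacement(five, 2))
        assert len(pairs) == 15
        # every registry analysis applies to at least one pair
        for analysis in ANALYSIS_REGISTRY:
            assert any(
                analysis_applicable(analysis.operands, list(pair)) for pair in pairs
            ), analysis.name
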