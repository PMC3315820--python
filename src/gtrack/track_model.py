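"""The track-type algebra and the formal coordinate model.

A genomic track is a set of positioned data units (track elements) over a
genome coordinate system.  Four *core informational properties* suffice to
classify tracks:

``gaps``
    elements do not tile the genome (there are positions between them);
``lengths``
    elements span intervals rather than single base pairs;
``values``
    a designated main value is attached to each element;
``interconnections``
    elements are linked to other elements by (possibly weighted) edges.

Of the :math:`2^4 = 16` presence/absence combinations, the all-absent one
carries no information, leaving fifteen *track types* — seven *basic*
(unlinked) and eight *linked*, or equivalently eight *sparse* (with gaps)
and seven *dense* (tiling their declared domain).

Two coordinate conventions appear throughout:

* the *formal model* uses 1-based, end-inclusive natural-number coordinates,
  with the discrete metric ``d(a, b) = |a - b| + 1`` counting the base pairs
  covered;
* the *canonical internal* convention used everywhere else in this package
  is 0-based, half-open ``[start, end)``.

The bijection between the two is ``start0 = start1 - 1``, ``end0 = end1``;
a segment's length is then ``end0 - start0 = d(start1, end1)``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "CoreProperties",
    "TrackType",
    "Point",
    "Segment",
    "EmptyTypeError",
    "properties_to_type",
    "type_to_properties",
    "type_from_columns",
    "columns_for_type",
    "is_dense",
    "is_linked",
    "is_basic",
    "metric_distance",
    "segment_length",
    "point_in_segment",
    "segments_overlap",
    "analysis_applicable",
    "AnalysisRequirement",
    "ANALYSIS_REGISTRY",
    "CORE_COLUMNS",
    "RESERVED_COLUMNS",
    "all_track_types",
]


class EmptyTypeError(ValueError):
    """Raised for the one core-property combination that defines no type.

    A track with none of the four core properties carries no information
    and is therefore of no interest.
    """


@dataclass(frozen=True, order=True)
class CoreProperties:
    """A point in the four-dimensional track-type lattice."""

    gaps: bool = False
    lengths: bool = False
    values: bool = False
    interconnections: bool = False

    def __post_init__(self) -> None:
        for name in ("gaps", "lengths", "values", "interconnections"):
            if not isinstance(getattr(self, name), bool):
                raise TypeError(f"{name} must be a bool")

    def is_superset_of(self, required: "CoreProperties") -> bool:
        return (
            (self.gaps or not required.gaps)
            and (self.lengths or not required.lengths)
            and (self.values or not required.values)
            and (self.interconnections or not required.interconnections)
        )

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "CoreProperties":
        names = set(names)
        valid = {"gaps", "lengths", "values", "interconnections"}
        unknown = names - valid
        if unknown:
            raise ValueError(f"unknown core properties: {sorted(unknown)}")
        return cls(**{n: True for n in names})


class TrackType(enum.Enum):
    """The fifteen genomic track types.

    Enum values are the full track-type names as written in GTrack
    ``##track type:`` header lines.
    """

    P = "points"
    VP = "valued points"
    S = "segments"
    VS = "valued segments"
    GP = "genome partition"
    SF = "step function"
    F = "function"
    LP = "linked points"
    LVP = "linked valued points"
    LS = "linked segments"
    LVS = "linked valued segments"
    LGP = "linked genome partition"
    LSF = "linked step function"
    LF = "linked function"
    LBP = "linked base pairs"

    @classmethod
    def from_name(cls, name: str) -> "TrackType":
        """Look up a type from its full name (case-insensitive) or abbreviation."""
        key = name.strip().lower()
        for t in cls:
            if t.value == key:
                return t
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown track type: {name!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# gaps <-> start, lengths <-> end, values <-> value, interconnections <-> edges
_TYPE_TO_PROPS: dict[TrackType, CoreProperties] = {
    TrackType.P: CoreProperties(gaps=True),
    TrackType.VP: CoreProperties(gaps=True, values=True),
    TrackType.S: CoreProperties(gaps=True, lengths=True),
    TrackType.VS: CoreProperties(gaps=True, lengths=True, values=True),
    TrackType.GP: CoreProperties(lengths=True),
    TrackType.SF: CoreProperties(lengths=True, values=True),
    TrackType.F: CoreProperties(values=True),
    TrackType.LP: CoreProperties(gaps=True, interconnections=True),
    TrackType.LVP: CoreProperties(gaps=True, values=True, interconnections=True),
    TrackType.LS: CoreProperties(gaps=True, lengths=True, interconnections=True),
    TrackType.LVS: CoreProperties(
        gaps=True, lengths=True, values=True, interconnections=True
    ),
    TrackType.LGP: CoreProperties(lengths=True, interconnections=True),
    TrackType.LSF: CoreProperties(lengths=True, values=True, interconnections=True),
    TrackType.LF: CoreProperties(values=True, interconnections=True),
    TrackType.LBP: CoreProperties(interconnections=True),
}

_PROPS_TO_TYPE = {props: t for t, props in _TYPE_TO_PROPS.items()}

#: The four core reserved columns, in conventional order.  The presence of
#: each corresponds one-to-one to a core property being defined.
CORE_COLUMNS: tuple[str, ...] = ("start", "end", "value", "edges")

#: All eight reserved column names of the GTrack column specification line.
RESERVED_COLUMNS: tuple[str, ...] = (
    "genome",
    "seqid",
    "start",
    "end",
    "value",
    "strand",
    "id",
    "edges",
)

_COLUMN_TO_PROPERTY = {
    "start": "gaps",
    "end": "lengths",
    "value": "values",
    "edges": "interconnections",
}
_PROPERTY_TO_COLUMN = {v: k for k, v in _COLUMN_TO_PROPERTY.items()}


def all_track_types() -> tuple[TrackType, ...]:
    """All fifteen track types, in lattice order (basic first, then linked)."""
    return tuple(TrackType)


def properties_to_type(props: CoreProperties) -> TrackType:
    """Map a combination of core properties to its unique track type.

    Raises :class:`EmptyTypeError` for the all-false combination.
    """
    if props not in _PROPS_TO_TYPE:
        raise EmptyTypeError(
            "no core properties defined: the empty combination is not a track type"
        )
    return _PROPS_TO_TYPE[props]


def type_to_properties(t: TrackType) -> CoreProperties:
    """The core-property combination defining track type *t*."""
    return _TYPE_TO_PROPS[t]


def type_from_columns(core_columns: Iterable[str]) -> TrackType:
    """Infer the track type from the set of core columns present.

    ``start`` marks gaps, ``end`` lengths, ``value`` values and ``edges``
    interconnections.  Non-core names in the input raise ``ValueError``;
    an empty set raises :class:`EmptyTypeError`.
    """
    cols = set(core_columns)
    unknown = cols - set(CORE_COLUMNS)
    if unknown:
        raise ValueError(f"not core columns: {sorted(unknown)}")
    props = CoreProperties(**{_COLUMN_TO_PROPERTY[c]: True for c in cols})
    return properties_to_type(props)


def columns_for_type(t: TrackType, include_id: bool = False) -> set[str]:
    """The core columns required by track type *t*.

    With ``include_id=True``, linked types additionally include ``id``
    (the edges column requires a unique identifier per element).
    """
    props = type_to_properties(t)
    cols = {
        _PROPERTY_TO_COLUMN[name]
        for name in ("gaps", "lengths", "values", "interconnections")
        if getattr(props, name)
    }
    if include_id and props.interconnections:
        cols.add("id")
    return cols


def is_dense(t: TrackType) -> bool:
    """Dense types have no gaps: their elements tile the bounding regions."""
    return not type_to_properties(t).gaps


def is_linked(t: TrackType) -> bool:
    """Linked (extended) types carry interconnections between elements."""
    return type_to_properties(t).interconnections


def is_basic(t: TrackType) -> bool:
    """The seven basic types are the unlinked ones."""
    return not is_linked(t)


# ---------------------------------------------------------------------------
# Formal coordinate model (1-based, end-inclusive natural numbers)
# ---------------------------------------------------------------------------


def metric_distance(a: int, b: int) -> int:
    """The discrete metric ``d(a, b) = |a - b| + 1`` on genome coordinates.

    In the 1-based inclusive model this counts the base pairs covered by
    the interval between ``a`` and ``b``: ``d(1, 3) = 3``.
    """
    if a < 1 or b < 1:
        raise ValueError("formal-model coordinates are natural numbers (>= 1)")
    return abs(a - b) + 1


@dataclass(frozen=True, order=True)
class Point:
    """A single base-pair position, canonical 0-based."""

    seqid: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True, order=True)
class Segment:
    """A non-empty interval, canonical 0-based half-open ``[start, end)``.

    In the formal model a segment must cover more than one base pair
    (a length-1 segment is indistinguishable from a point); file-level
    tracks may still contain length-1 elements, which the validator
    flags only as a strictness warning.
    """

    seqid: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be non-negative")
        if self.end <= self.start:
            raise ValueError(f"empty segment: end ({self.end}) must exceed start ({self.start})")


def segment_length(s: Segment) -> int:
    """Number of base pairs covered: ``end - start``.

    Equals ``metric_distance`` on the equivalent 1-based inclusive
    coordinates ``(start + 1, end)``.
    """
    return s.end - s.start


def point_in_segment(p: Point, s: Segment) -> bool:
    """Whether point *p* falls inside segment *s* (subset relation).

    Points on a different sequence are simply outside (``False``).
    """
    if p.seqid != s.seqid:
        return False
    return s.start <= p.position < s.end


def segments_overlap(s1: Segment, s2: Segment) -> bool:
    """Whether two segments share at least one base pair."""
    if s1.seqid != s2.seqid:
        return False
    return s1.start < s2.end and s2.start < s1.end


# ---------------------------------------------------------------------------
# Analysis applicability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisRequirement:
    """A named analysis with the core properties it requires per operand.

    An analysis defined for minimal property sets generalizes to any
    operand types defining supersets of those properties: asking whether
    points fall inside segments also makes sense for valued points versus
    valued segments.
    """

    name: str
    operands: tuple[CoreProperties, ...]
    symmetric: bool = True


def analysis_applicable(
    required: Sequence[CoreProperties],
    operand_types: Sequence[TrackType],
    symmetric: bool = True,
) -> bool:
    """Whether an analysis requiring *required* properties applies to tracks
    of the given types.

    True iff every operand's type defines a superset of the corresponding
    required properties; with ``symmetric=True`` (the default) any operand
    order is accepted.
    """
    if len(required) != len(operand_types):
        raise ValueError("one requirement record per operand track is needed")
    orders = (
        itertools.permutations(operand_types)
        if symmetric
        else [tuple(operand_types)]
    )
    for order in orders:
        if all(
            type_to_properties(t).is_superset_of(req)
            for req, t in zip(required, order)
        ):
            return True
    return False


def _props(*names: str) -> CoreProperties:
    return CoreProperties.from_names(names)


#: Example pairwise analyses over the five unlinked types P, S, F, VP, VS,
#: recorded as property-requirement records (no statistics are computed).
ANALYSIS_REGISTRY: tuple[AnalysisRequirement, ...] = (
    AnalysisRequirement("Different frequencies?", (_props("gaps"), _props("gaps"))),
    AnalysisRequirement("Located inside?", (_props("gaps"), _props("gaps", "lengths"))),
    AnalysisRequirement(
        "Higher values at locations?", (_props("gaps"), _props("values"))
    ),
    AnalysisRequirement(
        "Located in highly valued segments?",
        (_props("gaps"), _props("gaps", "lengths", "values")),
    ),
    AnalysisRequirement(
        "Overlap?", (_props("gaps", "lengths"), _props("gaps", "lengths"))
    ),
    AnalysisRequirement(
        "Higher values inside?", (_props("gaps", "lengths"), _props("values"))
    ),
    AnalysisRequirement("Correlated?", (_props("values"), _props("values"))),
    AnalysisRequirement(
        "Nearby values similar?", (_props("gaps", "values"), _props("gaps", "values"))
    ),
    AnalysisRequirement(
        "Categories differentially located in targets?",
        (_props("gaps", "values"), _props("gaps", "lengths", "values")),
    ),
)
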