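"""In-memory model of a GTrack 1.0 document.

A document is a set of header variables, a column specification, and an
ordered list of bounding regions each holding ordered track elements.
All coordinates held by these objects are canonical: 0-based, half-open.
The ``1-indexed`` and ``end inclusive`` header variables only describe how
coordinates are rendered in the file; parsing normalizes them away and
writing re-applies them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterator

from .track_model import TrackType, type_from_columns

__all__ = [
    "HeaderSet",
    "ColumnSpec",
    "BoundingRegion",
    "EdgeRef",
    "TrackElement",
    "GTrackDocument",
    "HEADER_FIELDS",
    "VALUE_TYPES",
    "VALUE_DIMENSIONS",
    "ADHERENCE_MODES",
]

VALUE_TYPES = ("number", "binary", "category", "character")
VALUE_DIMENSIONS = ("scalar", "list")
ADHERENCE_MODES = ("free", "strict")

#: field name -> (header line name, default value), in Table order.
HEADER_FIELDS: dict[str, tuple[str, Any]] = {
    "gtrack_version": ("gtrack version", "1.0"),
    "track_type": ("track type", TrackType.S),
    "value_type": ("value type", "number"),
    "value_dimension": ("value dimension", "scalar"),
    "undirected_edges": ("undirected edges", False),
    "edge_weights": ("edge weights", False),
    "edge_weight_type": ("edge weight type", "number"),
    "edge_weight_dimension": ("edge weight dimension", "scalar"),
    "uninterrupted_data_lines": ("uninterrupted data lines", False),
    "sorted_elements": ("sorted elements", False),
    "no_overlapping_elements": ("no overlapping elements", False),
    "circular_elements": ("circular elements", False),
    "one_indexed": ("1-indexed", False),
    "end_inclusive": ("end inclusive", False),
    "value_column": ("value column", "value"),
    "edges_column": ("edges column", "edges"),
    "fixed_length": ("fixed length", 1),
    "fixed_gap_size": ("fixed gap size", 0),
    "fixed_size_data_lines": ("fixed-size data lines", False),
    "data_line_size": ("data line size", 1),
    "subtype_name": ("gtrack subtype", ""),
    "subtype_version": ("subtype version", "1.0"),
    "subtype_url": ("subtype url", ""),
    "subtype_adherence": ("subtype adherence", "free"),
}

_NAME_TO_FIELD = {name: f for f, (name, _) in HEADER_FIELDS.items()}


@dataclass
class HeaderSet:
    """The header variables of a GTrack file, with their defaults.

    ``explicit`` records which variables were stated as header lines (or
    set deliberately by a tool); it is bookkeeping, not content, and is
    excluded from equality.
    """

    gtrack_version: str = "1.0"
    track_type: TrackType = TrackType.S
    value_type: str = "number"
    value_dimension: str = "scalar"
    undirected_edges: bool = False
    edge_weights: bool = False
    edge_weight_type: str = "number"
    edge_weight_dimension: str = "scalar"
    uninterrupted_data_lines: bool = False
    sorted_elements: bool = False
    no_overlapping_elements: bool = False
    circular_elements: bool = False
    one_indexed: bool = False
    end_inclusive: bool = False
    value_column: str = "value"
    edges_column: str = "edges"
    fixed_length: int = 1
    fixed_gap_size: int = 0
    fixed_size_data_lines: bool = False
    data_line_size: int = 1
    subtype_name: str = ""
    subtype_version: str = "1.0"
    subtype_url: str = ""
    subtype_adherence: str = "free"
    explicit: frozenset[str] = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise ValueError(f"invalid value type: {self.value_type!r}")
        if self.value_dimension not in VALUE_DIMENSIONS:
            raise ValueError(f"invalid value dimension: {self.value_dimension!r}")
        if self.edge_weight_type not in VALUE_TYPES:
            raise ValueError(f"invalid edge weight type: {self.edge_weight_type!r}")
        if self.edge_weight_dimension not in VALUE_DIMENSIONS:
            raise ValueError(
                f"invalid edge weight dimension: {self.edge_weight_dimension!r}"
            )
        if self.fixed_length < 1:
            raise ValueError("fixed length must be a positive integer")
        if self.fixed_gap_size < 0:
            raise ValueError("fixed gap size must be non-negative")
        if self.data_line_size < 1:
            raise ValueError("data line size must be a positive integer")

    def declared(self, field_name: str) -> bool:
        """Whether a variable was explicitly stated or differs from its default."""
        return (
            field_name in self.explicit
            or getattr(self, field_name) != HEADER_FIELDS[field_name][1]
        )

    def replace(self, **changes: Any) -> "HeaderSet":
        """Copy with changes; changed fields are marked explicit."""
        explicit = set(changes.pop("explicit", self.explicit))
        explicit.update(changes)
        return dataclasses.replace(self, explicit=frozenset(explicit), **changes)

    @staticmethod
    def field_for_name(header_name: str) -> str | None:
        """Map a header line name (case-insensitive) to a field name."""
        return _NAME_TO_FIELD.get(header_name.strip().lower())


@dataclass(frozen=True)
class ColumnSpec:
    """The ordered column names of every data line."""

    names: tuple[str, ...] = ("seqid", "start", "end")

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate column names: {self.names}")
        if not self.names:
            raise ValueError("column specification must name at least one column")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def role_of(self, name: str, headers: HeaderSet) -> str:
        """The role a column plays: a reserved role or ``"extra"``.

        The ``value column`` and ``edges column`` header variables choose
        which column carries the main value / the active edges; a column
        literally named ``value`` while the focus lies elsewhere is an
        ordinary extra column.
        """
        if name == headers.value_column:
            return "value"
        if name == headers.edges_column:
            return "edges"
        if name in ("genome", "seqid", "start", "end", "strand", "id"):
            return name
        return "extra"

    def column_for_role(self, role: str, headers: HeaderSet) -> str | None:
        for name in self.names:
            if self.role_of(name, headers) == role:
                return name
        return None

    def has_role(self, role: str, headers: HeaderSet) -> bool:
        return self.column_for_role(role, headers) is not None

    def core_roles(self, headers: HeaderSet) -> set[str]:
        """Core columns physically present, after value/edges aliasing."""
        return {
            self.role_of(n, headers) for n in self.names
        } & {"start", "end", "value", "edges"}

    def implied_track_type(self, headers: HeaderSet) -> TrackType:
        """The type inferred from the columns when no type is declared.

        A non-default ``fixed length`` stands in for the end column and
        an explicitly stated ``fixed gap size`` for the start column
        (coordinates are then implied rather than listed).
        """
        roles = self.core_roles(headers)
        if headers.fixed_length != 1 and "end" not in roles:
            roles.add("end")
        if "fixed_gap_size" in headers.explicit and "start" not in roles:
            roles.add("start")
        return type_from_columns(roles)

    def check_against_type(self, headers: HeaderSet, t: TrackType) -> str | None:
        """Why the columns are incompatible with a declared type, or None.

        Core columns must not exceed the type's requirements; missing
        required columns are acceptable only when supplied by declared
        fixed-geometry headers (``fixed length`` for end, ``fixed gap
        size`` for start).
        """
        from .track_model import columns_for_type  # local: avoid cycle at import

        required = columns_for_type(t)
        present = self.core_roles(headers)
        extra = present - required
        if extra:
            return (
                f"column(s) {sorted(extra)} are not part of track type {t.value!r}"
            )
        missing = required - present
        for role in sorted(missing):
            if role == "end" and headers.declared("fixed_length"):
                continue
            if role == "start" and headers.declared("fixed_gap_size"):
                continue
            return (
                f"track type {t.value!r} requires the {role!r} column "
                f"(or a fixed-geometry header supplying it)"
            )
        return None


@dataclass(frozen=True)
class BoundingRegion:
    """Declared domain of a block of track elements (canonical coordinates).

    Bounding regions distinguish "no data" from "value zero"; dense track
    types require them, as their elements tile the region exactly.
    """

    seqid: str
    start: int
    end: int
    genome: str | None = None
    line_number: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("bounding region start must be non-negative")
        if self.end <= self.start:
            raise ValueError("bounding region must be non-empty (end > start)")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EdgeRef:
    """A link from one track element to another, optionally weighted."""

    target_id: str
    weight: Any = None

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("edge target id must be non-empty")


@dataclass(frozen=True)
class TrackElement:
    """One track element (one data line), in canonical coordinates.

    ``start``/``end``/``value``/``edges`` are ``None`` exactly when the
    document's track type leaves the corresponding core property
    undefined (for dense types, implicit coordinates are materialized at
    parse time).  ``extras`` holds out-of-focus columns verbatim.
    """

    seqid: str
    start: int | None = None
    end: int | None = None
    value: Any = None
    strand: str | None = None
    id: str | None = None
    edges: tuple[EdgeRef, ...] | None = None
    genome: str | None = None
    extras: tuple[tuple[str, str], ...] = ()
    line_number: int | None = field(default=None, compare=False)

    @property
    def length(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start

    @property
    def span(self) -> tuple[int, int]:
        """The base pairs occupied, ``[start, end)``; a point covers one bp."""
        if self.start is not None and self.end is not None:
            return (self.start, self.end)
        if self.start is not None:
            return (self.start, self.start + 1)
        raise ValueError("element has no explicit coordinates")

    def extra(self, name: str) -> str | None:
        for key, cell in self.extras:
            if key == name:
                return cell
        return None


@dataclass
class GTrackDocument:
    """A parsed GTrack document: headers, columns and grouped elements.

    ``groups`` pairs each bounding region (or ``None`` for ungrouped
    sparse data) with its ordered track elements.
    """

    headers: HeaderSet = field(default_factory=HeaderSet)
    columns: ColumnSpec = field(default_factory=ColumnSpec)
    groups: list[tuple[BoundingRegion | None, list[TrackElement]]] = field(
        default_factory=list
    )
    comments: list[str] = field(default_factory=list, compare=False)
    column_spec_declared: bool = field(default=True, compare=False)

    @property
    def track_type(self) -> TrackType:
        return self.headers.track_type

    @property
    def regions(self) -> list[BoundingRegion]:
        return [r for r, _ in self.groups if r is not None]

    def elements(self) -> Iterator[TrackElement]:
        for _, els in self.groups:
            yield from els

    @property
    def n_elements(self) -> int:
        return sum(len(els) for _, els in self.groups)

    def ids(self) -> dict[str, TrackElement]:
        out: dict[str, TrackElement] = {}
        for el in self.elements():
            if el.id is not None:
                out[el.id] = el
        return out
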