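"""Reading and writing GTrack 1.0 text.

Line grammar (prefix length decides the class of a line):

* ``####`` — bounding region specification: ``"; "``-separated ``key=value``
  pairs over ``genome``, ``seqid``, ``start``, ``end``;
* ``###`` — column specification: tab-separated column names immediately
  following the prefix;
* ``##`` — header line, ``name: value``, names case-insensitive;
* ``#`` — comment;
* anything else — a tab-separated data line (blank lines are ignored).

Parsing normalizes all coordinates to the canonical 0-based half-open
convention according to the ``1-indexed`` and ``end inclusive`` headers;
writing converts back to the requested dialect.  For dense track types the
implicit positions of the elements are materialized from the bounding
regions while parsing.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Iterable, Sequence

from .document import (
    ADHERENCE_MODES,
    HEADER_FIELDS,
    BoundingRegion,
    ColumnSpec,
    EdgeRef,
    GTrackDocument,
    HeaderSet,
    TrackElement,
)
from .issues import GTrackParseError, RuleCode
from .track_model import EmptyTypeError, TrackType, is_dense, type_to_properties

__all__ = [
    "parse_document",
    "write_document",
    "normalize_coordinates",
    "denormalize_coordinates",
    "compute_dense_positions",
    "apply_fixed_geometry",
    "parse_edges",
    "format_edges",
    "parse_value",
    "format_value",
    "expand_headers",
    "expand_headers_text",
    "infer_value_type",
    "resolve_subtype",
    "read_gtrack",
    "write_gtrack",
]

_MISSING = "."


# ---------------------------------------------------------------------------
# Coordinate dialects
# ---------------------------------------------------------------------------


def normalize_coordinates(
    raw_start: int | None,
    raw_end: int | None,
    one_indexed: bool,
    end_inclusive: bool,
    *,
    circular: bool = False,
    line_number: int | None = None,
) -> tuple[int | None, int | None]:
    """Convert dialect coordinates to canonical 0-based half-open.

    ``start' = start - [1-indexed]``; ``end' = end - [1-indexed] +
    [end inclusive]``.  An empty interval (``end' <= start'``) is an
    error unless the document declares circular elements.
    """
    start = raw_start - int(one_indexed) if raw_start is not None else None
    end = raw_end - int(one_indexed) + int(end_inclusive) if raw_end is not None else None
    if start is not None and start < 0:
        raise GTrackParseError(
            f"negative canonical start coordinate: {start}", line_number=line_number
        )
    if start is not None and end is not None and end <= start and not circular:
        raise GTrackParseError(
            f"empty interval: canonical end ({end}) must exceed start ({start})",
            line_number=line_number,
        )
    return start, end


def denormalize_coordinates(
    start: int | None, end: int | None, one_indexed: bool, end_inclusive: bool
) -> tuple[int | None, int | None]:
    """Inverse of :func:`normalize_coordinates`."""
    raw_start = start + int(one_indexed) if start is not None else None
    raw_end = end + int(one_indexed) - int(end_inclusive) if end is not None else None
    return raw_start, raw_end


# ---------------------------------------------------------------------------
# Value cells
# ---------------------------------------------------------------------------


def _parse_scalar(cell: str, value_type: str, line_number: int | None) -> Any:
    if value_type == "number":
        try:
            return float(cell)
        except ValueError:
            raise GTrackParseError(
                f"value {cell!r} is not a number",
                code=RuleCode.R10,
                line_number=line_number,
            ) from None
    if value_type == "binary":
        if cell not in ("0", "1"):
            raise GTrackParseError(
                f"value {cell!r} is not binary (0/1)",
                code=RuleCode.R10,
                line_number=line_number,
            )
        return int(cell)
    if value_type == "character":
        if len(cell) != 1:
            raise GTrackParseError(
                f"value {cell!r} is not a single character",
                code=RuleCode.R10,
                line_number=line_number,
            )
        return cell
    if value_type == "category":
        if "\t" in cell:
            raise GTrackParseError(
                "category value contains a tab",
                code=RuleCode.R10,
                line_number=line_number,
            )
        return cell
    raise ValueError(f"unknown value type: {value_type!r}")


def parse_value(
    cell: str,
    value_type: str = "number",
    value_dimension: str = "scalar",
    line_number: int | None = None,
) -> Any:
    """Parse a value cell per the declared type and dimension.

    A lone period is the missing value (``None``).  List-dimensioned
    values are comma-separated and parse to a tuple.
    """
    if cell == _MISSING:
        return None
    if value_dimension == "list":
        return tuple(
            _parse_scalar(item, value_type, line_number) for item in cell.split(",")
        )
    return _parse_scalar(cell, value_type, line_number)


def _format_scalar(v: Any, value_type: str) -> str:
    if value_type == "number":
        f = float(v)
        return repr(int(f)) if f.is_integer() else repr(f)
    if value_type == "binary":
        return str(int(v))
    return str(v)


def format_value(value: Any, value_type: str = "number", value_dimension: str = "scalar") -> str:
    if value is None:
        return _MISSING
    if value_dimension == "list":
        return ",".join(_format_scalar(v, value_type) for v in value)
    return _format_scalar(value, value_type)


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------


def _parse_weight(text: str, headers: HeaderSet, line_number: int | None) -> Any:
    if headers.edge_weight_dimension == "list":
        return tuple(
            _parse_scalar(item, headers.edge_weight_type, line_number)
            for item in text.split("|")
        )
    return _parse_scalar(text, headers.edge_weight_type, line_number)


def parse_edges(
    text: str, headers: HeaderSet, line_number: int | None = None
) -> tuple[EdgeRef, ...]:
    """Parse an edges cell: a comma-separated list of target ids,
    each optionally weighted as ``id=weight`` (list weights use ``|``
    between components)."""
    if text == _MISSING or text == "":
        return ()
    edges = []
    for item in text.split(","):
        if "=" in item:
            target, _, weight_text = item.partition("=")
            if not headers.edge_weights:
                raise GTrackParseError(
                    f"weighted edge {item!r} but 'edge weights' is false",
                    code=RuleCode.R10,
                    line_number=line_number,
                )
            weight = _parse_weight(weight_text, headers, line_number)
        else:
            target, weight = item, None
        if not target:
            raise GTrackParseError(
                f"empty edge target in {text!r}",
                code=RuleCode.R10,
                line_number=line_number,
            )
        edges.append(EdgeRef(target_id=target, weight=weight))
    return tuple(edges)


def _format_weight(weight: Any, headers: HeaderSet) -> str:
    if headers.edge_weight_dimension == "list":
        return "|".join(_format_scalar(w, headers.edge_weight_type) for w in weight)
    return _format_scalar(weight, headers.edge_weight_type)


def format_edges(edges: tuple[EdgeRef, ...] | None, headers: HeaderSet) -> str:
    if not edges:
        return _MISSING
    items = []
    for e in edges:
        if e.weight is None:
            items.append(e.target_id)
        else:
            items.append(f"{e.target_id}={_format_weight(e.weight, headers)}")
    return ",".join(items)


# ---------------------------------------------------------------------------
# Header lines
# ---------------------------------------------------------------------------

_BOOLEAN_FIELDS = {
    f for f, (_, default) in HEADER_FIELDS.items() if isinstance(default, bool)
}
_INT_FIELDS = {
    f
    for f, (_, default) in HEADER_FIELDS.items()
    if isinstance(default, int) and not isinstance(default, bool)
}


def _parse_header_value(field_name: str, raw: str, line_number: int | None) -> Any:
    if field_name == "track_type":
        try:
            return TrackType.from_name(raw)
        except ValueError as exc:
            raise GTrackParseError(
                str(exc), code=RuleCode.HEADER, line_number=line_number
            ) from None
    if field_name in _BOOLEAN_FIELDS:
        low = raw.strip().lower()
        if low not in ("true", "false"):
            raise GTrackParseError(
                f"header {field_name!r} expects true/false, got {raw!r}",
                code=RuleCode.HEADER,
                line_number=line_number,
            )
        return low == "true"
    if field_name in _INT_FIELDS:
        try:
            return int(raw)
        except ValueError:
            raise GTrackParseError(
                f"header {field_name!r} expects an integer, got {raw!r}",
                code=RuleCode.HEADER,
                line_number=line_number,
            ) from None
    return raw.strip()


def _format_header_value(field_name: str, value: Any) -> str:
    if field_name == "track_type":
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _parse_bounding_region_line(
    line: str, headers: HeaderSet, line_number: int
) -> BoundingRegion:
    body = line[4:].strip()
    fields: dict[str, str] = {}
    if body:
        for pair in body.split(";"):
            pair = pair.strip()
            if not pair:
                continue
            if "=" not in pair:
                raise GTrackParseError(
                    f"malformed bounding region field {pair!r}",
                    line_number=line_number,
                )
            key, _, val = pair.partition("=")
            key = key.strip().lower()
            if key not in ("genome", "seqid", "start", "end"):
                raise GTrackParseError(
                    f"unknown bounding region key {key!r}", line_number=line_number
                )
            fields[key] = val.strip()
    if "seqid" not in fields:
        raise GTrackParseError(
            "bounding region must declare a seqid", line_number=line_number
        )
    if "start" not in fields or "end" not in fields:
        raise GTrackParseError(
            "bounding region must declare start and end", line_number=line_number
        )
    try:
        raw_start, raw_end = int(fields["start"]), int(fields["end"])
    except ValueError:
        raise GTrackParseError(
            "bounding region start/end must be integers", line_number=line_number
        ) from None
    start, end = normalize_coordinates(
        raw_start,
        raw_end,
        headers.one_indexed,
        headers.end_inclusive,
        line_number=line_number,
    )
    try:
        return BoundingRegion(
            seqid=fields["seqid"],
            start=start,
            end=end,
            genome=fields.get("genome"),
            line_number=line_number,
        )
    except ValueError as exc:
        raise GTrackParseError(str(exc), line_number=line_number) from None


def _int_cell(cell: str, what: str, line_number: int) -> int:
    try:
        return int(cell)
    except ValueError:
        raise GTrackParseError(
            f"malformed {what} coordinate {cell!r}", line_number=line_number
        ) from None


def compute_dense_positions(
    region: BoundingRegion,
    raw_lines: Sequence[tuple[int, str | None]],
    track_type: TrackType,
    headers: HeaderSet,
) -> list[tuple[int, int | None, int]]:
    """Materialize implicit coordinates of dense data lines.

    ``raw_lines`` pairs each data line number with its raw end cell (or
    ``None`` for the per-bp types, which have no end column).  For the
    end-positioned dense types (GP, SF, LGP, LSF) line *k* spans from
    the previous end (initially the region start) to its own end, and
    the last end must equal the region end.  For the per-base-pair types
    (F, LF, LBP) line *k* is the single position ``region.start + k``
    and the line count must equal the region length.

    Returns ``(start, end, line_number)`` tuples; ``end`` is ``None``
    for the per-bp types.
    """
    props = type_to_properties(track_type)
    if props.gaps:
        raise ValueError(f"{track_type.name} is not a dense track type")
    out: list[tuple[int, int | None, int]] = []
    if props.lengths:
        prev_end = region.start
        for lineno, end_cell in raw_lines:
            if end_cell is None or end_cell == _MISSING:
                raise GTrackParseError(
                    "dense track element is missing its end coordinate",
                    code=RuleCode.R9,
                    line_number=lineno,
                )
            raw_end = _int_cell(end_cell, "end", lineno)
            _, end = normalize_coordinates(
                None,
                raw_end,
                headers.one_indexed,
                headers.end_inclusive,
                line_number=lineno,
            )
            if end <= prev_end:
                raise GTrackParseError(
                    f"dense end positions must be strictly increasing within the "
                    f"bounding region (got {end} after {prev_end})",
                    code=RuleCode.R9,
                    line_number=lineno,
                )
            if end > region.end:
                raise GTrackParseError(
                    f"dense element end {end} exceeds bounding region end {region.end}",
                    code=RuleCode.R9,
                    line_number=lineno,
                )
            out.append((prev_end, end, lineno))
            prev_end = end
        if raw_lines and prev_end != region.end:
            raise GTrackParseError(
                f"dense elements do not tile the bounding region: last end "
                f"{prev_end} != region end {region.end}",
                code=RuleCode.R9,
                line_number=raw_lines[-1][0],
            )
        if not raw_lines:
            raise GTrackParseError(
                "dense bounding region contains no data lines",
                code=RuleCode.R9,
                line_number=region.line_number,
            )
    else:
        if len(raw_lines) != region.length:
            raise GTrackParseError(
                f"per-bp dense region of length {region.length} has "
                f"{len(raw_lines)} data lines",
                code=RuleCode.R9,
                line_number=region.line_number,
            )
        for k, (lineno, _) in enumerate(raw_lines):
            out.append((region.start + k, None, lineno))
    return out


def apply_fixed_geometry(
    elements: list[TrackElement],
    region: BoundingRegion | None,
    headers: HeaderSet,
    track_type: TrackType,
) -> list[TrackElement]:
    """Fill in coordinates implied by ``fixed length`` / ``fixed gap size``.

    A declared fixed length supplies ``end = start + L`` where the end
    column is omitted; a declared fixed gap size supplies ``start`` from
    the previous element's end (the first start is the region start).
    """
    props = type_to_properties(track_type)
    fixed_len = headers.declared("fixed_length")
    fixed_gap = headers.declared("fixed_gap_size")
    if not (fixed_len or fixed_gap):
        return elements
    out = []
    first = True
    prev_end: int | None = region.start if region is not None else None
    for el in elements:
        start, end = el.start, el.end
        if fixed_gap and props.gaps and start is None:
            if prev_end is None:
                raise GTrackParseError(
                    "fixed gap size requires a bounding region to anchor the "
                    "first element",
                    line_number=el.line_number,
                )
            # no gap precedes the first element of a region
            start = prev_end if first else prev_end + headers.fixed_gap_size
        if fixed_len and props.lengths and end is None:
            if start is None:
                raise GTrackParseError(
                    "cannot apply fixed length without a start position",
                    line_number=el.line_number,
                )
            end = start + headers.fixed_length
        if end is not None:
            prev_end = end
        elif start is not None:
            prev_end = start + 1
        first = False
        out.append(dataclasses.replace(el, start=start, end=end))
    return out


def parse_document(text: str) -> GTrackDocument:
    """Parse GTrack text into a canonical :class:`GTrackDocument`.

    Raises :class:`GTrackParseError` (carrying a rule code and line
    number) on structural violations; the validator wraps this into
    issue lists for total validation.

    When no column specification line is present the columns default to
    ``(seqid, start, end)``, so a plain three-column BED file parses
    directly as a segments track.  When no ``track type`` header is
    present the type is inferred from the columns.
    """
    raw_headers: dict[str, tuple[Any, int]] = {}
    columns: ColumnSpec | None = None
    comments: list[str] = []
    # groups of (region, [(lineno, raw_cells_by_column)])
    pending: list[tuple[BoundingRegion | None, list[tuple[int, list[str]]]]] = []
    current: list[tuple[int, list[str]]] = []
    current_region: BoundingRegion | None = None
    seen_data = False
    region_lines: list[tuple[int, str]] = []

    lines = text.replace("\r\n", "\n").split("\n")
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("####"):
            region_lines.append((lineno, line))
        elif line.startswith("###"):
            if seen_data or region_lines:
                raise GTrackParseError(
                    "column specification line after data", line_number=lineno
                )
            if columns is not None:
                raise GTrackParseError(
                    "duplicate column specification line", line_number=lineno
                )
            names = tuple(line[3:].split("\t"))
            try:
                columns = ColumnSpec(names=names)
            except ValueError as exc:
                raise GTrackParseError(str(exc), line_number=lineno) from None
        elif line.startswith("##"):
            if seen_data or region_lines:
                raise GTrackParseError("header line after data", line_number=lineno)
            body = line[2:]
            name, sep, value = body.partition(":")
            if not sep:
                raise GTrackParseError(
                    f"malformed header line {line!r} (expected '##name: value')",
                    code=RuleCode.HEADER,
                    line_number=lineno,
                )
            field_name = HeaderSet.field_for_name(name)
            if field_name is None:
                raise GTrackParseError(
                    f"unknown header variable {name.strip()!r}",
                    code=RuleCode.HEADER,
                    line_number=lineno,
                )
            raw_headers[field_name] = (value.strip(), lineno)
        elif line.startswith("#"):
            comments.append(line[1:].strip())
        elif line.strip() == "":
            continue
        else:
            seen_data = True
            region_lines.append((lineno, line))

    headers_kwargs: dict[str, Any] = {}
    for field_name, (raw, lineno) in raw_headers.items():
        headers_kwargs[field_name] = _parse_header_value(field_name, raw, lineno)
    if (
        "subtype_adherence" in headers_kwargs
        and headers_kwargs["subtype_adherence"] not in ADHERENCE_MODES
    ):
        raise GTrackParseError(
            f"unsupported subtype adherence "
            f"{headers_kwargs['subtype_adherence']!r} (supported: free, strict)",
            code=RuleCode.HEADER,
            line_number=raw_headers["subtype_adherence"][1],
        )
    try:
        headers = HeaderSet(
            explicit=frozenset(headers_kwargs), **headers_kwargs
        )
    except ValueError as exc:
        raise GTrackParseError(str(exc), code=RuleCode.HEADER) from None

    column_spec_declared = columns is not None
    if columns is None:
        columns = ColumnSpec()

    # Declared vs column-implied track type.
    if "track_type" in headers.explicit:
        problem = columns.check_against_type(headers, headers.track_type)
        if problem is not None:
            raise GTrackParseError(problem, code=RuleCode.R1)
    else:
        try:
            implied = columns.implied_track_type(headers)
        except (EmptyTypeError, ValueError) as exc:
            raise GTrackParseError(str(exc), code=RuleCode.R1) from None
        headers = dataclasses.replace(headers, track_type=implied)
    track_type = headers.track_type
    props = type_to_properties(track_type)

    # Split the body into bounding-region groups.
    for lineno, line in region_lines:
        if line.startswith("####"):
            if current or current_region is not None:
                pending.append((current_region, current))
                current = []
            current_region = _parse_bounding_region_line(line, headers, lineno)
        else:
            if headers.fixed_size_data_lines:
                if len(line) != headers.data_line_size:
                    raise GTrackParseError(
                        f"data line has {len(line)} characters, expected "
                        f"{headers.data_line_size}",
                        code=RuleCode.R11,
                        line_number=lineno,
                    )
                line = line.rstrip(" ")
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise GTrackParseError(
                    f"data line has {len(cells)} columns, expected {len(columns)}",
                    code=RuleCode.R3,
                    line_number=lineno,
                )
            current.append((lineno, cells))
    if current or current_region is not None:
        pending.append((current_region, current))

    groups: list[tuple[BoundingRegion | None, list[TrackElement]]] = []
    dense = is_dense(track_type)
    for region, raw_rows in pending:
        rows = [
            (lineno, dict(zip(columns.names, cells))) for lineno, cells in raw_rows
        ]

        def cell_for(role: str, cells: dict[str, str]) -> str | None:
            col = columns.column_for_role(role, headers)
            return cells[col] if col is not None else None

        if dense:
            if region is None:
                raise GTrackParseError(
                    "dense track data outside any bounding region",
                    code=RuleCode.R9,
                    line_number=rows[0][0] if rows else None,
                )
            end_cells = [(lineno, cell_for("end", cells)) for lineno, cells in rows]
            positioned = compute_dense_positions(region, end_cells, track_type, headers)
            elements = []
            for (start, end, lineno), (_, cells) in zip(positioned, rows):
                elements.append(
                    _build_element(
                        cells, columns, headers, region, props,
                        start=start, end=end, line_number=lineno,
                    )
                )
        else:
            elements = []
            for lineno, cells in rows:
                start_cell = cell_for("start", cells)
                end_cell = cell_for("end", cells)
                raw_start = (
                    _int_cell(start_cell, "start", lineno)
                    if start_cell not in (None, _MISSING)
                    else None
                )
                raw_end = (
                    _int_cell(end_cell, "end", lineno)
                    if end_cell not in (None, _MISSING)
                    else None
                )
                start, end = normalize_coordinates(
                    raw_start,
                    raw_end,
                    headers.one_indexed,
                    headers.end_inclusive,
                    circular=headers.circular_elements or not props.lengths,
                    line_number=lineno,
                )
                elements.append(
                    _build_element(
                        cells, columns, headers, region, props,
                        start=start, end=end, line_number=lineno,
                    )
                )
            elements = apply_fixed_geometry(elements, region, headers, track_type)
        groups.append((region, elements))

    return GTrackDocument(
        headers=headers,
        columns=columns,
        groups=groups,
        comments=comments,
        column_spec_declared=column_spec_declared,
    )


def _build_element(
    cells: dict[str, str],
    columns: ColumnSpec,
    headers: HeaderSet,
    region: BoundingRegion | None,
    props,
    *,
    start: int | None,
    end: int | None,
    line_number: int,
) -> TrackElement:
    def cell_for(role: str) -> str | None:
        col = columns.column_for_role(role, headers)
        return cells[col] if col is not None else None

    seqid = cell_for("seqid")
    if seqid in (None, _MISSING):
        if region is None:
            raise GTrackParseError(
                "data line has no seqid and no enclosing bounding region",
                line_number=line_number,
            )
        seqid = region.seqid
    genome = cell_for("genome")
    if genome in (None, _MISSING):
        genome = region.genome if region is not None else None

    value_cell = cell_for("value")
    value = (
        parse_value(value_cell, headers.value_type, headers.value_dimension, line_number)
        if value_cell is not None
        else None
    )
    edges_cell = cell_for("edges")
    edges = (
        parse_edges(edges_cell, headers, line_number) if edges_cell is not None else None
    )
    strand = cell_for("strand")
    id_cell = cell_for("id")
    extras = tuple(
        (name, cells[name])
        for name in columns.names
        if columns.role_of(name, headers) == "extra"
    )
    return TrackElement(
        seqid=seqid,
        start=start,
        end=end,
        value=value,
        strand=strand,
        id=None if id_cell in (None, _MISSING) else id_cell,
        edges=edges,
        genome=genome,
        extras=extras,
        line_number=line_number,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_document(
    doc: GTrackDocument,
    one_indexed: bool | None = None,
    end_inclusive: bool | None = None,
    emit_defaults: bool = False,
) -> str:
    """Serialize a document to GTrack text.

    ``one_indexed`` / ``end_inclusive`` override the document's own
    coordinate dialect headers.  Header lines whose value equals the
    default are omitted unless ``emit_defaults`` (or they were explicitly
    set).  ``parse_document(write_document(doc))`` reproduces ``doc`` up
    to comment placement.
    """
    headers = doc.headers
    if one_indexed is not None or end_inclusive is not None:
        changes = {}
        if one_indexed is not None:
            changes["one_indexed"] = one_indexed
        if end_inclusive is not None:
            changes["end_inclusive"] = end_inclusive
        headers = headers.replace(**changes)

    lines: list[str] = []
    for field_name, (header_name, default) in HEADER_FIELDS.items():
        value = getattr(headers, field_name)
        if emit_defaults or value != default or field_name in headers.explicit:
            if header_name.startswith("gtrack"):
                display = "GTrack" + header_name[len("gtrack"):]
            elif header_name == "subtype url":
                display = "Subtype URL"
            else:
                display = header_name[0].upper() + header_name[1:]
            lines.append(f"##{display}: {_format_header_value(field_name, value)}")
    for comment in doc.comments:
        lines.append(f"# {comment}" if comment else "#")
    lines.append("###" + "\t".join(doc.columns.names))

    groups = doc.groups
    if headers.undirected_edges:
        groups = _complete_reciprocal_edges(groups)

    for region, elements in groups:
        if region is not None:
            raw_start, raw_end = denormalize_coordinates(
                region.start, region.end, headers.one_indexed, headers.end_inclusive
            )
            fields = []
            if region.genome is not None:
                fields.append(f"genome={region.genome}")
            fields.append(f"seqid={region.seqid}")
            fields.append(f"start={raw_start}")
            fields.append(f"end={raw_end}")
            lines.append("####" + "; ".join(fields))
        for el in elements:
            lines.append(_format_data_line(el, doc.columns, headers))
    return "\n".join(lines) + "\n"


def _format_data_line(el: TrackElement, columns: ColumnSpec, headers: HeaderSet) -> str:
    raw_start, raw_end = denormalize_coordinates(
        el.start, el.end, headers.one_indexed, headers.end_inclusive
    )
    cells = []
    for name in columns.names:
        role = columns.role_of(name, headers)
        if role == "seqid":
            cells.append(el.seqid)
        elif role == "genome":
            cells.append(el.genome if el.genome is not None else _MISSING)
        elif role == "start":
            cells.append(str(raw_start) if raw_start is not None else _MISSING)
        elif role == "end":
            cells.append(str(raw_end) if raw_end is not None else _MISSING)
        elif role == "value":
            cells.append(
                format_value(el.value, headers.value_type, headers.value_dimension)
            )
        elif role == "strand":
            cells.append(el.strand if el.strand is not None else _MISSING)
        elif role == "id":
            cells.append(el.id if el.id is not None else _MISSING)
        elif role == "edges":
            cells.append(format_edges(el.edges, headers))
        else:
            cell = el.extra(name)
            cells.append(cell if cell is not None else _MISSING)
    line = "\t".join(cells)
    if headers.fixed_size_data_lines:
        line = line.ljust(headers.data_line_size)
    return line


def _complete_reciprocal_edges(groups):
    """Add any missing reciprocal edges (undirected graphs only)."""
    all_edges: dict[str, dict[str, Any]] = {}
    for _, elements in groups:
        for el in elements:
            if el.id is not None and el.edges:
                all_edges.setdefault(el.id, {})
                for e in el.edges:
                    all_edges[el.id][e.target_id] = e.weight
    out = []
    for region, elements in groups:
        new_elements = []
        for el in elements:
            if el.id is not None and el.edges is not None:
                have = {e.target_id for e in el.edges}
                missing = tuple(
                    EdgeRef(target_id=src, weight=targets[el.id])
                    for src, targets in all_edges.items()
                    if el.id in targets and src not in have
                )
                if missing:
                    el = dataclasses.replace(el, edges=el.edges + missing)
            new_elements.append(el)
        out.append((region, new_elements))
    return out


# ---------------------------------------------------------------------------
# Header expansion and subtypes
# ---------------------------------------------------------------------------


def infer_value_type(cells: Iterable[str]) -> tuple[str, str]:
    """Infer (value type, value dimension) from raw value cells.

    Inference is conservative: numbers win whenever every component
    parses as a number (so 0/1-coded data stays ``number``); otherwise
    single characters, otherwise ``category``.  ``binary`` is never
    inferred — it narrows beyond the evidence.
    """
    dimension = "scalar"
    components: list[str] = []
    for cell in cells:
        if cell == _MISSING:
            continue
        if "," in cell:
            dimension = "list"
            components.extend(cell.split(","))
        else:
            components.append(cell)
    if not components:
        return "number", dimension

    def all_parse(vtype: str) -> bool:
        try:
            for c in components:
                _parse_scalar(c, vtype, None)
        except GTrackParseError:
            return False
        return True

    for vtype in ("number", "character", "category"):
        if all_parse(vtype):
            return vtype, dimension
    return "category", dimension


def _elements_sorted(doc: GTrackDocument) -> bool:
    regions = [r for r, _ in doc.groups if r is not None]
    keys = [(r.genome or "", r.seqid, r.start) for r in regions]
    if keys != sorted(keys):
        return False
    for region, elements in doc.groups:
        spans = [el.span for el in elements if el.start is not None]
        if spans != sorted(spans):
            return False
    return True


def _elements_overlap(doc: GTrackDocument) -> bool:
    by_seqid: dict[str, list[tuple[int, int]]] = {}
    for el in doc.elements():
        try:
            span = el.span
        except ValueError:
            continue
        by_seqid.setdefault(el.seqid, []).append(span)
    for spans in by_seqid.values():
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                return True
    return False


def expand_headers(doc: GTrackDocument) -> HeaderSet:
    """Fill in header variables by inspecting the document contents.

    Sets the track type from the columns, verifies sortedness, overlap
    freedom and data-line contiguity over the data, and marks every
    variable explicit so a full header block is written.  Inference
    never contradicts the data and never narrows a declared value type.
    """
    headers = doc.headers
    changes: dict[str, Any] = {
        "track_type": doc.columns.implied_track_type(headers),
        "sorted_elements": _elements_sorted(doc),
        "no_overlapping_elements": not _elements_overlap(doc),
        "uninterrupted_data_lines": sum(
            1 for _, els in doc.groups if els
        ) <= 1,
    }
    new = headers.replace(**changes)
    return dataclasses.replace(new, explicit=frozenset(HEADER_FIELDS))


def expand_headers_text(text: str) -> str:
    """The "expand headers" tool on raw text: returns the same document
    with a complete header block.

    The value type, if undeclared, is first inferred from the raw value
    cells so that files with e.g. category values but minimal headers
    still parse.
    """
    injected = text
    probe = parse_document(_strip_data(text))
    headers = probe.headers
    if "value_type" not in headers.explicit and probe.columns.has_role(
        "value", headers
    ):
        col_idx = probe.columns.names.index(
            probe.columns.column_for_role("value", headers)
        )
        cells = []
        for line in text.replace("\r\n", "\n").split("\n"):
            if line and not line.startswith("#"):
                parts = line.split("\t")
                if col_idx < len(parts):
                    cells.append(parts[col_idx])
        vtype, vdim = infer_value_type(cells)
        extra = f"##Value type: {vtype}\n##Value dimension: {vdim}\n"
        injected = extra + text
    doc = parse_document(injected)
    full = expand_headers(doc)
    return write_document(
        dataclasses.replace(doc, headers=full), emit_defaults=True
    )


def _strip_data(text: str) -> str:
    kept = [
        line
        for line in text.replace("\r\n", "\n").split("\n")
        if line.startswith("##") and not line.startswith("####")
    ]
    return "\n".join(kept) + "\n"


_SUBTYPE_FIELDS = {"subtype_name", "subtype_version", "subtype_url", "subtype_adherence"}


def resolve_subtype(doc: GTrackDocument, model: GTrackDocument) -> GTrackDocument:
    """Merge a subtype model document under a document's own headers.

    The model (a GTrack file with headers and a column specification,
    referenced by the ``subtype URL`` header) supplies every header the
    document does not itself state, and the column specification when
    the document has none — allowing a complete header block to shrink
    to a single subtype line.  Under ``free`` adherence the document's
    own explicit headers win; under ``strict`` adherence any deviation
    from the model is an error.
    """
    adherence = doc.headers.subtype_adherence
    if adherence not in ADHERENCE_MODES:
        raise GTrackParseError(
            f"unsupported subtype adherence {adherence!r}", code=RuleCode.HEADER
        )
    merged_kwargs: dict[str, Any] = {}
    explicit: set[str] = set()
    for field_name in HEADER_FIELDS:
        if field_name in _SUBTYPE_FIELDS:
            merged_kwargs[field_name] = getattr(doc.headers, field_name)
            if field_name in doc.headers.explicit:
                explicit.add(field_name)
            continue
        doc_has = field_name in doc.headers.explicit
        model_has = field_name in model.headers.explicit
        if doc_has and model_has and adherence == "strict":
            if getattr(doc.headers, field_name) != getattr(model.headers, field_name):
                raise GTrackParseError(
                    f"strict subtype adherence: header {field_name!r} deviates "
                    f"from the subtype model",
                    code=RuleCode.HEADER,
                )
        if doc_has:
            merged_kwargs[field_name] = getattr(doc.headers, field_name)
            explicit.add(field_name)
        elif model_has:
            merged_kwargs[field_name] = getattr(model.headers, field_name)
            explicit.add(field_name)
        else:
            merged_kwargs[field_name] = getattr(doc.headers, field_name)
    headers = HeaderSet(explicit=frozenset(explicit), **merged_kwargs)

    if doc.column_spec_declared and model.column_spec_declared:
        if adherence == "strict" and doc.columns != model.columns:
            raise GTrackParseError(
                "strict subtype adherence: column specification deviates from "
                "the subtype model",
                code=RuleCode.HEADER,
            )
        columns = doc.columns
    elif doc.column_spec_declared:
        columns = doc.columns
    else:
        columns = model.columns

    if "track_type" not in explicit:
        headers = dataclasses.replace(
            headers, track_type=columns.implied_track_type(headers)
        )
    return GTrackDocument(
        headers=headers,
        columns=columns,
        groups=doc.groups,
        comments=doc.comments,
        column_spec_declared=True,
    )


# ---------------------------------------------------------------------------
# File helpers
# ---------------------------------------------------------------------------


def read_gtrack(path) -> GTrackDocument:
    """Parse a GTrack file from *path* (UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return parse_document(fh.read())


def write_gtrack(doc: GTrackDocument, path, **kwargs) -> None:
    """Write a document to *path* (UTF-8, Unix line endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(write_document(doc, **kwargs))
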