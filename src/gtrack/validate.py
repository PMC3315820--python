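"""The "validate GTrack file" tool.

Validation is total: every problem is returned as a typed, located
:class:`~gtrack.issues.ValidationIssue`, never raised.  An empty issue
list means the file is fully conformant with the format and with its own
declared structural headers — the headers are promises (sortedness,
overlap freedom, fixed line sizes, ...) that a quick downstream script
may rely on without scanning the data.
"""

from __future__ import annotations

from typing import Any

from .document import GTrackDocument
from .io import parse_document
from .issues import GTrackParseError, RuleCode, Severity, ValidationIssue
from .track_model import TrackType, is_dense, type_to_properties

__all__ = ["validate", "assert_structure", "ValidationIssue", "RuleCode", "Severity"]


def _issue(
    code: RuleCode,
    message: str,
    line_number: int | None = None,
    severity: Severity = Severity.ERROR,
) -> ValidationIssue:
    return ValidationIssue(
        code=code, severity=severity, message=message, line_number=line_number
    )


def validate(source: str | GTrackDocument) -> list[ValidationIssue]:
    """Check raw GTrack text or a parsed document; return all issues found.

    Structural problems that prevent parsing (wrong column counts,
    broken dense tiling, malformed values, ...) are reported with the
    rule code carried by the parser.  Issues are ordered by line number,
    then code, for deterministic output.
    """
    if isinstance(source, GTrackDocument):
        doc = source
    else:
        try:
            doc = parse_document(source)
        except GTrackParseError as exc:
            return [exc.as_issue()]
    issues: list[ValidationIssue] = []
    issues += _check_columns_vs_type(doc)       # R1, R2
    issues += _check_ids_and_edges(doc)         # R4, R5, R6
    issues += _check_sortedness(doc)            # R7
    issues += _check_overlaps(doc)              # R8
    issues += _check_dense_regions(doc)         # R9
    issues += _check_elements_in_regions(doc)   # R12
    issues += _check_region_overlap(doc)        # R13
    issues += _check_strands(doc)               # R14
    issues += _check_strict_model(doc)          # R15
    issues.sort(key=lambda i: i.sort_key)
    return issues


def _check_columns_vs_type(doc: GTrackDocument) -> list[ValidationIssue]:
    issues = []
    problem = doc.columns.check_against_type(doc.headers, doc.track_type)
    if problem is not None:
        issues.append(_issue(RuleCode.R1, problem))
    if doc.columns.has_role("edges", doc.headers) and not doc.columns.has_role(
        "id", doc.headers
    ):
        issues.append(
            _issue(RuleCode.R2, "the edges column requires the id column to be present")
        )
    return issues


def _check_ids_and_edges(doc: GTrackDocument) -> list[ValidationIssue]:
    issues = []
    seen: dict[str, int | None] = {}
    for el in doc.elements():
        if el.id is None:
            continue
        if el.id in seen:
            issues.append(
                _issue(
                    RuleCode.R4,
                    f"duplicate id {el.id!r} (first seen at line {seen[el.id]})",
                    el.line_number,
                )
            )
        else:
            seen[el.id] = el.line_number
    edges_by_id: dict[str, dict[str, Any]] = {}
    for el in doc.elements():
        if not el.edges:
            continue
        if el.id is not None:
            edges_by_id[el.id] = {e.target_id: e.weight for e in el.edges}
        for e in el.edges:
            if e.target_id not in seen:
                issues.append(
                    _issue(
                        RuleCode.R5,
                        f"edge target {e.target_id!r} does not match any element id",
                        el.line_number,
                    )
                )
    if doc.headers.undirected_edges:
        for el in doc.elements():
            if not el.edges or el.id is None:
                continue
            for e in el.edges:
                back = edges_by_id.get(e.target_id, {})
                if el.id not in back:
                    issues.append(
                        _issue(
                            RuleCode.R6,
                            f"undirected edge {el.id!r}->{e.target_id!r} lacks its "
                            f"reciprocal",
                            el.line_number,
                        )
                    )
                elif back[el.id] != e.weight:
                    issues.append(
                        _issue(
                            RuleCode.R6,
                            f"undirected edge {el.id!r}<->{e.target_id!r} has "
                            f"unequal weights",
                            el.line_number,
                        )
                    )
    return issues


def _check_sortedness(doc: GTrackDocument) -> list[ValidationIssue]:
    if not doc.headers.sorted_elements:
        return []
    issues = []
    regions = [r for r, _ in doc.groups if r is not None]
    keys = [(r.genome or "", r.seqid, r.start) for r in regions]
    for prev, cur, region in zip(keys, keys[1:], regions[1:]):
        if cur < prev:
            issues.append(
                _issue(
                    RuleCode.R7,
                    "bounding regions are not in sorted order",
                    region.line_number,
                )
            )
    if is_dense(doc.track_type):
        return issues
    for region, elements in doc.groups:
        spans = []
        for el in elements:
            try:
                spans.append((el.span, el.line_number))
            except ValueError:
                continue
        for (prev, _), (cur, lineno) in zip(spans, spans[1:]):
            if cur < prev:
                issues.append(
                    _issue(
                        RuleCode.R7,
                        "track elements are not in sorted order",
                        lineno,
                    )
                )
    return issues


def _check_overlaps(doc: GTrackDocument) -> list[ValidationIssue]:
    if not doc.headers.no_overlapping_elements:
        return []
    issues = []
    by_seqid: dict[str, list[tuple[int, int, int | None]]] = {}
    for el in doc.elements():
        try:
            s, e = el.span
        except ValueError:
            continue
        by_seqid.setdefault(el.seqid, []).append((s, e, el.line_number))
    for seqid, spans in by_seqid.items():
        spans.sort(key=lambda t: (t[0], t[1]))
        for (s1, e1, _), (s2, _, lineno) in zip(spans, spans[1:]):
            if s2 < e1:
                issues.append(
                    _issue(
                        RuleCode.R8,
                        f"overlapping track elements on {seqid} despite "
                        f"'no overlapping elements: true'",
                        lineno,
                    )
                )
    return issues


def _check_dense_regions(doc: GTrackDocument) -> list[ValidationIssue]:
    if not is_dense(doc.track_type):
        return []
    issues = []
    has_region = any(r is not None for r, _ in doc.groups)
    if doc.n_elements and not has_region:
        issues.append(
            _issue(RuleCode.R9, "dense track types require bounding regions")
        )
        return issues
    props = type_to_properties(doc.track_type)
    for region, elements in doc.groups:
        if region is None:
            if elements:
                issues.append(
                    _issue(
                        RuleCode.R9,
                        "dense track data outside any bounding region",
                        elements[0].line_number,
                    )
                )
            continue
        if props.lengths:
            prev = region.start
            ok = True
            for el in elements:
                if el.start != prev or el.end is None:
                    ok = False
                    break
                prev = el.end
            if not ok or prev != region.end:
                issues.append(
                    _issue(
                        RuleCode.R9,
                        f"dense elements do not tile bounding region "
                        f"{region.seqid}:[{region.start},{region.end})",
                        region.line_number,
                    )
                )
        else:
            if len(elements) != region.length:
                issues.append(
                    _issue(
                        RuleCode.R9,
                        f"per-bp dense region of length {region.length} holds "
                        f"{len(elements)} elements",
                        region.line_number,
                    )
                )
    return issues


def _check_elements_in_regions(doc: GTrackDocument) -> list[ValidationIssue]:
    issues = []
    for region, elements in doc.groups:
        if region is None:
            continue
        for el in elements:
            try:
                s, e = el.span
            except ValueError:
                continue
            if el.seqid != region.seqid or s < region.start or e > region.end:
                issues.append(
                    _issue(
                        RuleCode.R12,
                        f"element {el.seqid}:[{s},{e}) lies outside its bounding "
                        f"region {region.seqid}:[{region.start},{region.end})",
                        el.line_number,
                    )
                )
    return issues


def _check_region_overlap(doc: GTrackDocument) -> list[ValidationIssue]:
    issues = []
    by_seqid: dict[tuple[str | None, str], list] = {}
    for r in doc.regions:
        by_seqid.setdefault((r.genome, r.seqid), []).append(r)
    for regions in by_seqid.values():
        regions.sort(key=lambda r: (r.start, r.end))
        for r1, r2 in zip(regions, regions[1:]):
            if r2.start < r1.end:
                issues.append(
                    _issue(
                        RuleCode.R13,
                        f"bounding regions overlap on {r1.seqid}: "
                        f"[{r1.start},{r1.end}) and [{r2.start},{r2.end})",
                        r2.line_number,
                    )
                )
    return issues


def _check_strands(doc: GTrackDocument) -> list[ValidationIssue]:
    issues = []
    for el in doc.elements():
        if el.strand is not None and el.strand not in ("+", "-", "."):
            issues.append(
                _issue(
                    RuleCode.R14,
                    f"invalid strand {el.strand!r} (expected +, - or .)",
                    el.line_number,
                )
            )
    return issues


def _check_strict_model(doc: GTrackDocument) -> list[ValidationIssue]:
    """Formal-model strictness: a length-1 segment equals a point, and the
    model excludes such segments; files may carry them, so this is only a
    warning."""
    props = type_to_properties(doc.track_type)
    if not (props.gaps and props.lengths):
        return []
    issues = []
    for el in doc.elements():
        if el.length == 1:
            issues.append(
                _issue(
                    RuleCode.R15,
                    f"length-1 segment at {el.seqid}:{el.start} is a point under "
                    f"the formal model",
                    el.line_number,
                    severity=Severity.WARNING,
                )
            )
    return issues


def assert_structure(
    doc: GTrackDocument,
    track_type: TrackType | str | None = None,
    **header_expectations: Any,
) -> bool:
    """Check a document's headers against stated expectations.

    The quick-script contract: e.g. require that the track type is
    segments with no overlapping elements, and fail explicitly if the
    header does not match.  Only stated expectations are checked; an
    empty requirement is vacuously true.
    """
    if track_type is not None:
        expected = (
            TrackType.from_name(track_type)
            if isinstance(track_type, str)
            else track_type
        )
        if doc.track_type != expected:
            return False
    for field_name, expected_value in header_expectations.items():
        if not hasattr(doc.headers, field_name):
            raise ValueError(f"unknown header variable {field_name!r}")
        if getattr(doc.headers, field_name) != expected_value:
            return False
    return True
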