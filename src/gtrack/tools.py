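"""Document-level tools: sort, standardize to linked valued segments,
and complement columns from another document."""

from __future__ import annotations

import dataclasses
import warnings

from .document import (
    ColumnSpec,
    GTrackDocument,
    HeaderSet,
    TrackElement,
)
from .track_model import TrackType, is_dense, type_to_properties

__all__ = ["sort_gtrack", "standardize_gtrack", "complement_columns"]

#: Above this many output elements, per-bp standardization of a function
#: track warns about the size explosion.
STANDARDIZE_WARN_THRESHOLD = 10**6


def _element_sort_key(el: TrackElement):
    try:
        span = el.span
    except ValueError:
        span = (-1, -1)
    return (span, el.id or "")


def sort_gtrack(doc: GTrackDocument) -> GTrackDocument:
    """Sort bounding regions and, for sparse types, the elements within
    each region; dense blocks keep their order (it is semantic).

    Idempotent; the multiset of elements is unchanged.  The output
    declares ``sorted elements: true``.
    """

    def region_key(group):
        region, _ = group
        if region is None:
            return (0, "", "", -1)
        return (1, region.genome or "", region.seqid, region.start)

    groups = sorted(doc.groups, key=region_key)
    if not is_dense(doc.track_type):
        groups = [
            (region, sorted(elements, key=_element_sort_key))
            for region, elements in groups
        ]
    headers = doc.headers.replace(sorted_elements=True)
    return dataclasses.replace(doc, headers=headers, groups=groups)


def _default_id(el: TrackElement, taken: set[str]) -> str:
    """The default indexing scheme: ``seqid:start-end`` in canonical
    coordinates, with ``.k`` suffixes on collisions."""
    s, e = el.span
    base = f"{el.seqid}:{s}-{e}"
    if base not in taken:
        return base
    k = 1
    while f"{base}.{k}" in taken:
        k += 1
    return f"{base}.{k}"


def standardize_gtrack(doc: GTrackDocument) -> GTrackDocument:
    """Convert any of the fifteen types to linked valued segments (LVS).

    Every element becomes an explicit segment carrying value, id and
    edges columns ("." where undefined): points become length-1
    segments, partitions and step functions keep their parts, functions
    expand to one segment per base pair (with a warning above
    ``STANDARDIZE_WARN_THRESHOLD`` elements).  Existing ids and edges
    are preserved; missing ids come from the default indexing scheme.
    """
    props = type_to_properties(doc.track_type)
    if not props.lengths and not props.gaps:
        n_out = doc.n_elements
        if n_out > STANDARDIZE_WARN_THRESHOLD:
            warnings.warn(
                f"standardizing a per-bp dense track expands to {n_out} "
                f"segments",
                stacklevel=2,
            )

    taken = {el.id for el in doc.elements() if el.id is not None}
    new_groups = []
    for region, elements in doc.groups:
        new_elements = []
        for el in elements:
            start, end = el.span
            new_id = el.id
            if new_id is None:
                new_id = _default_id(el, taken)
                taken.add(new_id)
            new_elements.append(
                dataclasses.replace(
                    el,
                    start=start,
                    end=end,
                    id=new_id,
                    edges=el.edges if el.edges is not None else (),
                )
            )
        new_groups.append((region, new_elements))

    names = ["seqid", "start", "end", "value"]
    if any(el.strand is not None for el in doc.elements()):
        names.append("strand")
    names += ["id", "edges"]
    extra_names = [n for n, _ in next(doc.elements()).extras] if doc.n_elements else []
    names += [n for n in extra_names if n not in names]

    headers = HeaderSet().replace(
        track_type=TrackType.LVS,
        value_type=doc.headers.value_type,
        value_dimension=doc.headers.value_dimension,
        undirected_edges=doc.headers.undirected_edges,
        edge_weights=doc.headers.edge_weights,
        edge_weight_type=doc.headers.edge_weight_type,
        edge_weight_dimension=doc.headers.edge_weight_dimension,
        one_indexed=doc.headers.one_indexed,
        end_inclusive=doc.headers.end_inclusive,
        sorted_elements=doc.headers.sorted_elements,
        no_overlapping_elements=doc.headers.no_overlapping_elements,
    )
    return GTrackDocument(
        headers=headers,
        columns=ColumnSpec(names=tuple(names)),
        groups=new_groups,
        comments=doc.comments,
    )


def complement_columns(
    target: GTrackDocument, source: GTrackDocument, key: str = "id"
) -> GTrackDocument:
    """Append columns present in *source* but absent in *target*,
    matching rows by *key* (``"id"`` or ``"position"``).

    Unmatched target rows receive "." in the new columns; existing
    target cells are never overwritten and the row count never changes.
    Duplicate keys in the source are ambiguous and raise ``ValueError``.
    """
    if key not in ("id", "position"):
        raise ValueError("key must be 'id' or 'position'")

    def key_of(el: TrackElement):
        if key == "id":
            return el.id
        try:
            return (el.seqid,) + el.span
        except ValueError:
            return None

    source_by_key: dict = {}
    for el in source.elements():
        k = key_of(el)
        if k is None:
            continue
        if k in source_by_key:
            raise ValueError(f"ambiguous {key} key in source document: {k!r}")
        source_by_key[k] = el

    new_names = [
        name for name in source.columns.names if name not in target.columns.names
    ]
    if not new_names:
        return dataclasses.replace(target)

    headers = target.headers
    value_added = any(
        source.columns.role_of(n, source.headers) == "value" for n in new_names
    ) and not target.columns.has_role("value", headers)
    edges_added = any(
        source.columns.role_of(n, source.headers) == "edges" for n in new_names
    ) and not target.columns.has_role("edges", headers)
    if value_added:
        headers = headers.replace(
            value_type=source.headers.value_type,
            value_dimension=source.headers.value_dimension,
            value_column=source.headers.value_column,
        )
    if edges_added:
        headers = headers.replace(
            edges_column=source.headers.edges_column,
            edge_weights=source.headers.edge_weights,
            undirected_edges=source.headers.undirected_edges,
            edge_weight_type=source.headers.edge_weight_type,
            edge_weight_dimension=source.headers.edge_weight_dimension,
        )

    new_groups = []
    for region, elements in target.groups:
        new_elements = []
        for el in elements:
            match = source_by_key.get(key_of(el))
            changes: dict = {}
            extras = list(el.extras)
            for name in new_names:
                role = source.columns.role_of(name, source.headers)
                if match is None:
                    if role == "extra":
                        extras.append((name, "."))
                    continue
                if role == "value" and el.value is None:
                    changes["value"] = match.value
                elif role == "edges" and el.edges is None:
                    changes["edges"] = match.edges
                elif role == "strand" and el.strand is None:
                    changes["strand"] = match.strand
                elif role == "id" and el.id is None:
                    changes["id"] = match.id
                elif role == "genome" and el.genome is None:
                    changes["genome"] = match.genome
                elif role == "extra":
                    cell = match.extra(name)
                    extras.append((name, cell if cell is not None else "."))
            changes["extras"] = tuple(extras)
            new_elements.append(dataclasses.replace(el, **changes))
        new_groups.append((region, new_elements))

    columns = ColumnSpec(names=target.columns.names + tuple(new_names))
    try:
        track_type = columns.implied_track_type(headers)
        headers = headers.replace(track_type=track_type)
    except ValueError:
        pass
    return dataclasses.replace(
        target, headers=headers, columns=columns, groups=new_groups
    )
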