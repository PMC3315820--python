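"""On-disk columnar representation of a track with a linear index.

The core informational columns are stored per sequence as fixed-width
little-endian binary vectors written directly to disk and memory-mapped
back as NumPy arrays: coordinates as 8-byte integers, numeric values as
8-byte floats, binary values and characters as single bytes, categories
dictionary-encoded as 4-byte codes with a sidecar string table.  Edge
lists are flattened with an offsets vector; element ids, strands and
extra columns live in a plain-text sidecar.

Random region access goes through a linear index: for each ``bin_size``
bp bin, the ordinal of the first element (in start-sorted order) whose
end reaches past the bin start.  Everything before that ordinal ends at
or before the bin, so a query scans forward from it and stops at the
first element starting at or past the query end.

The store records a content hash of its source file; staleness is
detected, never auto-repaired.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np

from .document import EdgeRef, GTrackDocument, HeaderSet, TrackElement
from .track_model import TrackType, type_to_properties

__all__ = ["TrackStore", "build_store", "query_region", "store_is_stale"]

DEFAULT_BIN_SIZE = 1024

_ENDIAN = "<"
_COORD_DTYPE = np.dtype(f"{_ENDIAN}i8")
_FLOAT_DTYPE = np.dtype(f"{_ENDIAN}f8")
_BYTE_DTYPE = np.dtype("u1")
_CODE_DTYPE = np.dtype(f"{_ENDIAN}i4")


def _value_dtype(value_type: str) -> np.dtype:
    return {
        "number": _FLOAT_DTYPE,
        "binary": _BYTE_DTYPE,
        "character": np.dtype("S1"),
        "category": _CODE_DTYPE,
    }[value_type]


@dataclass
class _SeqData:
    """All vectors of one sequence."""

    starts: np.ndarray | None
    ends: np.ndarray | None
    values: np.ndarray | None
    edge_offsets: np.ndarray | None
    edge_targets: list[str]
    edge_weights: np.ndarray | None
    payload: list[tuple[str | None, str | None, tuple[tuple[str, str], ...]]]
    regions: list[tuple[int, int]]
    category_table: list[str]
    n: int


@dataclass
class TrackStore:
    """A built (or opened) column-vector store with its linear index."""

    directory: str
    track_type: TrackType
    headers: HeaderSet
    bin_size: int
    source_hash: str | None
    seqids: list[str]
    data: dict[str, _SeqData] = field(repr=False, default_factory=dict)
    index: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def per_bp(self) -> bool:
        props = type_to_properties(self.track_type)
        return not props.gaps and not props.lengths

    def element_count(self, seqid: str | None = None) -> int:
        if seqid is not None:
            return self.data[seqid].n
        return sum(d.n for d in self.data.values())

    def elements(self, seqid: str) -> list[TrackElement]:
        return _materialize(self, seqid, range(self.data[seqid].n))

    def all_elements(self) -> list[TrackElement]:
        out = []
        for seqid in self.seqids:
            out.extend(self.elements(seqid))
        return out


def _spans(doc_elements: list[TrackElement]) -> np.ndarray:
    return np.array([el.span for el in doc_elements], dtype=np.int64).reshape(-1, 2)


def _encode_values(elements, headers, table: list[str]) -> np.ndarray:
    vt = headers.value_type
    dtype = _value_dtype(vt)
    if vt == "number":
        return np.array(
            [np.nan if el.value is None else float(el.value) for el in elements],
            dtype=dtype,
        )
    if vt == "binary":
        return np.array(
            [255 if el.value is None else int(el.value) for el in elements],
            dtype=dtype,
        )
    if vt == "character":
        return np.array(
            [b"." if el.value is None else str(el.value).encode() for el in elements],
            dtype=dtype,
        )
    codes = []
    lookup = {c: i for i, c in enumerate(table)}
    for el in elements:
        if el.value is None:
            codes.append(-1)
            continue
        key = str(el.value)
        if key not in lookup:
            lookup[key] = len(table)
            table.append(key)
        codes.append(lookup[key])
    return np.array(codes, dtype=dtype)


def _decode_value(raw, value_type: str, table: list[str]):
    if value_type == "number":
        v = float(raw)
        return None if np.isnan(v) else v
    if value_type == "binary":
        return None if int(raw) == 255 else int(raw)
    if value_type == "character":
        s = bytes(raw).decode()
        return None if s == "." else s
    code = int(raw)
    return None if code < 0 else table[code]


def build_store(doc: GTrackDocument, directory: str | os.PathLike,
                bin_size: int = DEFAULT_BIN_SIZE,
                source_path: str | os.PathLike | None = None) -> TrackStore:
    """Write a document's elements to a column-vector store directory.

    The document must be sorted (per sequence, by element start) and
    scalar-valued; a full scan of the store reproduces its elements
    exactly.  When ``source_path`` is given its content hash is recorded
    for staleness detection.
    """
    if doc.headers.value_dimension != "scalar":
        raise ValueError("list-valued tracks are not supported by the binary store")
    props = type_to_properties(doc.track_type)
    per_bp = not props.gaps and not props.lengths

    by_seqid: dict[str, list[TrackElement]] = {}
    regions_by_seqid: dict[str, list[tuple[int, int]]] = {}
    for region, elements in doc.groups:
        if region is not None:
            regions_by_seqid.setdefault(region.seqid, []).append(
                (region.start, region.end)
            )
        for el in elements:
            by_seqid.setdefault(el.seqid, []).append(el)

    os.makedirs(directory, exist_ok=True)
    store = TrackStore(
        directory=str(directory),
        track_type=doc.track_type,
        headers=doc.headers,
        bin_size=bin_size,
        source_hash=_hash_file(source_path) if source_path else None,
        seqids=sorted(by_seqid),
    )
    for seqid in store.seqids:
        elements = by_seqid[seqid]
        spans = _spans(elements)
        if np.any(np.diff(spans[:, 0]) < 0):
            raise ValueError(
                f"elements on {seqid} are not sorted by start; sort the "
                f"document before building a store"
            )
        starts = None if per_bp else spans[:, 0].astype(_COORD_DTYPE)
        ends = (
            spans[:, 1].astype(_COORD_DTYPE)
            if (props.lengths and not per_bp)
            else None
        )
        table: list[str] = []
        values = (
            _encode_values(elements, doc.headers, table) if props.values else None
        )
        edge_offsets = edge_weights = None
        edge_targets: list[str] = []
        if props.interconnections:
            offsets = [0]
            weights: list[float] = []
            for el in elements:
                for e in el.edges or ():
                    edge_targets.append(e.target_id)
                    weights.append(
                        np.nan if e.weight is None else float(e.weight)
                    )
                offsets.append(len(edge_targets))
            edge_offsets = np.array(offsets, dtype=_COORD_DTYPE)
            edge_weights = np.array(weights, dtype=_FLOAT_DTYPE)
        payload = [
            (el.id, el.strand, el.extras) for el in elements
        ]
        data = _SeqData(
            starts=starts,
            ends=ends,
            values=values,
            edge_offsets=edge_offsets,
            edge_targets=edge_targets,
            edge_weights=edge_weights,
            payload=payload,
            regions=regions_by_seqid.get(seqid, []),
            category_table=table,
            n=len(elements),
        )
        store.data[seqid] = data
        store.index[seqid] = _build_index(store, seqid, spans)
        _write_seq_files(store, seqid, data)
    _write_metadata(store)
    return store


def _effective_spans(store: TrackStore, seqid: str) -> np.ndarray:
    """(start, end) pairs for every element, materializing per-bp types."""
    d = store.data[seqid]
    if store.per_bp:
        positions = np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in d.regions]
        ) if d.regions else np.arange(d.n, dtype=np.int64)
        return np.stack([positions, positions + 1], axis=1)
    starts = d.starts.astype(np.int64)
    ends = (
        d.ends.astype(np.int64) if d.ends is not None else starts + 1
    )
    return np.stack([starts, ends], axis=1)


def _build_index(store: TrackStore, seqid: str, spans: np.ndarray) -> np.ndarray:
    """bin -> ordinal of the first element whose end exceeds the bin start."""
    bs = store.bin_size
    max_end = int(spans[:, 1].max()) if len(spans) else 0
    n_bins = max_end // bs + 1
    index = np.full(n_bins, len(spans), dtype=np.int64)
    # Monotone: raising the bin start only shrinks {i: end_i > bin_start},
    # so a single pointer sweep suffices.
    ptr = 0
    ends = spans[:, 1]
    for b in range(n_bins):
        threshold = b * bs
        while ptr < len(ends) and ends[ptr] <= threshold:
            ptr += 1
        index[b] = ptr
    return index


def query_region(
    store: TrackStore, seqid: str, start: int, end: int
) -> list[TrackElement]:
    """All elements overlapping ``[start, end)`` on *seqid*, in genomic
    order — equal to a brute-force scan of the source document."""
    if seqid not in store.data:
        raise KeyError(f"unknown seqid {seqid!r}")
    if end <= start:
        return []
    spans = _effective_spans(store, seqid)
    if not len(spans):
        return []
    index = store.index[seqid]
    b = min(start // store.bin_size, len(index) - 1)
    i0 = int(index[b])
    hits = []
    for i in range(i0, len(spans)):
        s, e = int(spans[i, 0]), int(spans[i, 1])
        if s >= end:
            break
        if e > start:
            hits.append(i)
    return _materialize(store, seqid, hits)


def _materialize(store: TrackStore, seqid: str, ordinals) -> list[TrackElement]:
    d = store.data[seqid]
    props = type_to_properties(store.track_type)
    spans = _effective_spans(store, seqid)
    out = []
    for i in ordinals:
        start: int | None = int(spans[i, 0])
        end: int | None = int(spans[i, 1])
        if not props.lengths:
            end = None
        if not props.gaps and not props.lengths:
            pass  # per-bp: keep the implicit position as start
        value = (
            _decode_value(d.values[i], store.headers.value_type, d.category_table)
            if d.values is not None
            else None
        )
        edges: tuple[EdgeRef, ...] | None = None
        if d.edge_offsets is not None:
            lo, hi = int(d.edge_offsets[i]), int(d.edge_offsets[i + 1])
            edges = tuple(
                EdgeRef(
                    target_id=d.edge_targets[j],
                    weight=None
                    if np.isnan(d.edge_weights[j])
                    else float(d.edge_weights[j]),
                )
                for j in range(lo, hi)
            )
        el_id, strand, extras = d.payload[i]
        out.append(
            TrackElement(
                seqid=seqid,
                start=start,
                end=end,
                value=value,
                strand=strand,
                id=el_id,
                edges=edges,
                extras=extras,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------


def _seq_path(store: TrackStore, seqid: str, column: str) -> str:
    return os.path.join(store.directory, f"{seqid}.{column}")


def _write_seq_files(store: TrackStore, seqid: str, d: _SeqData) -> None:
    if d.starts is not None:
        d.starts.tofile(_seq_path(store, seqid, "start.bin"))
    if d.ends is not None:
        d.ends.tofile(_seq_path(store, seqid, "end.bin"))
    if d.values is not None:
        d.values.tofile(_seq_path(store, seqid, "value.bin"))
    if d.category_table:
        with open(_seq_path(store, seqid, "value.dict.txt"), "w") as fh:
            fh.write("\n".join(d.category_table) + "\n")
    if d.edge_offsets is not None:
        d.edge_offsets.tofile(_seq_path(store, seqid, "edge_offsets.bin"))
        d.edge_weights.tofile(_seq_path(store, seqid, "edge_weights.bin"))
        with open(_seq_path(store, seqid, "edge_targets.txt"), "w") as fh:
            fh.write("\n".join(d.edge_targets) + ("\n" if d.edge_targets else ""))
    store.index[seqid].tofile(_seq_path(store, seqid, "index.bin"))
    with open(_seq_path(store, seqid, "payload.tsv"), "w") as fh:
        for el_id, strand, extras in d.payload:
            cells = [el_id or ".", strand or ""]
            for name, cell in extras:
                cells.append(f"{name}={cell}")
            fh.write("\t".join(cells) + "\n")


def _write_metadata(store: TrackStore) -> None:
    lines = [
        f"track type: {store.track_type.value}",
        f"value type: {store.headers.value_type}",
        f"edge weight type: {store.headers.edge_weight_type}",
        f"bin size: {store.bin_size}",
    ]
    if store.source_hash:
        lines.append(f"source hash: {store.source_hash}")
    for seqid in store.seqids:
        d = store.data[seqid]
        regions = ";".join(f"{s}-{e}" for s, e in d.regions)
        lines.append(f"seq: {seqid}\t{d.n}\t{regions}")
    with open(os.path.join(store.directory, "metadata.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _hash_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def store_is_stale(
    store: TrackStore, source_path: str | os.PathLike
) -> bool:
    """Whether the source file changed (or vanished) since the store was
    built.  Conservative: an unhashed store is considered stale."""
    if store.source_hash is None:
        return True
    if not os.path.exists(source_path):
        return True
    return _hash_file(source_path) != store.source_hash
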