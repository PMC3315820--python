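"""Deterministic synthetic GTrack documents for all fifteen track types,
plus a corruptor injecting single validation-rule violations.

The generator produces structurally valid documents — geometry, typing
and linking follow the track-type definitions — with no claim of
biological realism: values are uniform floats in [0, 1), characters are
drawn from {A, C, G, T}, categories from cat0..cat9.  A single integer
seed drives all randomness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .document import (
    BoundingRegion,
    ColumnSpec,
    EdgeRef,
    GTrackDocument,
    HeaderSet,
    TrackElement,
)
from .io import denormalize_coordinates, write_document
from .issues import RuleCode
from .track_model import TrackType, is_dense, type_to_properties

__all__ = ["GenomeSpec", "FixtureParams", "generate", "generate_all_types", "corrupt"]


@dataclass(frozen=True)
class GenomeSpec:
    """Sequence names with lengths (bp) and the master seed."""

    seqids: tuple[tuple[str, int], ...] = (("chr1", 300), ("chr2", 200))
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.seqids):
            raise ValueError("sequence lengths must be positive")


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of one synthetic document."""

    track_type: TrackType = TrackType.S
    n_elements: int = 20
    value_type: str = "number"
    value_dimension: str = "scalar"
    edge_density: float = 0.3
    edge_weights: bool = False
    undirected: bool = False
    one_indexed: bool = False
    end_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in [0, 1]")


def _draw_value(rng: np.random.Generator, params: FixtureParams):
    def scalar():
        if params.value_type == "number":
            return round(float(rng.uniform(0, 1)), 6)
        if params.value_type == "binary":
            return int(rng.integers(0, 2))
        if params.value_type == "character":
            return "ACGT"[rng.integers(0, 4)]
        return f"cat{rng.integers(0, 10)}"

    if params.value_dimension == "list":
        return tuple(scalar() for _ in range(int(rng.integers(2, 4))))
    return scalar()


def _sparse_layout(
    rng: np.random.Generator, length: int, n: int, with_lengths: bool
) -> list[tuple[int, int | None]]:
    """Non-overlapping sorted spans within [0, length)."""
    if with_lengths:
        lengths = rng.integers(2, 9, size=n)
        gaps = rng.integers(1, 6, size=n + 1)
        needed = int(lengths.sum() + gaps.sum())
        if needed > length:
            raise ValueError(
                f"cannot fit {n} segments in a {length} bp sequence"
            )
        spans = []
        pos = int(gaps[0])
        for seg_len, gap in zip(lengths, gaps[1:]):
            spans.append((pos, pos + int(seg_len)))
            pos += int(seg_len) + int(gap)
        return spans
    if n > length:
        raise ValueError(f"cannot place {n} points on a {length} bp sequence")
    positions = np.sort(rng.choice(length, size=n, replace=False))
    return [(int(p), None) for p in positions]


def _dense_partition(rng: np.random.Generator, length: int, n: int) -> list[int]:
    """n strictly increasing part ends, the last equal to length."""
    if n > length:
        raise ValueError(f"cannot partition {length} bp into {n} parts")
    if n == 1:
        return [length]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n - 1, replace=False))
    return [int(c) for c in cuts] + [length]


def _columns_for(params: FixtureParams) -> ColumnSpec:
    t = params.track_type
    props = type_to_properties(t)
    names: list[str] = []
    dense = is_dense(t)
    if not dense:
        names.append("seqid")
        names.append("start")
    if props.lengths:
        names.append("end")
    if props.values:
        names.append("value")
    if not dense and not props.interconnections:
        names.append("strand")
    if props.interconnections:
        names += ["id", "edges"]
    return ColumnSpec(names=tuple(names))


def generate(params: FixtureParams, genome: GenomeSpec) -> GTrackDocument:
    """A valid, deterministic document of the requested type.

    Sparse documents carry one bounding region per sequence covering the
    whole sequence, sorted elements, and no overlaps; dense documents
    tile their regions exactly.  Dense documents omit the seqid column
    (elements inherit it from the bounding region), sparse ones state it.
    """
    t = params.track_type
    props = type_to_properties(t)
    type_index = list(TrackType).index(t)
    rng = np.random.default_rng([genome.seed % 2**31, type_index])
    columns = _columns_for(params)

    headers = HeaderSet().replace(
        track_type=t,
        value_type=params.value_type,
        value_dimension=params.value_dimension,
        undirected_edges=params.undirected,
        edge_weights=params.edge_weights,
        sorted_elements=True,
        no_overlapping_elements=True,
        one_indexed=params.one_indexed,
        end_inclusive=params.end_inclusive,
    )

    groups: list[tuple[BoundingRegion | None, list[TrackElement]]] = []
    counter = 0
    n_seqs = len(genome.seqids)
    for seqid, length in genome.seqids:
        region = BoundingRegion(seqid=seqid, start=0, end=length)
        elements: list[TrackElement] = []
        if is_dense(t):
            if props.lengths:
                n_parts = max(1, params.n_elements // n_seqs)
                ends = _dense_partition(rng, length, n_parts)
                prev = 0
                for end in ends:
                    elements.append(
                        _make_element(seqid, prev, end, rng, params, props, counter)
                    )
                    prev = end
                    counter += 1
            else:
                for pos in range(length):
                    elements.append(
                        _make_element(seqid, pos, None, rng, params, props, counter)
                    )
                    counter += 1
        else:
            n = max(1, params.n_elements // n_seqs)
            for start, end in _sparse_layout(rng, length, n, props.lengths):
                elements.append(
                    _make_element(seqid, start, end, rng, params, props, counter)
                )
                counter += 1
        groups.append((region, elements))

    doc = GTrackDocument(headers=headers, columns=columns, groups=groups)
    if props.interconnections:
        doc = _add_edges(doc, rng, params)
    return doc


def _make_element(seqid, start, end, rng, params, props, counter) -> TrackElement:
    value = _draw_value(rng, params) if props.values else None
    strand = None
    if not is_dense(params.track_type) and not props.interconnections:
        strand = ["+", "-", "."][rng.integers(0, 3)]
    return TrackElement(
        seqid=seqid,
        start=start,
        end=end,
        value=value,
        strand=strand,
        id=f"e{counter}" if props.interconnections else None,
        edges=() if props.interconnections else None,
    )


def _add_edges(
    doc: GTrackDocument, rng: np.random.Generator, params: FixtureParams
) -> GTrackDocument:
    ids = [el.id for el in doc.elements()]
    edges_of: dict[str, list[EdgeRef]] = {i: [] for i in ids}
    if len(ids) >= 2:
        for i, el_id in enumerate(ids):
            if rng.uniform() >= params.edge_density:
                continue
            j = int(rng.integers(0, len(ids) - 1))
            if j >= i:
                j += 1
            target = ids[j]
            weight = (
                round(float(rng.uniform(0, 1)), 6) if params.edge_weights else None
            )
            if any(e.target_id == target for e in edges_of[el_id]):
                continue
            edges_of[el_id].append(EdgeRef(target_id=target, weight=weight))
            if params.undirected and not any(
                e.target_id == el_id for e in edges_of[target]
            ):
                edges_of[target].append(EdgeRef(target_id=el_id, weight=weight))
    new_groups = []
    for region, elements in doc.groups:
        new_groups.append(
            (
                region,
                [
                    dataclasses.replace(el, edges=tuple(edges_of[el.id]))
                    for el in elements
                ],
            )
        )
    return dataclasses.replace(doc, groups=new_groups)


def generate_all_types(
    genome: GenomeSpec, seed: int | None = None
) -> dict[TrackType, GTrackDocument]:
    """One valid document per track type: fifteen documents, fifteen
    pairwise distinct inferred types."""
    if seed is not None:
        genome = dataclasses.replace(genome, seed=seed)
    out = {}
    for t in TrackType:
        out[t] = generate(FixtureParams(track_type=t), genome)
    return out


# ---------------------------------------------------------------------------
# Corruptor
# ---------------------------------------------------------------------------


class RuleNotApplicable(ValueError):
    """The requested rule cannot be violated on a document of this type."""


def _split(text: str) -> list[str]:
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    return lines


def _data_line_indices(lines: list[str]) -> list[int]:
    return [
        i for i, line in enumerate(lines) if line and not line.startswith("#")
    ]


def _region_line_indices(lines: list[str]) -> list[int]:
    return [i for i, line in enumerate(lines) if line.startswith("####")]


def _set_cell(lines: list[str], idx: int, col: int, cell: str) -> None:
    parts = lines[idx].split("\t")
    parts[col] = cell
    lines[idx] = "\t".join(parts)


def _clear_edges(lines: list[str], doc: GTrackDocument) -> None:
    col = doc.columns.names.index(
        doc.columns.column_for_role("edges", doc.headers)
    )
    for i in _data_line_indices(lines):
        _set_cell(lines, i, col, ".")


def _col_index(doc: GTrackDocument, role: str) -> int:
    name = doc.columns.column_for_role(role, doc.headers)
    if name is None:
        raise RuleNotApplicable(f"document has no {role} column")
    return doc.columns.names.index(name)


def corrupt(doc: GTrackDocument, rule_code: RuleCode | str) -> str:
    """Serialize *doc* and inject a violation of exactly one rule.

    The mutation is chosen so that no other error code is triggered
    where avoidable.  Raises :class:`RuleNotApplicable` when the
    document's type cannot exhibit the violation.
    """
    code = RuleCode(rule_code)
    text = write_document(doc)
    lines = _split(text)
    t = doc.track_type
    props = type_to_properties(t)
    data = _data_line_indices(lines)
    if not data:
        raise RuleNotApplicable("document has no data lines")

    if code is RuleCode.R1:
        other = TrackType.S if t is not TrackType.S else TrackType.P
        lines = [l for l in lines if not l.lower().startswith("##track type")]
        lines.insert(0, f"##Track type: {other.value}")
    elif code is RuleCode.R2:
        if not props.interconnections:
            raise RuleNotApplicable("R2 needs an edges column")
        _clear_edges(lines, doc)
        id_col = _col_index(doc, "id")
        spec_idx = next(i for i, l in enumerate(lines) if l.startswith("###") and not l.startswith("####"))
        names = lines[spec_idx][3:].split("\t")
        names[id_col] = "ident"
        lines[spec_idx] = "###" + "\t".join(names)
    elif code is RuleCode.R3:
        lines[data[0]] = "\t".join(lines[data[0]].split("\t")[:-1])
    elif code is RuleCode.R4:
        if not props.interconnections:
            raise RuleNotApplicable("R4 needs an id column")
        if len(data) < 2:
            raise RuleNotApplicable("R4 needs at least two elements")
        _clear_edges(lines, doc)
        id_col = _col_index(doc, "id")
        first_id = lines[data[0]].split("\t")[id_col]
        _set_cell(lines, data[1], id_col, first_id)
    elif code is RuleCode.R5:
        if not props.interconnections:
            raise RuleNotApplicable("R5 needs an edges column")
        edges_col = _col_index(doc, "edges")
        _set_cell(lines, data[0], edges_col, "no_such_id")
        if doc.headers.edge_weights:
            _set_cell(lines, data[0], edges_col, "no_such_id=0.5")
    elif code is RuleCode.R6:
        if not doc.headers.undirected_edges:
            raise RuleNotApplicable("R6 needs undirected edges")
        edges_col = _col_index(doc, "edges")
        target = next(
            (i for i in data if lines[i].split("\t")[edges_col] != "."), None
        )
        if target is None:
            raise RuleNotApplicable("document has no edges to corrupt")
        _set_cell(lines, target, edges_col, ".")
    elif code is RuleCode.R7:
        if is_dense(t):
            raise RuleNotApplicable("dense element order is semantic")
        if len(data) < 2:
            raise RuleNotApplicable("R7 needs at least two elements")
        i, j = data[0], data[1]
        lines[i], lines[j] = lines[j], lines[i]
    elif code is RuleCode.R8:
        if is_dense(t) or not props.gaps:
            raise RuleNotApplicable("R8 corruption targets sparse documents")
        if len(data) < 2:
            raise RuleNotApplicable("R8 needs at least two elements")
        start_col = _col_index(doc, "start")
        first_start = lines[data[0]].split("\t")[start_col]
        _set_cell(lines, data[1], start_col, first_start)
    elif code is RuleCode.R9:
        if not is_dense(t):
            raise RuleNotApplicable("R9 applies to dense documents")
        if props.lengths:
            end_col = _col_index(doc, "end")
            last = data[-1]
            raw_end = int(lines[last].split("\t")[end_col])
            _set_cell(lines, last, end_col, str(raw_end - 1))
        else:
            lines.pop(data[-1])
    elif code is RuleCode.R10:
        if not props.values:
            raise RuleNotApplicable("R10 needs a value column")
        if doc.headers.value_type == "category":
            raise RuleNotApplicable("any tab-free string is a valid category")
        value_col = _col_index(doc, "value")
        _set_cell(lines, data[0], value_col, "xx")
    elif code is RuleCode.R11:
        actual = len(lines[data[0]])
        lines.insert(0, f"##Data line size: {actual + 7}")
        lines.insert(0, "##Fixed-size data lines: true")
    elif code is RuleCode.R12:
        if is_dense(t):
            raise RuleNotApplicable("dense tiling violations are rule R9")
        regions = doc.regions
        if not regions:
            raise RuleNotApplicable("R12 needs bounding regions")
        group_idx = next(
            i for i, (r, els) in enumerate(doc.groups) if r is not None and els
        )
        region, elements = doc.groups[group_idx]
        n_before = sum(len(els) for _, els in doc.groups[:group_idx])
        line_idx = data[n_before + len(elements) - 1]
        start_col = _col_index(doc, "start")
        new_start = region.end + 10
        raw_start, raw_end = denormalize_coordinates(
            new_start,
            new_start + 5 if props.lengths else None,
            doc.headers.one_indexed,
            doc.headers.end_inclusive,
        )
        _set_cell(lines, line_idx, start_col, str(raw_start))
        if props.lengths:
            _set_cell(lines, line_idx, _col_index(doc, "end"), str(raw_end))
    elif code is RuleCode.R13:
        if is_dense(t):
            raise RuleNotApplicable("duplicating a dense region breaks tiling too")
        region_idx = _region_line_indices(lines)
        if not region_idx:
            raise RuleNotApplicable("R13 needs bounding regions")
        lines.append(lines[region_idx[-1]])
    elif code is RuleCode.R14:
        strand_col = _col_index(doc, "strand")
        _set_cell(lines, data[0], strand_col, "x")
    elif code is RuleCode.R15:
        if not (props.gaps and props.lengths):
            raise RuleNotApplicable("R15 applies to segment-bearing sparse types")
        first = next(el for el in doc.elements())
        _, raw_end = denormalize_coordinates(
            first.start,
            first.start + 1,
            doc.headers.one_indexed,
            doc.headers.end_inclusive,
        )
        _set_cell(lines, data[0], _col_index(doc, "end"), str(raw_end))
    else:
        raise RuleNotApplicable(f"no corruption defined for {code}")
    return "\n".join(lines) + "\n"
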