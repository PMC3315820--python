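"""Converters between the internal track model and BED, bedGraph, WIG
(fixedStep/variableStep) and GFF3, plus a generic tabular importer and an
analytic representation-size estimator.

Coordinate conventions of the external formats:

* BED and bedGraph are 0-based, half-open — identical to the canonical
  internal convention;
* WIG and GFF3 are 1-based; WIG positions denote the first covered base
  of a span, GFF3 ends are inclusive.

GFF3 line parsing and attribute handling are delegated to ``gffutils``.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils.feature

from .document import (
    BoundingRegion,
    ColumnSpec,
    EdgeRef,
    GTrackDocument,
    HeaderSet,
    TrackElement,
)
from .io import parse_document
from .track_model import TrackType, is_dense, type_to_properties

__all__ = [
    "BedRecord",
    "BedGraphRecord",
    "WigBlock",
    "GffRecord",
    "read_bed",
    "write_bed",
    "bed_to_gtrack",
    "gtrack_to_bed",
    "read_bedgraph",
    "write_bedgraph",
    "bedgraph_to_gtrack",
    "gtrack_to_bedgraph",
    "read_wig",
    "write_wig",
    "wig_to_gtrack",
    "gtrack_to_wig",
    "read_gff",
    "write_gff",
    "gff_to_gtrack",
    "gtrack_to_gff",
    "tabular_to_gtrack",
    "estimate_representation_size",
]


class UnsupportedConversion(ValueError):
    """The document's track type cannot be expressed in the target format."""


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedRecord:
    """One BED line (3–12 populated leading fields, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: int | None = None
    strand: str | None = None
    thick_start: int | None = None
    thick_end: int | None = None
    item_rgb: str | None = None
    block_count: int | None = None
    block_sizes: tuple[int, ...] | None = None
    block_starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.block_count is not None:
            if (
                self.block_sizes is None
                or self.block_starts is None
                or len(self.block_sizes) != self.block_count
                or len(self.block_starts) != self.block_count
            ):
                raise ValueError("blockCount inconsistent with block lists")


def _int_list(cell: str) -> tuple[int, ...]:
    return tuple(int(x) for x in cell.rstrip(",").split(",") if x != "")


def read_bed(text: str) -> list[BedRecord]:
    records = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"BED line has fewer than 3 fields: {line!r}")
        records.append(
            BedRecord(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                name=f[3] if len(f) > 3 else None,
                score=int(f[4]) if len(f) > 4 else None,
                strand=f[5] if len(f) > 5 else None,
                thick_start=int(f[6]) if len(f) > 6 else None,
                thick_end=int(f[7]) if len(f) > 7 else None,
                item_rgb=f[8] if len(f) > 8 else None,
                block_count=int(f[9]) if len(f) > 9 else None,
                block_sizes=_int_list(f[10]) if len(f) > 10 else None,
                block_starts=_int_list(f[11]) if len(f) > 11 else None,
            )
        )
    return records


_BED_FIELDS = (
    "name",
    "score",
    "strand",
    "thick_start",
    "thick_end",
    "item_rgb",
    "block_count",
    "block_sizes",
    "block_starts",
)
_BED_DEFAULTS = (".", "0", ".", None, None, "0", None, None, None)


def write_bed(records: list[BedRecord]) -> str:
    n_fields = 3
    for r in records:
        for i, name in enumerate(_BED_FIELDS):
            if getattr(r, name) is not None:
                n_fields = max(n_fields, 4 + i)
    lines = []
    for r in records:
        cells = [r.chrom, str(r.start), str(r.end)]
        for i, name in enumerate(_BED_FIELDS):
            if 4 + i > n_fields:
                break
            v = getattr(r, name)
            if v is None:
                v = _BED_DEFAULTS[i]
                if v is None:
                    v = str(r.start) if name == "thick_start" else (
                        str(r.end) if name == "thick_end" else "0"
                    )
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            cells.append(str(v))
        lines.append("\t".join(cells))
    return "\n".join(lines) + ("\n" if lines else "")


def bed_to_gtrack(records: list[BedRecord], mode: str = "direct") -> GTrackDocument:
    """BED records as a GTrack document.

    ``direct``: one element per record; the score (when any record has
    one) becomes the value column, other optional BED fields become
    extra columns; the type is S or VS.  ``linked``: each record's
    blocks become child segments carrying an edge to their parent
    record; parent ids come from the name field (else ``bedN``), child
    ids are ``parentId.k``; the type is LS or LVS.
    """
    if mode not in ("direct", "linked"):
        raise ValueError("mode must be 'direct' or 'linked'")
    has_score = any(r.score is not None for r in records)
    has_strand = any(r.strand is not None for r in records)
    if mode == "direct":
        extra_fields = [
            ("name", "name"),
            ("thickStart", "thick_start"),
            ("thickEnd", "thick_end"),
            ("itemRgb", "item_rgb"),
            ("blockCount", "block_count"),
            ("blockSizes", "block_sizes"),
            ("blockStarts", "block_starts"),
        ]
        used = [
            (col, attr)
            for col, attr in extra_fields
            if any(getattr(r, attr) is not None for r in records)
        ]
        names = ["seqid", "start", "end"]
        if has_score:
            names.append("value")
        if has_strand:
            names.append("strand")
        names += [col for col, _ in used]
        elements = []
        for r in records:
            extras = []
            for col, attr in used:
                v = getattr(r, attr)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                extras.append((col, str(v) if v is not None else "."))
            elements.append(
                TrackElement(
                    seqid=r.chrom,
                    start=r.start,
                    end=r.end,
                    value=float(r.score) if (has_score and r.score is not None) else None,
                    strand=r.strand if has_strand else None,
                    extras=tuple(extras),
                )
            )
        t = TrackType.VS if has_score else TrackType.S
    else:
        names = ["seqid", "start", "end"]
        if has_score:
            names.append("value")
        names += ["id", "edges"]
        elements = []
        for i, r in enumerate(records):
            parent_id = r.name if r.name else f"bed{i}"
            elements.append(
                TrackElement(
                    seqid=r.chrom,
                    start=r.start,
                    end=r.end,
                    value=float(r.score) if (has_score and r.score is not None) else None,
                    id=parent_id,
                    edges=(),
                )
            )
            if r.block_count:
                for k, (size, offset) in enumerate(
                    zip(r.block_sizes, r.block_starts)
                ):
                    elements.append(
                        TrackElement(
                            seqid=r.chrom,
                            start=r.start + offset,
                            end=r.start + offset + size,
                            value=None,
                            id=f"{parent_id}.{k}",
                            edges=(EdgeRef(target_id=parent_id),),
                        )
                    )
        t = TrackType.LVS if has_score else TrackType.LS
    headers = HeaderSet().replace(track_type=t)
    return GTrackDocument(
        headers=headers,
        columns=ColumnSpec(names=tuple(names)),
        groups=[(None, elements)],
    )


_BED_EXPORTABLE = {
    TrackType.P,
    TrackType.S,
    TrackType.VP,
    TrackType.VS,
    TrackType.LS,
    TrackType.LVS,
}


def gtrack_to_bed(doc: GTrackDocument) -> list[BedRecord]:
    """Sparse point/segment documents as BED records; points become
    length-1 intervals.  Dense types have no BED representation."""
    if doc.track_type not in _BED_EXPORTABLE:
        raise UnsupportedConversion(
            f"track type {doc.track_type.value!r} has no BED representation"
        )
    records = []
    for el in doc.elements():
        start, end = el.span
        score = None
        if el.value is not None and not isinstance(el.value, tuple):
            score = int(round(float(el.value)))
        name = el.id if el.id is not None else el.extra("name")
        records.append(
            BedRecord(
                chrom=el.seqid,
                start=start,
                end=end,
                name=name,
                score=score,
                strand=el.strand if el.strand in ("+", "-") else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedGraphRecord:
    chrom: str
    start: int
    end: int
    value: float


def read_bedgraph(text: str) -> list[BedGraphRecord]:
    records = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) != 4:
            raise ValueError(f"bedGraph line must have 4 fields: {line!r}")
        records.append(
            BedGraphRecord(chrom=f[0], start=int(f[1]), end=int(f[2]), value=float(f[3]))
        )
    return records


def write_bedgraph(records: list[BedGraphRecord]) -> str:
    lines = [
        "\t".join(
            (
                r.chrom,
                str(r.start),
                str(r.end),
                repr(int(r.value)) if float(r.value).is_integer() else repr(r.value),
            )
        )
        for r in records
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def bedgraph_to_gtrack(records: list[BedGraphRecord]) -> GTrackDocument:
    """A valued-segments document: bedGraph is the sparse, varying-size
    counterpart of WIG."""
    elements = [
        TrackElement(seqid=r.chrom, start=r.start, end=r.end, value=float(r.value))
        for r in records
    ]
    headers = HeaderSet().replace(track_type=TrackType.VS)
    return GTrackDocument(
        headers=headers,
        columns=ColumnSpec(names=("seqid", "start", "end", "value")),
        groups=[(None, elements)],
    )


def gtrack_to_bedgraph(doc: GTrackDocument) -> list[BedGraphRecord]:
    props = type_to_properties(doc.track_type)
    if props.interconnections:
        raise UnsupportedConversion("linked track types have no bedGraph form")
    if not props.values:
        raise UnsupportedConversion("bedGraph requires a value column")
    if doc.headers.value_type != "number" or doc.headers.value_dimension != "scalar":
        raise UnsupportedConversion("bedGraph values must be scalar numbers")
    records = []
    for el in doc.elements():
        start, end = el.span
        records.append(
            BedGraphRecord(chrom=el.seqid, start=start, end=end, value=float(el.value))
        )
    return records


# ---------------------------------------------------------------------------
# WIG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WigBlock:
    """One WIG declaration block.

    ``fixedStep`` lines are bare values stepping from ``start`` (1-based)
    by ``step``; ``variableStep`` lines carry their own 1-based start.
    ``lines`` holds floats for fixedStep and ``(start1, value)`` pairs
    for variableStep; every covered interval spans ``span`` bases.
    """

    mode: str
    chrom: str
    span: int = 1
    step: int | None = None
    start: int | None = None
    lines: tuple = ()

    def __post_init__(self) -> None:
        if self.mode not in ("fixedStep", "variableStep"):
            raise ValueError("mode must be fixedStep or variableStep")
        if self.span < 1:
            raise ValueError("span must be positive")
        if self.mode == "fixedStep":
            if self.step is None or self.start is None:
                raise ValueError("fixedStep requires step and start")
            if self.step < self.span:
                raise ValueError("fixedStep requires step >= span")


def read_wig(text: str) -> list[WigBlock]:
    blocks: list[WigBlock] = []
    header: dict | None = None
    lines_acc: list = []

    def flush():
        nonlocal header, lines_acc
        if header is not None:
            blocks.append(WigBlock(lines=tuple(lines_acc), **header))
        header, lines_acc = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith(("fixedStep", "variableStep")):
            flush()
            parts = line.split()
            mode = parts[0]
            kv = dict(p.split("=", 1) for p in parts[1:])
            header = {
                "mode": mode,
                "chrom": kv["chrom"],
                "span": int(kv.get("span", 1)),
            }
            if mode == "fixedStep":
                header["start"] = int(kv["start"])
                header["step"] = int(kv["step"])
        else:
            if header is None:
                raise ValueError(f"WIG data before any declaration line: {line!r}")
            if header["mode"] == "fixedStep":
                lines_acc.append(float(line))
            else:
                pos, val = line.split()
                lines_acc.append((int(pos), float(val)))
    flush()
    return blocks


def _fmt_num(v: float) -> str:
    return repr(int(v)) if float(v).is_integer() else repr(float(v))


def write_wig(blocks: list[WigBlock]) -> str:
    out = []
    for b in blocks:
        if b.mode == "fixedStep":
            out.append(
                f"fixedStep chrom={b.chrom} start={b.start} step={b.step} span={b.span}"
            )
            out += [_fmt_num(v) for v in b.lines]
        else:
            out.append(f"variableStep chrom={b.chrom} span={b.span}")
            out += [f"{pos}\t{_fmt_num(v)}" for pos, v in b.lines]
    return "\n".join(out) + ("\n" if out else "")


def wig_to_gtrack(blocks: list[WigBlock]) -> GTrackDocument:
    """Typing rules: variableStep span=1 → valued points; variableStep
    span>1 → valued segments; fixedStep step=span → step function (dense,
    one bounding region per block, end positions used for positioning);
    fixedStep step>span → valued segments encoded compactly with
    ``fixed length`` / ``fixed gap size`` headers."""
    if not blocks:
        raise ValueError("no WIG blocks")
    modes = {b.mode for b in blocks}
    if modes == {"variableStep"}:
        spans = {b.span for b in blocks}
        if spans == {1}:
            elements = []
            for b in blocks:
                prev = None
                for pos1, val in b.lines:
                    if prev is not None and pos1 <= prev:
                        raise ValueError("overlapping spans within a WIG block")
                    prev = pos1
                    elements.append(
                        TrackElement(seqid=b.chrom, start=pos1 - 1, value=val)
                    )
            headers = HeaderSet().replace(track_type=TrackType.VP)
            return GTrackDocument(
                headers=headers,
                columns=ColumnSpec(names=("seqid", "start", "value")),
                groups=[(None, elements)],
            )
        elements = []
        for b in blocks:
            prev_end = None
            for pos1, val in b.lines:
                start = pos1 - 1
                if prev_end is not None and start < prev_end:
                    raise ValueError("overlapping spans within a WIG block")
                prev_end = start + b.span
                elements.append(
                    TrackElement(
                        seqid=b.chrom, start=start, end=start + b.span, value=val
                    )
                )
        headers = HeaderSet().replace(track_type=TrackType.VS)
        return GTrackDocument(
            headers=headers,
            columns=ColumnSpec(names=("seqid", "start", "end", "value")),
            groups=[(None, elements)],
        )
    if modes != {"fixedStep"}:
        raise UnsupportedConversion(
            "mixed fixedStep/variableStep WIG input is not supported"
        )
    if all(b.step == b.span for b in blocks):
        groups = []
        for b in blocks:
            region_start = b.start - 1
            region = BoundingRegion(
                seqid=b.chrom,
                start=region_start,
                end=region_start + len(b.lines) * b.span,
            )
            elements = []
            prev = region_start
            for val in b.lines:
                elements.append(
                    TrackElement(
                        seqid=b.chrom, start=prev, end=prev + b.span, value=float(val)
                    )
                )
                prev += b.span
            groups.append((region, elements))
        headers = HeaderSet().replace(track_type=TrackType.SF)
        return GTrackDocument(
            headers=headers,
            columns=ColumnSpec(names=("end", "value")),
            groups=groups,
        )
    spans = {b.span for b in blocks}
    steps = {b.step for b in blocks}
    if len(spans) != 1 or len(steps) != 1:
        raise UnsupportedConversion(
            "fixedStep blocks with differing span/step cannot share fixed "
            "geometry headers"
        )
    span, step = spans.pop(), steps.pop()
    groups = []
    for b in blocks:
        region_start = b.start - 1
        region_end = region_start + (len(b.lines) - 1) * step + span
        region = BoundingRegion(seqid=b.chrom, start=region_start, end=region_end)
        elements = []
        pos = region_start
        for val in b.lines:
            elements.append(
                TrackElement(
                    seqid=b.chrom,
                    start=pos,
                    end=pos + span if span > 1 else None,
                    value=float(val),
                )
            )
            pos += step
        groups.append((region, elements))
    # span-1 elements are single base pairs: valued points, not segments
    t = TrackType.VS if span > 1 else TrackType.VP
    headers = HeaderSet().replace(
        track_type=t, fixed_length=span, fixed_gap_size=step - span
    )
    if span == 1:
        headers = HeaderSet().replace(
            track_type=t, fixed_gap_size=step - span
        )
    return GTrackDocument(
        headers=headers,
        columns=ColumnSpec(names=("value",)),
        groups=groups,
    )


def gtrack_to_wig(doc: GTrackDocument) -> list[WigBlock]:
    """Dense uniform data exports as fixedStep, sparse as variableStep.

    Varying element sizes have no WIG form; bedGraph is the recommended
    format for sparse or varying-size continuous data."""
    if doc.headers.value_type != "number" or doc.headers.value_dimension != "scalar":
        raise UnsupportedConversion("WIG values must be scalar numbers")
    t = doc.track_type
    if t == TrackType.VP:
        return _variable_blocks(doc, span=1)
    if t == TrackType.VS:
        lengths = {el.length for el in doc.elements()}
        if len(lengths) > 1:
            raise UnsupportedConversion(
                "valued segments of varying lengths have no WIG form; "
                "use bedGraph for sparse or varying-size continuous data"
            )
        return _variable_blocks(doc, span=lengths.pop() if lengths else 1)
    if t == TrackType.SF:
        blocks = []
        for region, elements in doc.groups:
            lengths = {el.length for el in elements}
            if len(lengths) != 1:
                raise UnsupportedConversion(
                    "step function with non-uniform part lengths has no WIG "
                    "form; use bedGraph for varying-size continuous data"
                )
            span = lengths.pop()
            blocks.append(
                WigBlock(
                    mode="fixedStep",
                    chrom=region.seqid,
                    start=region.start + 1,
                    step=span,
                    span=span,
                    lines=tuple(float(el.value) for el in elements),
                )
            )
        return blocks
    if t == TrackType.F:
        blocks = []
        for region, elements in doc.groups:
            blocks.append(
                WigBlock(
                    mode="fixedStep",
                    chrom=region.seqid,
                    start=region.start + 1,
                    step=1,
                    span=1,
                    lines=tuple(float(el.value) for el in elements),
                )
            )
        return blocks
    raise UnsupportedConversion(f"track type {t.value!r} has no WIG representation")


def _variable_blocks(doc: GTrackDocument, span: int) -> list[WigBlock]:
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for el in doc.elements():
        by_chrom.setdefault(el.seqid, []).append((el.start + 1, float(el.value)))
    return [
        WigBlock(mode="variableStep", chrom=chrom, span=span, lines=tuple(lines))
        for chrom, lines in by_chrom.items()
    ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GffRecord:
    """One GFF3 data line: nine tab-separated fields, 1-based inclusive
    coordinates, "." for missing, attributes as an ordered multimap."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    phase: str
    attributes: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def attr(self, key: str) -> tuple[str, ...] | None:
        for k, v in self.attributes:
            if k == key:
                return v
        return None


def read_gff(text: str) -> list[GffRecord]:
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"GFF3 data line must have 9 fields: {line!r}")
        f = gffutils.feature.feature_from_line(line)
        records.append(
            GffRecord(
                seqid=f.seqid,
                source=f.source,
                type=f.featuretype,
                start=f.start,
                end=f.end,
                score=None if f.score in (".", "", None) else float(f.score),
                strand=f.strand,
                phase=f.frame,
                attributes=tuple(
                    (k, tuple(v)) for k, v in f.attributes.items()
                ),
            )
        )
    return records


def write_gff(records: list[GffRecord]) -> str:
    lines = ["##gff-version 3"]
    for r in records:
        attr_text = ";".join(
            f"{k}={','.join(vals)}" for k, vals in r.attributes
        ) or "."
        lines.append(
            "\t".join(
                (
                    r.seqid,
                    r.source,
                    r.type,
                    str(r.start),
                    str(r.end),
                    "." if r.score is None else _fmt_num(r.score),
                    r.strand,
                    r.phase,
                    attr_text,
                )
            )
        )
    return "\n".join(lines) + "\n"


def gff_to_gtrack(records: list[GffRecord], link_parents: bool = False) -> GTrackDocument:
    """GFF3 records as a GTrack document.

    The score becomes the value column; source, type and phase become
    extra columns, as does the union of all attribute keys present
    anywhere in the input ("." where a record lacks one).  With
    ``link_parents`` the ID/Parent attributes populate the id and edges
    columns instead and the type becomes linked.
    """
    has_score = any(r.score is not None for r in records)
    attr_keys = sorted({k for r in records for k, _ in r.attributes})
    consumed = {"ID", "Parent"} if link_parents else set()
    extra_attr_keys = [k for k in attr_keys if k not in consumed]
    names = ["seqid", "start", "end"]
    if has_score:
        names.append("value")
    names += ["strand", "source", "type", "phase"]
    if link_parents:
        names += ["id", "edges"]
    names += extra_attr_keys
    elements = []
    for i, r in enumerate(records):
        extras = [
            ("source", r.source),
            ("type", r.type),
            ("phase", r.phase),
        ]
        for k in extra_attr_keys:
            vals = r.attr(k)
            extras.append((k, ",".join(vals) if vals else "."))
        el_id = None
        edges = None
        if link_parents:
            ids = r.attr("ID")
            el_id = ids[0] if ids else f"gff{i}"
            parents = r.attr("Parent") or ()
            edges = tuple(EdgeRef(target_id=p) for p in parents)
        elements.append(
            TrackElement(
                seqid=r.seqid,
                start=r.start - 1,
                end=r.end,
                value=float(r.score) if (has_score and r.score is not None) else None,
                strand=r.strand,
                id=el_id,
                edges=edges,
                extras=tuple(extras),
            )
        )
    if link_parents:
        t = TrackType.LVS if has_score else TrackType.LS
    else:
        t = TrackType.VS if has_score else TrackType.S
    headers = HeaderSet().replace(track_type=t)
    return GTrackDocument(
        headers=headers,
        columns=ColumnSpec(names=tuple(names)),
        groups=[(None, elements)],
    )


def gtrack_to_gff(doc: GTrackDocument) -> list[GffRecord]:
    """Sparse documents as GFF3: every data line has exactly nine
    fields; extra columns and edges serialize into the attributes field.

    Dense types are rejected: representing every base pair as a
    nine-column line would be highly impractical.
    """
    if is_dense(doc.track_type):
        raise UnsupportedConversion(
            "dense track types are not exported to GFF3: one nine-column "
            "line per base pair would be highly impractical"
        )
    records = []
    for el in doc.elements():
        start, end = el.span
        attrs: list[tuple[str, tuple[str, ...]]] = []
        if el.id is not None:
            attrs.append(("ID", (el.id,)))
        if el.edges:
            attrs.append(
                (
                    "edges",
                    tuple(
                        e.target_id
                        if e.weight is None
                        else f"{e.target_id}:{_fmt_num(e.weight)}"
                        for e in el.edges
                    ),
                )
            )
        source, ftype, phase = ".", ".", "."
        for k, cell in el.extras:
            if k == "source":
                source = cell
            elif k == "type":
                ftype = cell
            elif k == "phase":
                phase = cell
            elif cell != ".":
                attrs.append((k, tuple(cell.split(","))))
        score = None
        if el.value is not None and not isinstance(el.value, tuple):
            try:
                score = float(el.value)
            except (TypeError, ValueError):
                attrs.append(("value", (str(el.value),)))
        records.append(
            GffRecord(
                seqid=el.seqid,
                source=source,
                type=ftype,
                start=start + 1,
                end=end,
                score=score,
                strand=el.strand if el.strand is not None else ".",
                phase=phase,
                attributes=tuple(attrs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Generic tabular import and size estimation
# ---------------------------------------------------------------------------


def tabular_to_gtrack(
    text: str,
    column_names: tuple[str, ...] | list[str],
    one_indexed: bool = False,
    end_inclusive: bool = False,
) -> GTrackDocument:
    """Import any tab-separated file by prepending a column specification
    line (and coordinate-dialect headers when needed)."""
    header_lines = []
    if one_indexed:
        header_lines.append("##1-indexed: true")
    if end_inclusive:
        header_lines.append("##End inclusive: true")
    header_lines.append("###" + "\t".join(column_names))
    return parse_document("\n".join(header_lines) + "\n" + text)


def estimate_representation_size(
    genome_length: int,
    format: str,
    bytes_per_value: int = 5,
    bytes_per_coordinate: int = 10,
    chrom_label_bytes: int = 5,
) -> int:
    """Analytic file-size estimate for a per-bp valued track.

    fixedStep WIG costs one value plus a newline per base pair; bedGraph
    additionally repeats the chromosome label and both coordinates on
    every line (three tabs and a newline as separators).  A per-bp track
    over the ~3.1 Gbp human genome thus lands around 20 GB as WIG and
    around 100 GB as bedGraph.
    """
    if genome_length < 0:
        raise ValueError("genome length must be non-negative")
    if format == "wig":
        return genome_length * (bytes_per_value + 1)
    if format == "bedgraph":
        return genome_length * (
            bytes_per_value + 2 * bytes_per_coordinate + chrom_label_bytes + 4
        )
    raise ValueError("format must be 'wig' or 'bedgraph'")
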