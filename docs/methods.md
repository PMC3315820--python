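# Methods

## The track-type model

A genomic track is a set of track elements positioned on a genome
coordinate system. Each element may define up to four core informational
properties — gaps, lengths, values, interconnections — and a track is
typed by which combination its elements define. The package represents
this as a four-bit lattice (`CoreProperties`) with a total bijection
onto the fifteen `TrackType` members; the all-false combination raises
`EmptyTypeError` rather than mapping to a type. All derived predicates
follow from the lattice: *dense* ⇔ no gaps (7 types), *linked* ⇔
interconnections (8 types), *basic* = not linked (7 types).

Coordinates exist in two conventions. The formal model treats positions
as natural numbers under the discrete metric `d(a, b) = |a − b| + 1`, so
the interval (1, 3) covers d(1, 3) = 3 base pairs, and a segment must
satisfy end > start — a length-1 segment would be indistinguishable from
a point, so the model excludes it. Files, however, routinely contain
length-1 segment elements; the validator therefore reports them only as
a strictness warning (rule R15), never an error. Everywhere else the
package uses canonical 0-based half-open coordinates; `d` on 1-based
inclusive (a, b) equals `end − start` on the canonical image (a−1, b).

Analysis applicability is modelled as a predicate, not as statistics: an
analysis record states the core properties it requires per operand, and
it applies to a tuple of track types iff each operand type defines a
superset of the requirement (in any operand order, by default). A small
registry of named pairwise analyses over the five basic valued/unvalued
types ships as data; no statistical test is computed.

## GTrack parsing and writing

Line classes are decided by prefix length: `####` bounding region,
`###` column specification, `##` header, `#` comment, else data. The
header grammar is `##name: value` with case-insensitive names; bounding
regions are `; `-separated `key=value` pairs over genome/seqid/start/
end; the missing-value marker is a period in any cell. Weighted edges
use `target=weight` within the comma-separated edge list, with `|`
separating list-weight components — chosen to keep cells tab-free and
unambiguous.

Every header variable has a default and may be omitted; `explicit` on
`HeaderSet` records which variables were actually stated, which matters
in three places: the writer re-emits explicitly-set defaults, subtype
resolution merges only stated variables, and a stated
`fixed gap size` can stand in for the start column.

Track-type resolution: if the file declares `##Track type`, the declared
type is authoritative and the columns are checked for *compatibility* —
core columns must not exceed the type's set, and missing required
columns are acceptable only when supplied by fixed-geometry headers
(`fixed length` for end, `fixed gap size` for start). If no type is
declared, it is inferred from the columns (plus non-default geometry
headers). The table-default "segments" is thus a fallback for
column-less inference only; a strict reading under which every
headerless non-segment file is invalid would defeat the stated
compatibility of plain BED3 files. Dense positioning follows the
end-column rule: element k spans from the previous end (initially the
bounding region start) to its own end, and the final end must equal the
region end; per-bp types (F, LF, LBP) take line k as position
`region.start + k` with the line count equal to the region length.

Parsing normalizes the `1-indexed` / `end inclusive` dialect away
(`start0 = start − [1-indexed]`, `end0 = end − [1-indexed] +
[end-inclusive]`); writing re-applies whichever dialect the headers (or
writer overrides) request. Round-tripping any document through any of
the four dialect combinations reproduces the identical canonical
document.

Undirected graphs: the parser verifies reciprocity (rule R6); the
writer auto-completes missing reciprocal edges with equal weight, so
programmatically built half-graphs serialize to valid files.

Subtypes: a document naming a subtype merges the model file's stated
headers and column specification underneath its own. Under `free`
adherence the document's own headers win; under `strict` any deviation
is an error. Other adherence vocabularies are rejected explicitly, and
model resolution takes a parsed model document (callers decide how to
fetch the URL; tests use local files).

## Validation

`validate()` is total: problems come back as `ValidationIssue(code,
severity, line, message)`, sorted by line then code, never as
exceptions. Structural violations that prevent building a document at
all (wrong column count R3, broken dense tiling R9, malformed values
R10, byte-length mismatches R11, type/column mismatch R1) surface
through the parser's error object and its rule code; the remaining
rules (id uniqueness R4, edge resolution R5, reciprocity R6, sortedness
R7, overlap freedom R8, region membership R12, region overlap R13,
strand vocabulary R14) are checked on the parsed document. Severity
`warning` is reserved for formal-model strictness (R15). Elements
outside a declared bounding region are treated as errors (R12): a
bounding region defines the domain of its block.

## Converters

BED and bedGraph share the canonical coordinate convention, so those
conversions are field mappings; BED scores map to a numeric value
column, and optional BED fields become extra columns without claimed
semantics. Linked BED expansion turns each record's blocks into child
segments holding an edge to the parent record, parent ids taken from
the name field (else synthesized ordinals `bedN`), child ids
`parent.k`. WIG typing follows the density of the input: variableStep
span 1 → valued points, wider spans → valued segments, fixedStep with
step = span → step function (one bounding region per block, end-column
positioning), and fixedStep with step > span → a sparse document using
`fixed length` / `fixed gap size` headers rather than exploded
coordinates (valued points when span is 1). Exports refuse shapes the
target cannot express — varying segment lengths for WIG (the error
suggests bedGraph), dense types for BED/GFF3 — rather than silently
resampling. GFF3 import flattens the attribute column into one extra
column per key in the union over all records, period-filled, with keys
sorted so the column set is independent of record order; with
`link_parents`, ID/Parent become the id and edges columns. GFF3 export
always emits exactly nine fields, converting to 1-based inclusive
coordinates and serializing extras and edges into the attributes field
(weighted edge values use `target:weight`, since `=` is reserved by the
attribute grammar). GFF3 line parsing itself is delegated to
`gffutils`.

The size estimator is arithmetic, not I/O: a per-bp valued track costs
`L × (value + newline)` bytes as fixedStep WIG and
`L × (value + 2·coordinate + label + 3 tabs + newline)` as bedGraph.
With 5-byte values, 10-byte coordinates and 5-byte labels over a
3.1 Gbp genome this gives ≈18.6 GB vs ≈105 GB — the order-of-magnitude
gap that motivates density-aware formats.

## Tools

Sorting orders bounding regions by (genome, seqid, start) and sparse
elements by (start, end, id); dense blocks are left untouched because
their order carries the positions. Standardization rewrites any type as
linked valued segments: points become length-1 segments, partitions and
step functions keep their parts, per-bp functions expand to unit
segments (warning above 10⁶ elements, surfacing the size explosion that
makes per-bp tabular data impractical), and missing ids are assigned by
the default indexing scheme `seqid:start-end` with `.k` suffixes on
collision — human-readable, deterministic and join-stable. Existing ids
and edges are preserved so links stay resolvable. Column
complementation is a keyed left join (by id or by position) that only
ever appends columns and never overwrites existing cells; duplicate
keys in the source are ambiguous and rejected.

## Binary store

Core columns are written per sequence as fixed-width little-endian
vectors (`numpy.ndarray.tofile`): coordinates int64, numeric values
float64, binary values and characters one byte, categories
dictionary-encoded int32 with a text string table. Edge lists are
flattened with an int64 offsets vector and a float64 weights vector;
ids, strands, edge targets and extra columns go to plain-text sidecars.
Per-bp dense tracks store only the value vector; positions are implied
by the recorded bounding regions.

The linear index maps each `bin_size` (default 1024 bp) bin to the
ordinal of the first start-sorted element whose end exceeds the bin
start. Because raising the bin start only shrinks the candidate set,
the index is monotone and is built in one pointer sweep; a query scans
forward from the indexed ordinal and stops at the first element
starting at or beyond the query end, which is exact even for
overlapping elements. Stores record a SHA-256 of their source file;
staleness is reported, never auto-repaired — rebuild policy belongs to
the caller.

## Synthetic documents

The generator emulates document *structure*, not biology: sparse
layouts draw element lengths uniformly from 2–8 bp and gaps from
1–5 bp, dense partitions draw strictly increasing cut points, values
are uniform floats in [0, 1) (characters from ACGT, categories
cat0–cat9), and linked types draw edges per element with a configurable
density, with reciprocal completion for undirected graphs. One integer
seed drives everything through `numpy.random.default_rng`, so fixtures
are byte-reproducible. The default genome used in the test suite is
two sequences of 300 and 200 bp — small enough that per-bp dense types
stay in the hundreds of lines while every geometric case (multiple
regions, multiple seqids, both dialects) is exercised; passing tests
therefore demonstrate structural correctness of parsing, validation,
conversion and storage, not performance or robustness to biological
edge cases like assembly gaps or chromosome-scale data.

The corruptor serializes a valid document and injects exactly one rule
violation, editing raw cells so the mutation is dialect-safe, and
clears edge cells where needed so no second rule fires avoidably.

## Numerical and degenerate-input choices

Numbers parse as Python floats and serialize via `repr` (shortest
round-tripping form), with integral floats printed without a decimal
part. Missing values are `None` in memory and `.` in files. Empty
intervals are rejected at parse time unless `circular elements` is
declared, in which case end < start is accepted as wrapping and
length checks are deferred with a warning-level posture. An empty
document (headers only) is valid, round-trips, and builds an empty
store. Queries over empty intervals return nothing.

## Known limitations

* Subtype URLs are not fetched over the network; callers supply the
  model document.
* The store does not rebuild itself on staleness and does not support
  list-dimensioned values.
* Mixed fixedStep/variableStep WIG input is rejected rather than
  split.
* Bounding regions must state start and end; whole-sequence shorthand
  is not accepted.
* The official GTrack subtype registry and web/Galaxy presentation
  layers are out of scope.
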