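# gtrack

Type-aware handling of genomic annotation tracks: the fifteen-type track
model and the GTrack 1.0 tabular format, as a Python library and command
line tool.

## The problem

Genome-wide annotations — protein binding sites, SNPs, gene models,
per-base-pair signals such as GC content or melting temperature, Hi-C
contact maps — are all "tracks": data units positioned on a genome
coordinate system. They differ in four *core informational properties*:

* **gaps** — do elements leave parts of the genome uncovered?
* **lengths** — do elements span intervals, or single base pairs?
* **values** — is there a designated main value per element?
* **interconnections** — are elements linked to each other by edges?

Of the 2⁴ = 16 presence/absence combinations, the empty one carries no
information, leaving **fifteen track types**: Points (P), Valued Points
(VP), Segments (S), Valued Segments (VS), Genome Partition (GP), Step
Function (SF), Function (F), and their eight *linked* counterparts (LP,
LVP, LS, LVS, LGP, LSF, LF, LBP). Types without gaps are *dense*: their
elements exactly tile declared bounding regions. The type of a track
decides which representations are compact (WIG for dense data, bedGraph
for sparse varying-size data) and which analyses are meaningful (SNPs
inside exons: yes; SNPs inside melting temperature: no).

Coordinates follow two conventions. The formal model uses 1-based,
end-inclusive natural numbers with the discrete metric
`d(a, b) = |a − b| + 1` (the number of base pairs covered; `d(1, 3) = 3`).
All in-memory coordinates in this package are canonical 0-based,
half-open `[start, end)`; the bijection is `start0 = start1 − 1`,
`end0 = end1`.

The GTrack 1.0 tabular format encodes any of the fifteen types in one
grammar: `##name: value` header lines, a `###`-prefixed tab-separated
column specification, `####`-prefixed bounding regions, and data lines
whose core columns (`start`, `end`, `value`, `edges`) map one-to-one to
the four core properties. A plain three-column BED file is already a
valid GTrack segments file.

## What the package provides

* `gtrack.track_model` — the type algebra (property/type/column
  bijections, dense/linked predicates, the coordinate metric, analysis
  applicability).
* `gtrack.io` — full GTrack 1.0 parser and writer: coordinate dialects
  (0/1-based, end in/exclusive), dense positioning from end columns,
  fixed element geometry, weighted edges, header expansion, subtypes.
* `gtrack.validate` — a total validator returning typed, located issues
  (rules R1–R15), plus `assert_structure` for quick header contracts.
* `gtrack.convert` — BED (3–12 column, with linked block expansion),
  bedGraph, WIG (fixedStep/variableStep), GFF3 (attribute flattening and
  ID/Parent linking) converters, a generic tabular importer, and an
  analytic file-size estimator.
* `gtrack.tools` — sort, standardize (any type → linked valued
  segments), complement columns.
* `gtrack.store` — binary columnar storage of core columns with a
  linear index for random region queries, plus staleness detection.
* `gtrack.synth` — deterministic fixture generator for all fifteen
  types and a rule-targeted corruptor.

## Worked example

```python
from gtrack import parse_document, validate, metric_distance
from gtrack import convert as cv

text = """##Track type: step function
###end\tvalue
####seqid=chr1; start=0; end=300
100\t13.7
250\t8.1
300\t22.4
"""
doc = parse_document(text)
print("track type:", doc.track_type.value)
print("elements:", [(e.seqid, e.start, e.end, e.value) for e in doc.elements()])
print("issues:", validate(doc))
print(cv.write_bedgraph(cv.gtrack_to_bedgraph(doc)), end="")
print("d(1, 3) =", metric_distance(1, 3))
```

prints

```
track type: step function
elements: [('chr1', 0, 100, 13.7), ('chr1', 100, 250, 8.1), ('chr1', 250, 300, 22.4)]
issues: []
chr1	0	100	13.7
chr1	100	250	8.1
chr1	250	300	22.4
d(1, 3) = 3
```

The step function is dense: data lines carry only end positions and
values, and the parser materializes each part from the previous end
(starting at the bounding region start), checking that the parts tile
the region exactly. The empty issue list says the file conforms to the
format and to its own declared structure; flattening to bedGraph makes
the implicit starts explicit.

The same functionality is exposed on the command line:

```sh
gtrack validate --in track.gtrack
gtrack convert --in a.bed --from bed --to gtrack --mode linked
gtrack sort --in unsorted.gtrack --out sorted.gtrack
gtrack standardize --in any.gtrack
gtrack synth --out-dir fixtures/ --seed 7
```

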