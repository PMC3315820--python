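"""Generator determinism, type coverage and generator/validator closure."""

import pytest

from gtrack.io import parse_document, write_document
from gtrack.issues import Severity
from gtrack.synth import FixtureParams, GenomeSpec, generate, generate_all_types
from gtrack.track_model import TrackType, is_dense
from gtrack.validate import validate


def test_same_seed_gives_byte_identical_files():
    genome = GenomeSpec(seed=7)
    params = FixtureParams(track_type=TrackType.S, n_elements=50)
    assert write_document(generate(params, genome)) == write_document(
        generate(params, genome)
    )


def test_all_types_distinct_and_dense_count(genome):
    docs = generate_all_types(genome)
    inferred = {
        parse_document(write_document(doc)).track_type for doc in docs.values()
    }
    assert len(inferred) == 15
    assert sum(is_dense(t) for t in inferred) == 7


def test_partition_lengths_sum_to_genome(genome):
    doc = generate(FixtureParams(track_type=TrackType.GP), genome)
    by_seqid: dict = {}
    for el in doc.elements():
        by_seqid[el.seqid] = by_seqid.get(el.seqid, 0) + el.length
    assert by_seqid == dict(genome.seqids)


def test_undirected_weighted_edges_are_reciprocal(genome):
    doc = generate(
        FixtureParams(
            track_type=TrackType.LVS,
            edge_density=0.5,
            undirected=True,
            edge_weights=True,
        ),
        genome,
    )
    issues = validate(write_document(doc))
    assert not [i for i in issues if i.severity is Severity.ERROR]
    assert any(e.edges for e in doc.elements())


@pytest.mark.parametrize("seed", range(7))
@pytest.mark.parametrize("dialect", [(False, False), (True, True)])
def test_generator_validator_closure(seed, dialect):
    """Seed-varied fixtures of every type, in both coordinate dialects,
    validate without errors (210 documents in total)."""
    genome = GenomeSpec(seed=seed)
    one_indexed, end_inclusive = dialect
    for t, doc in generate_all_types(genome).items():
        text = write_document(
            doc, one_indexed=one_indexed, end_inclusive=end_inclusive
        )
        errors = [i for i in validate(text) if i.severity is Severity.ERROR]
        assert errors == [], (t, seed, dialect, errors[:3])


def test_infeasible_parameters_rejected():
    tiny = GenomeSpec(seqids=(("chr1", 10),), seed=0)
    with pytest.raises(ValueError):
        generate(FixtureParams(track_type=TrackType.S, n_elements=50), tiny)
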