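import pytest

from gtrack.synth import FixtureParams, GenomeSpec, generate, generate_all_types
from gtrack.track_model import TrackType


@pytest.fixture(scope="session")
def genome() -> GenomeSpec:
    return GenomeSpec(seqids=(("chr1", 300), ("chr2", 200)), seed=7)


@pytest.fixture(scope="session")
def all_docs(genome):
    """One valid document per track type, shared across the suite."""
    return generate_all_types(genome)


@pytest.fixture(scope="session")
def make_doc(genome):
    def _make(track_type, **kwargs):
        if isinstance(track_type, str):
            track_type = TrackType[track_type]
        return generate(FixtureParams(track_type=track_type, **kwargs), genome)

    return _make
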