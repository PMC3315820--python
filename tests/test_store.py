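"""Columnar store: round trips, indexed queries vs brute force, layout
sizes and staleness."""

import os

import numpy as np
import pytest

from gtrack.io import write_gtrack
from gtrack.store import build_store, query_region, store_is_stale
from gtrack.synth import FixtureParams, GenomeSpec, generate
from gtrack.tools import sort_gtrack
from gtrack.track_model import TrackType

QUERY_TYPES = ("P", "S", "VP", "VS", "SF", "F")


@pytest.fixture(scope="module")
def big_genome():
    return GenomeSpec(seqids=(("chr1", 2000), ("chr2", 1500)), seed=11)


def _brute_force(doc, seqid, start, end):
    if end <= start:
        return []
    return [
        el
        for el in doc.elements()
        if el.seqid == seqid and el.span[1] > start and el.span[0] < end
    ]


class TestRoundTrip:
    @pytest.mark.parametrize("type_name", QUERY_TYPES + ("LS", "LVS", "GP"))
    def test_full_scan_reproduces_elements(self, big_genome, tmp_path, type_name):
        doc = generate(
            FixtureParams(
                track_type=TrackType[type_name], n_elements=40, edge_density=0.4
            ),
            big_genome,
        )
        store = build_store(doc, tmp_path / type_name)
        assert store.all_elements() == sorted(
            doc.elements(), key=lambda e: (e.seqid, e.span)
        )

    def test_empty_document(self, tmp_path):
        from gtrack.document import GTrackDocument

        store = build_store(GTrackDocument(), tmp_path / "empty")
        assert store.element_count() == 0

    def test_unsorted_input_rejected(self, big_genome, tmp_path):
        import dataclasses

        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        region, els = doc.groups[0]
        doc = dataclasses.replace(doc, groups=[(region, list(reversed(els)))])
        with pytest.raises(ValueError, match="sorted"):
            build_store(doc, tmp_path / "unsorted")

    def test_list_values_unsupported(self, big_genome, tmp_path):
        doc = generate(
            FixtureParams(track_type=TrackType.VS, value_dimension="list"),
            big_genome,
        )
        with pytest.raises(ValueError):
            build_store(doc, tmp_path / "list")


class TestQueries:
    @pytest.mark.parametrize("type_name", QUERY_TYPES)
    def test_indexed_query_equals_brute_force(
        self, big_genome, tmp_path, type_name
    ):
        doc = generate(
            FixtureParams(track_type=TrackType[type_name], n_elements=40),
            big_genome,
        )
        store = build_store(doc, tmp_path / type_name, bin_size=128)
        rng = np.random.default_rng(20_000 + len(type_name))
        for _ in range(200):
            seqid = ("chr1", "chr2")[int(rng.integers(0, 2))]
            a = int(rng.integers(0, 2100))
            b = a + int(rng.integers(0, 400))
            assert query_region(store, seqid, a, b) == _brute_force(
                doc, seqid, a, b
            ), (type_name, seqid, a, b)

    def test_empty_interval_returns_nothing(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        store = build_store(doc, tmp_path / "s")
        assert query_region(store, "chr1", 50, 50) == []

    def test_whole_genome_query_returns_everything(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.VS), big_genome)
        store = build_store(doc, tmp_path / "vs")
        got = query_region(store, "chr1", 0, 10_000)
        assert got == [el for el in doc.elements() if el.seqid == "chr1"]

    def test_unknown_seqid_rejected(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        store = build_store(doc, tmp_path / "s2")
        with pytest.raises(KeyError):
            query_region(store, "chrX", 0, 10)

    def test_index_is_monotone(self, big_genome, tmp_path):
        doc = generate(
            FixtureParams(track_type=TrackType.S, n_elements=60), big_genome
        )
        store = build_store(doc, tmp_path / "mono", bin_size=64)
        for seqid, idx in store.index.items():
            assert np.all(np.diff(idx) >= 0), seqid


class TestLayout:
    def test_sparse_vector_sizes_linear_in_n(self, big_genome, tmp_path):
        doc = generate(
            FixtureParams(track_type=TrackType.VS, n_elements=40), big_genome
        )
        store = build_store(doc, tmp_path / "sizes")
        for seqid in store.seqids:
            n = store.element_count(seqid)
            assert os.path.getsize(tmp_path / "sizes" / f"{seqid}.start.bin") == 8 * n
            assert os.path.getsize(tmp_path / "sizes" / f"{seqid}.end.bin") == 8 * n
            assert os.path.getsize(tmp_path / "sizes" / f"{seqid}.value.bin") == 8 * n

    def test_function_stores_value_vector_only(self, tmp_path):
        genome = GenomeSpec(seqids=(("chr1", 500),), seed=2)
        doc = generate(FixtureParams(track_type=TrackType.F), genome)
        store = build_store(doc, tmp_path / "f")
        assert os.path.getsize(tmp_path / "f" / "chr1.value.bin") == 8 * 500
        assert not os.path.exists(tmp_path / "f" / "chr1.start.bin")
        assert not os.path.exists(tmp_path / "f" / "chr1.end.bin")

    def test_metadata_written(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        build_store(doc, tmp_path / "meta")
        text = (tmp_path / "meta" / "metadata.txt").read_text()
        assert "track type: segments" in text


class TestStaleness:
    def test_hash_tracking(self, big_genome, tmp_path):
        doc = sort_gtrack(generate(FixtureParams(track_type=TrackType.S), big_genome))
        src = tmp_path / "src.gtrack"
        write_gtrack(doc, src)
        store = build_store(doc, tmp_path / "store", source_path=src)
        assert not store_is_stale(store, src)
        with open(src, "a") as fh:
            fh.write("# touched\n")
        assert store_is_stale(store, src)

    def test_missing_source_is_stale(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        src = tmp_path / "src.gtrack"
        write_gtrack(doc, src)
        store = build_store(doc, tmp_path / "store", source_path=src)
        os.unlink(src)
        assert store_is_stale(store, src)

    def test_unhashed_store_is_conservatively_stale(self, big_genome, tmp_path):
        doc = generate(FixtureParams(track_type=TrackType.S), big_genome)
        store = build_store(doc, tmp_path / "store")
        assert store_is_stale(store, tmp_path / "whatever")
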