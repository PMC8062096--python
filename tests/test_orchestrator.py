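"""Record store, delta construction, incremental flow, query partitioning."""

from random import Random

import pytest

from incblast import parse_result
from incblast.fixtures import MockExecutor, ScenarioSpec, generate_scenario
from incblast.model import SearchParams, results_equal
from incblast.orchestrator import (
    DeltaSpec,
    RecordStore,
    SearchRecord,
    ShrinkageError,
    compute_delta,
    incremental_search,
    load_db_profile,
    params_digest,
    partition_queries,
    query_set_digest,
    read_queries,
    save_db_profile,
    write_alias,
)
from incblast.stats import DatabaseProfile


def _record(db_id="nt", result_path="r.xml", n=100, files=("v0",)):
    return SearchRecord(
        query_digest="q" * 8,
        db_id=db_id,
        program="blastn",
        params_digest="p" * 8,
        db_snapshot=DatabaseProfile(db_id, n, 10, files=files),
        result_path=result_path,
    )


class TestRecordStore:
    def test_empty_store_lookup_returns_none(self):
        store = RecordStore(":memory:")
        assert store.lookup("x", "nt", "blastn", "y") is None

    def test_store_then_lookup_round_trips(self, tmp_path):
        store = RecordStore(tmp_path / "rec.sqlite")
        rec = _record()
        store.store(rec)
        found = store.lookup(rec.query_digest, rec.db_id, rec.program, rec.params_digest)
        assert found is not None
        assert found.db_snapshot == rec.db_snapshot
        assert found.result_path == rec.result_path

    def test_only_most_recent_record_survives_per_key(self, tmp_path):
        store = RecordStore(tmp_path / "rec.sqlite")
        rec1 = _record(result_path="old.xml", n=100)
        rec2 = _record(result_path="new.xml", n=250, files=("v0", "v1"))
        store.store(rec1)
        store.store(rec2)
        found = store.lookup(rec1.query_digest, "nt", "blastn", rec1.params_digest)
        assert found.result_path == "new.xml"
        assert found.db_snapshot.n == 250
        assert len(store.records()) == 1


class TestDigests:
    def test_query_digest_ignores_record_order_and_case(self):
        a = [("q1", "acgtACGT"), ("q2", "TTTT")]
        b = [("q2", "tttt"), ("q1", "ACGTACGT")]
        assert query_set_digest(a) == query_set_digest(b)
        assert query_set_digest(a) != query_set_digest([("q1", "ACGT")])

    def test_changed_parameters_are_a_different_record_key(self):
        assert params_digest(SearchParams(max_target_seqs=100)) != params_digest(
            SearchParams(max_target_seqs=500)
        )

    def test_profile_sidecar_round_trips(self, tmp_path):
        db = DatabaseProfile("nt", 1000, 10, files=("a", "b"), molecule="nucleotide",
                             timestamp="t1")
        save_db_profile(db, tmp_path / "db.json")
        assert load_db_profile(tmp_path / "db.json") == db


class TestComputeDelta:
    @pytest.mark.parametrize(
        "past_n,present_n,expected",
        [
            (80_740_533_243, 113_749_495_340, 33_008_962_097),
            (113_749_495_340, 152_471_828_601, 38_722_333_261),
        ],
    )
    def test_delta_lengths_by_subtraction(self, past_n, present_n, expected):
        past = DatabaseProfile("nt", past_n, 100, files=("v0",))
        present = DatabaseProfile("nt", present_n, 150, files=("v0", "v1"))
        delta = compute_delta(past, present)
        assert delta.delta_n == expected
        assert delta.delta_n + past.n == present.n

    def test_identical_snapshots_give_empty_delta(self):
        db = DatabaseProfile("nt", 100, 10, files=("v0",))
        delta = compute_delta(db, db)
        assert delta.empty and delta.delta_files == () and delta.delta_n == 0

    def test_lost_volume_raises_shrinkage(self):
        past = DatabaseProfile("nt", 100, 10, files=("v0", "v1"))
        present = DatabaseProfile("nt", 120, 12, files=("v1", "v2"))
        with pytest.raises(ShrinkageError, match="full search"):
            compute_delta(past, present)

    def test_delta_file_order_follows_present_snapshot(self):
        past = DatabaseProfile("nt", 100, 10, files=("v0",))
        present = DatabaseProfile("nt", 300, 30, files=("v0", "v2", "v1"))
        assert compute_delta(past, present).delta_files == ("v2", "v1")


class TestWriteAlias:
    def _delta(self, molecule="nucleotide"):
        past = DatabaseProfile("nt", 100, 10, files=("v0",), molecule=molecule)
        present = DatabaseProfile(
            "nt", 300, 30, files=("v0", "nt.01.fasta", "nt.02.fasta"),
            molecule=molecule,
        )
        return compute_delta(past, present)

    def test_nucleotide_alias_lists_delta_volume_basenames(self, tmp_path):
        path = write_alias(self._delta(), "nt_delta", tmp_path)
        assert path.suffix == ".nal"
        content = path.read_text()
        assert "DBLIST nt nt" in content  # basenames without volume extensions
        assert content.startswith("TITLE nt_delta\n")

    def test_protein_molecule_selects_pal_extension(self, tmp_path):
        path = write_alias(self._delta("protein"), "nr_delta", tmp_path)
        assert path.suffix == ".pal"

    def test_output_is_byte_stable(self, tmp_path):
        p1 = write_alias(self._delta(), "d", tmp_path / "a")
        p2 = write_alias(self._delta(), "d", tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_delta_writes_nothing(self, tmp_path):
        db = DatabaseProfile("nt", 100, 10, files=("v0",))
        assert write_alias(compute_delta(db, db), "d", tmp_path) is None
        assert list(tmp_path.iterdir()) == []


class TestIncrementalSearch:
    def _setup(self, tmp_path, seed=40, n_steps=2, **kw):
        bundle = generate_scenario(
            ScenarioSpec(seed=seed, mode="temporal", n_steps=n_steps, **kw),
            tmp_path / "scen",
        )
        params = parse_result(bundle.part_paths[0])[0].params
        executor = MockExecutor(bundle.universe, seed,
                                hit_rate=bundle.spec.hit_rate)
        store = RecordStore(":memory:")
        return bundle, params, executor, store

    def test_cold_path_runs_full_search_and_creates_record(self, tmp_path):
        bundle, params, executor, store = self._setup(tmp_path)
        results = incremental_search(
            bundle.queries, bundle.snapshots[0], "blastn", params, executor,
            store, tmp_path / "res",
        )
        assert len(executor.calls) == 1
        assert executor.calls[0].files == bundle.snapshots[0].files
        assert len(store.records()) == 1
        assert len(results) == len(bundle.queries)

    def test_unchanged_database_is_a_pure_cache_hit(self, tmp_path):
        bundle, params, executor, store = self._setup(tmp_path)
        first = incremental_search(
            bundle.queries, bundle.snapshots[0], "blastn", params, executor,
            store, tmp_path / "res",
        )
        second = incremental_search(
            bundle.queries, bundle.snapshots[0], "blastn", params, executor,
            store, tmp_path / "res",
        )
        assert len(executor.calls) == 1  # executor untouched the second time
        assert all(results_equal(a, b) for a, b in zip(first, second))

    def test_grown_database_searches_only_the_delta_and_matches_whole_run(
        self, tmp_path
    ):
        bundle, params, executor, store = self._setup(tmp_path, n_steps=3)
        for snap in bundle.snapshots:
            results = incremental_search(
                bundle.queries, snap, "blastn", params, executor,
                store, tmp_path / "res",
            )
        # one full call plus one delta-only call per later snapshot
        assert [c.files for c in executor.calls] == [
            bundle.snapshots[0].files, ("vol01",), ("vol02",)
        ]
        reference = {r.query.query_id: r
                     for r in parse_result(bundle.reference_path)}
        for result in results:
            assert results_equal(
                result, reference[result.query.query_id], compare_stats=False
            )
        # record snapshot advanced to the present database
        rec = store.records()[0]
        assert rec.db_snapshot.n == bundle.snapshots[-1].n

    def test_shrunken_database_warns_and_repeats_full_search(self, tmp_path):
        bundle, params, executor, store = self._setup(tmp_path)
        incremental_search(
            bundle.queries, bundle.snapshots[1], "blastn", params, executor,
            store, tmp_path / "res",
        )
        with pytest.warns(UserWarning, match="full search"):
            results = incremental_search(
                bundle.queries, bundle.snapshots[0], "blastn", params, executor,
                store, tmp_path / "res",
            )
        assert executor.calls[-1].files == bundle.snapshots[0].files
        assert len(results) == len(bundle.queries)

    def test_fasta_queries_drive_the_same_flow(self, tmp_path):
        bundle, params, executor, store = self._setup(tmp_path)
        queries = read_queries(bundle.queries_fasta)
        assert query_set_digest(queries) == query_set_digest(bundle.queries)


class TestPartitionQueries:
    def test_single_partition_holds_everything(self):
        queries = [("a", "ACGT"), ("b", "AC")]
        parts = partition_queries(queries, 1, seed=0)
        assert len(parts) == 1 and sorted(parts[0]) == sorted(queries)

    def test_equal_length_queries_spread_one_each(self):
        queries = [(f"q{i}", "A" * 50) for i in range(20)]
        parts = partition_queries(queries, 20, seed=1)
        assert sorted(len(p) for p in parts) == [1] * 20

    def test_more_partitions_than_queries_leaves_empties(self):
        parts = partition_queries([("a", "ACGT")], 5, seed=0)
        assert sum(len(p) for p in parts) == 1

    def test_deterministic_given_seed(self):
        queries = [(f"q{i}", "A" * (10 + 7 * i)) for i in range(30)]
        assert partition_queries(queries, 4, seed=9) == partition_queries(
            queries, 4, seed=9
        )

    def test_residue_balance_beats_count_balance_on_heavy_tails(self):
        rng = Random(13)
        # heavy-tailed lengths: a few huge transcripts among many short ones
        queries = [
            (f"q{i}", "A" * (int(rng.paretovariate(0.8) * 100) + 50))
            for i in range(200)
        ]
        k = 20
        parts = partition_queries(queries, k, seed=2)
        loads = [sum(len(s) for _, s in p) for p in parts]

        order = list(queries)
        Random(2).shuffle(order)
        count_balanced = [order[i::k] for i in range(k)]
        naive_loads = [sum(len(s) for _, s in p) for p in count_balanced]

        ratio = max(loads) / max(min(loads), 1)
        naive_ratio = max(naive_loads) / max(min(naive_loads), 1)
        assert ratio < naive_ratio
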