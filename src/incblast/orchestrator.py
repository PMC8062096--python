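"""Incremental search orchestration.

The incremental flow: look up a prior result for (query set, database,
program, parameters) in a lightweight record store; diff the database's
volume list against the snapshot recorded at search time; search only the
newly added volumes (the delta database, expressed as a standard BLAST
alias file); recalibrate both the stored and the delta results against the
present database and merge them; write the record back.  For a database
that grew by a fraction δ this costs δ/(1+δ) of a full search — the source
of the (1+δ)/δ projected speedup.

The actual alignment search is behind a pluggable executor: any callable
``executor(queries, db_profile, program, params) -> XML text`` satisfies the
contract, whether it shells out to the NCBI BLAST+ binaries or is a
deterministic mock.  The record store keeps metadata and a result-file
reference only — never sequence data — and holds one record per key, so its
size is independent of database growth.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from random import Random
from typing import Callable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO

from . import io as result_io
from .merge import MergePlan, merge
from .model import SearchParams, SearchResult
from .stats import DatabaseProfile, DomainError

__all__ = [
    "ShrinkageError",
    "RecordStoreError",
    "SearchRecord",
    "RecordStore",
    "DeltaSpec",
    "compute_delta",
    "write_alias",
    "incremental_search",
    "partition_queries",
    "read_queries",
    "query_set_digest",
    "params_digest",
    "snapshot_digest",
    "load_db_profile",
    "save_db_profile",
]

Query = Tuple[str, str]  # (query_id, sequence)
Executor = Callable[[Sequence[Query], DatabaseProfile, str, SearchParams], str]


class ShrinkageError(DomainError):
    """The present database lost volumes or residues relative to the past
    snapshot; the delta is undefined and a full re-search is required."""


class RecordStoreError(RuntimeError):
    """The record store is unreadable or internally inconsistent."""


# ---------------------------------------------------------------------------
# Digests and database metadata sidecars
# ---------------------------------------------------------------------------


def query_set_digest(queries: Sequence[Query]) -> str:
    """Order-insensitive content digest of a query set.

    A reformatted but sequence-identical FASTA maps to the same digest, so
    stored results are found again regardless of record order or wrapping.
    """
    per_seq = sorted(
        hashlib.sha256(f"{qid}\n{seq.upper()}".encode()).hexdigest()
        for qid, seq in queries
    )
    return hashlib.sha256("\n".join(per_seq).encode()).hexdigest()


def params_digest(params: SearchParams) -> str:
    canon = json.dumps(
        {
            "max_target_seqs": params.max_target_seqs,
            "expect": params.expect,
            "matrix": params.matrix,
            "match": params.match,
            "mismatch": params.mismatch,
            "gap_open": params.gap_open,
            "gap_extend": params.gap_extend,
        },
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def snapshot_digest(db: DatabaseProfile) -> str:
    """Content identity of one database snapshot (volume list + sizes)."""
    canon = json.dumps([sorted(db.files), db.n, db.N], sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def read_queries(fasta_path) -> List[Query]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]


def save_db_profile(db: DatabaseProfile, path) -> None:
    """Write a database metadata sidecar (JSON) for when live BLAST database
    introspection is unavailable."""
    Path(path).write_text(
        json.dumps(
            {
                "db_id": db.db_id,
                "n": db.n,
                "N": db.N,
                "files": list(db.files),
                "molecule": db.molecule,
                "timestamp": db.timestamp,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )


def load_db_profile(path) -> DatabaseProfile:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return DatabaseProfile(
        db_id=data["db_id"],
        n=int(data["n"]),
        N=int(data["N"]),
        files=tuple(data.get("files", ())),
        molecule=data.get("molecule", "nucleotide"),
        timestamp=data.get("timestamp", ""),
    )


# ---------------------------------------------------------------------------
# Record store
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchRecord:
    """Metadata linking one (query set, database, program, params) key to its
    most recent stored result.  No sequence data is ever stored."""

    query_digest: str
    db_id: str
    program: str
    params_digest: str
    db_snapshot: DatabaseProfile
    result_path: str
    created_at: str = ""

    @property
    def record_id(self) -> str:
        return hashlib.sha256(
            "|".join(
                (self.query_digest, self.db_id, self.program, self.params_digest)
            ).encode()
        ).hexdigest()[:16]


_SCHEMA = """
CREATE TABLE IF NOT EXISTS search_records (
    query_digest TEXT NOT NULL,
    db_id        TEXT NOT NULL,
    program      TEXT NOT NULL,
    params_digest TEXT NOT NULL,
    db_snapshot  TEXT NOT NULL,
    result_path  TEXT NOT NULL,
    created_at   TEXT NOT NULL,
    PRIMARY KEY (query_digest, db_id, program, params_digest)
)
"""


class RecordStore:
    """Embedded single-file store of :class:`SearchRecord` rows.

    The primary key enforces the most-recent-only policy: storing a record
    for an existing key replaces the old row, so the store holds O(1) rows
    per (query set, database, program, params) regardless of how often the
    database grows.
    """

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        try:
            self._conn = sqlite3.connect(self.path)
            self._conn.execute(_SCHEMA)
            self._conn.commit()
        except sqlite3.DatabaseError as exc:
            raise RecordStoreError(f"cannot open record store {path}: {exc}") from exc

    def close(self) -> None:
        self._conn.close()

    def store(self, record: SearchRecord) -> None:
        snapshot = {
            "db_id": record.db_snapshot.db_id,
            "n": record.db_snapshot.n,
            "N": record.db_snapshot.N,
            "files": list(record.db_snapshot.files),
            "molecule": record.db_snapshot.molecule,
            "timestamp": record.db_snapshot.timestamp,
        }
        with self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO search_records VALUES (?,?,?,?,?,?,?)",
                (
                    record.query_digest,
                    record.db_id,
                    record.program,
                    record.params_digest,
                    json.dumps(snapshot, sort_keys=True),
                    record.result_path,
                    record.created_at
                    or datetime.now(timezone.utc).isoformat(timespec="seconds"),
                ),
            )

    def lookup(
        self, query_digest: str, db_id: str, program: str, params_digest: str
    ) -> Optional[SearchRecord]:
        try:
            rows = self._conn.execute(
                "SELECT db_snapshot, result_path, created_at FROM search_records "
                "WHERE query_digest=? AND db_id=? AND program=? AND params_digest=?",
                (query_digest, db_id, program, params_digest),
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise RecordStoreError(f"record store corrupt: {exc}") from exc
        if not rows:
            return None
        if len(rows) > 1:  # impossible under the schema's primary key
            raise RecordStoreError("duplicate records for one key")
        snapshot_json, result_path, created_at = rows[0]
        data = json.loads(snapshot_json)
        snapshot = DatabaseProfile(
            db_id=data["db_id"],
            n=data["n"],
            N=data["N"],
            files=tuple(data["files"]),
            molecule=data["molecule"],
            timestamp=data.get("timestamp", ""),
        )
        return SearchRecord(
            query_digest=query_digest,
            db_id=db_id,
            program=program,
            params_digest=params_digest,
            db_snapshot=snapshot,
            result_path=result_path,
            created_at=created_at,
        )

    def records(self) -> List[SearchRecord]:
        rows = self._conn.execute(
            "SELECT query_digest, db_id, program, params_digest FROM search_records "
            "ORDER BY created_at, db_id"
        ).fetchall()
        return [self.lookup(*row) for row in rows]


# ---------------------------------------------------------------------------
# Delta database construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeltaSpec:
    """The difference between two snapshots of the same database."""

    past: DatabaseProfile
    present: DatabaseProfile
    delta_files: tuple
    delta_n: int
    delta_N: int

    @property
    def empty(self) -> bool:
        return not self.delta_files and self.delta_n == 0

    def profile(self) -> DatabaseProfile:
        """A :class:`DatabaseProfile` for the delta database alone."""
        return DatabaseProfile(
            db_id=f"{self.present.db_id}.delta",
            n=self.delta_n,
            N=self.delta_N,
            files=self.delta_files,
            molecule=self.present.molecule,
            timestamp=self.present.timestamp,
        )


def compute_delta(past: DatabaseProfile, present: DatabaseProfile) -> DeltaSpec:
    """Volume-list difference between two snapshots, with size deltas.

    Delta detection is by filename-list difference; ordering follows the
    present snapshot.  Any volume or residue loss raises
    :class:`ShrinkageError` — the correction mathematics assumes growth, so
    a shrunken database forces a full re-search.
    """
    present_set = set(present.files)
    missing = [f for f in past.files if f not in present_set]
    if missing:
        raise ShrinkageError(
            f"present snapshot lost volumes {missing}; run a full search"
        )
    past_set = set(past.files)
    delta_files = tuple(f for f in present.files if f not in past_set)
    delta_n = present.n - past.n
    delta_N = present.N - past.N
    if delta_n < 0 or delta_N < 0:
        raise ShrinkageError(
            f"present snapshot smaller than past (delta_n={delta_n}, "
            f"delta_N={delta_N}); run a full search"
        )
    return DeltaSpec(
        past=past,
        present=present,
        delta_files=delta_files,
        delta_n=delta_n,
        delta_N=delta_N,
    )


def write_alias(
    delta: DeltaSpec, title: str, directory: Union[str, Path]
) -> Optional[Path]:
    """Emit a standard BLAST alias file for the delta volumes.

    ``.nal`` for nucleotide databases, ``.pal`` for protein; the DBLIST line
    enumerates the delta volume basenames in present-snapshot order.  Output
    is byte-stable for identical input.  Returns ``None`` (writing nothing)
    when the delta is empty: the database is up to date and the prior result
    can be reused unchanged.
    """
    if delta.empty:
        return None
    ext = ".nal" if delta.present.molecule == "nucleotide" else ".pal"
    basenames = " ".join(Path(f).name.split(".")[0] for f in delta.delta_files)
    content = f"TITLE {title}\nDBLIST {basenames}\n"
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{title}{ext}"
    path.write_text(content, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Incremental search
# ---------------------------------------------------------------------------


def _run_and_store(
    queries: Sequence[Query],
    db: DatabaseProfile,
    program: str,
    params: SearchParams,
    executor: Executor,
    store: RecordStore,
    results_dir: Path,
    qdigest: str,
    pdigest: str,
) -> List[SearchResult]:
    document = executor(queries, db, program, params)
    results = result_io.parse_result(_as_stream(document), dialect="xml")
    record = SearchRecord(
        query_digest=qdigest,
        db_id=db.db_id,
        program=program,
        params_digest=pdigest,
        db_snapshot=db,
        result_path="",
    )
    out_path = results_dir / f"{record.record_id}.xml"
    result_io.write_result(results, dialect="xml", path=out_path)
    store.store(
        SearchRecord(
            query_digest=qdigest,
            db_id=db.db_id,
            program=program,
            params_digest=pdigest,
            db_snapshot=db,
            result_path=str(out_path),
        )
    )
    return results


def _as_stream(document: str):
    import io as _io

    return _io.StringIO(document)


def incremental_search(
    queries: Sequence[Query],
    present_db: DatabaseProfile,
    program: str,
    params: SearchParams,
    executor: Executor,
    store: RecordStore,
    results_dir: Union[str, Path],
) -> List[SearchResult]:
    """Answer a search, reusing any stored result for the unchanged part.

    Three paths:

    * no stored record — full search through the executor; record created;
    * record found, database unchanged — stored result returned, executor
      not invoked;
    * record found, database grew — executor invoked on the delta volumes
      only, then both results are recalibrated against the present database
      and merged; the record is updated to the present snapshot.

    A shrunken database triggers a warning and a full re-search.
    """
    results_dir = Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    qdigest = query_set_digest(queries)
    pdigest = params_digest(params)
    record = store.lookup(qdigest, present_db.db_id, program, pdigest)

    if record is None:
        return _run_and_store(
            queries, present_db, program, params, executor, store,
            results_dir, qdigest, pdigest,
        )

    try:
        delta = compute_delta(record.db_snapshot, present_db)
    except ShrinkageError as exc:
        warnings.warn(f"{exc}; repeating the full search", stacklevel=2)
        return _run_and_store(
            queries, present_db, program, params, executor, store,
            results_dir, qdigest, pdigest,
        )

    if delta.empty:
        return result_io.parse_result(record.result_path, dialect="xml")

    past_results = result_io.parse_result(record.result_path, dialect="xml")
    delta_doc = executor(queries, delta.profile(), program, params)
    delta_results = result_io.parse_result(_as_stream(delta_doc), dialect="xml")

    past_by_query = {r.query.query_id: r for r in past_results}
    delta_by_query = {r.query.query_id: r for r in delta_results}
    if set(past_by_query) != set(delta_by_query):
        raise DomainError(
            "stored and delta results answer different query sets; "
            "the record does not match this search"
        )

    merged: List[SearchResult] = []
    for qid in (r.query.query_id for r in past_results):
        plan = MergePlan.build(
            [
                (past_by_query[qid], record.db_snapshot),
                (delta_by_query[qid], delta.profile()),
            ],
            union_db=present_db,
            max_target_seqs=params.max_target_seqs,
        )
        merged.append(merge(plan))

    out_path = results_dir / f"{record.record_id}.xml"
    result_io.write_result(merged, dialect="xml", path=out_path)
    store.store(
        SearchRecord(
            query_digest=qdigest,
            db_id=present_db.db_id,
            program=program,
            params_digest=pdigest,
            db_snapshot=present_db,
            result_path=str(out_path),
        )
    )
    return merged


# ---------------------------------------------------------------------------
# Residue-balanced query partitioning
# ---------------------------------------------------------------------------


def partition_queries(
    queries: Sequence[Query], k: int, seed: int = 0
) -> List[List[Query]]:
    """Split queries into ``k`` partitions of roughly equal residue totals.

    Query order is randomized by ``seed``, then each query is assigned
    greedily to the currently lightest partition (ties broken by partition
    index), which balances residue workload far better than count-balanced
    splitting when query lengths are heavy-tailed.  Partitions may be empty
    when ``k`` exceeds the number of queries.  Deterministic given ``seed``.
    """
    if k < 1:
        raise DomainError(f"number of partitions must be >= 1, got {k}")
    order = list(queries)
    Random(seed).shuffle(order)
    loads = [0] * k
    parts: List[List[Query]] = [[] for _ in range(k)]
    for query in order:
        idx = min(range(k), key=lambda i: (loads[i], i))
        parts[idx].append(query)
        loads[idx] += len(query[1])
    return parts
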