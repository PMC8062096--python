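"""Synthetic search scenarios and independent reference oracles.

Everything in this package is testable offline: this module fabricates
database timelines (temporal growth) and disjoint taxon partitions
(spatial splits), queries, and internally consistent BLAST-format result
files, plus brute-force reference implementations of the significance
formulas.

The central design constraint is that the synthetic score model is
*partition-invariant*: the raw score of a (query, subject) pair is a pure
function of a seed and the two identifiers, never of which database volume
or snapshot the subject sits in.  A real aligner has this property too —
an alignment's score does not depend on what else is in the database —
and it is exactly what makes split-vs-whole comparisons meaningful: a
merged set of per-part results can be checked hit-for-hit against a single
simulated whole-database search.

The mock executor reports every score-model hit regardless of its e-value
(no expect-threshold filtering), so part searches and whole-database
searches see identical hit sets and the fidelity of the correction
mathematics can be measured in isolation.  Alignment strings are
schematic: the correction method touches only scores, sizes and e-values.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from random import Random
from typing import Dict, List, Optional, Sequence, Tuple

from . import io as result_io
from .model import (
    Hit,
    Hsp,
    SearchParams,
    SearchResult,
    StatisticsBlock,
    sort_hits,
)
from .orchestrator import Query, compute_delta, save_db_profile
from .stats import (
    DatabaseProfile,
    DomainError,
    EValue,
    KarlinParams,
    QueryProfile,
    ZERO_ROUND_LOG_THRESHOLD,
)

__all__ = [
    "BLASTN_PARAMS",
    "BLASTP_PARAMS",
    "oracle_length_adjustment",
    "oracle_evalue",
    "oracle_rescale",
    "MockExecutor",
    "ScenarioSpec",
    "ScenarioBundle",
    "generate_scenario",
]

# Scoring systems used by the generators: blastn with match/mismatch 2/-3 and
# gap costs 5/2 (Karlin-Altschul family), blastp with BLOSUM62 11/1 (Spouge
# family).  Values as in the bundled parameter table.
BLASTN_PARAMS = KarlinParams(lambda_=0.625, K=0.41, H=0.78, alpha=0.8, beta=-2)
BLASTP_PARAMS = KarlinParams(lambda_=0.267, K=0.041, H=0.14, alpha=1.9, beta=-30)

_SEARCH_PARAMS = {
    "blastn": SearchParams(match=2, mismatch=-3, gap_open=5, gap_extend=2),
    "blastp": SearchParams(matrix="BLOSUM62", gap_open=11, gap_extend=1),
}


# ---------------------------------------------------------------------------
# Brute-force oracles (test-time ground truth; no iterative solving)
# ---------------------------------------------------------------------------


def oracle_length_adjustment(params: KarlinParams, m: int, n: int, N: int) -> int:
    """Exhaustive integer scan for the saturating length adjustment.

    Checks every integer l with positive effective lengths and returns the
    largest one satisfying l <= (alpha/lambda)·ln(K(m−l)(n−Nl)) + beta.
    """
    if m <= 0 or n <= 0 or N <= 0:
        raise DomainError(f"degenerate input (m={m}, n={n}, N={N})")
    l_max = min(m - 1, (n - 1) // N)
    if l_max < 0:
        raise DomainError("no integer l keeps effective lengths positive")
    best = 0
    for l in range(0, l_max + 1):
        rhs = (params.alpha / params.lambda_) * math.log(
            params.K * (m - l) * (n - N * l)
        ) + params.beta
        if l <= rhs:
            best = l
    return best


def oracle_evalue(
    params: KarlinParams, m: int, db: DatabaseProfile, score: float
) -> EValue:
    """Direct evaluation of E = K·(m−l)·(n−Nl)·e^(−λS) with the scanned l."""
    l = oracle_length_adjustment(params, m, db.n, db.N)
    log_e = math.fsum(
        (
            math.log(params.K),
            math.log(m - l),
            math.log(db.n - db.N * l),
            -params.lambda_ * score,
        )
    )
    return EValue(log_e=log_e)


def oracle_rescale(ev: EValue, n_part: int, n_total: int) -> EValue:
    """Direct log-space database-length rescaling (Spouge-family oracle)."""
    return EValue(log_e=ev.log_e + (math.log(n_total) - math.log(n_part)))


# ---------------------------------------------------------------------------
# Deterministic mock search executor
# ---------------------------------------------------------------------------


def _hash_u32(*parts: str) -> int:
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:4], "big")


class MockExecutor:
    """A deterministic stand-in for the BLAST search binaries.

    ``universe`` maps each database volume filename to its subject catalog
    ``[(subject_id, subject_len), ...]``; a search over a
    :class:`DatabaseProfile` sees exactly the subjects of the profile's
    volumes.  Whether a (query, subject) pair hits, and with what raw score,
    is derived from a seeded hash of the two identifiers alone, so scores
    are identical however the database is partitioned.  E-values and
    statistics blocks are produced with the brute-force oracle formulas of
    this module, independent of the package's solver/correction code paths.

    ``zero_round`` emulates standard BLAST text output, in which e-values
    below e^-180 collapse to a literal 0.0.
    """

    def __init__(
        self,
        universe: Dict[str, List[Tuple[str, int]]],
        seed: int,
        *,
        hit_rate: float = 0.6,
        deep_rate: float = 0.0,
        zero_round: bool = False,
        max_hsps: int = 2,
    ):
        self.universe = universe
        self.seed = seed
        self.hit_rate = hit_rate
        self.deep_rate = deep_rate
        self.zero_round = zero_round
        self.max_hsps = max_hsps
        self.calls: List[DatabaseProfile] = []  # call log, inspected by tests

    # -- score model -------------------------------------------------------

    def pair_hits(self, query_id: str, subject_id: str) -> bool:
        u = _hash_u32(str(self.seed), "hit", query_id, subject_id)
        return (u % 10_000) < int(self.hit_rate * 10_000)

    def pair_score(self, query_id: str, subject_id: str) -> int:
        u = _hash_u32(str(self.seed), "score", query_id, subject_id)
        if self.deep_rate > 0:
            d = _hash_u32(str(self.seed), "deep", query_id, subject_id)
            if (d % 10_000) < int(self.deep_rate * 10_000):
                return 800 + u % 900  # drives e-values far below e^-180
        return 40 + u % 120

    # -- search ------------------------------------------------------------

    def __call__(
        self,
        queries: Sequence[Query],
        db: DatabaseProfile,
        program: str,
        params: SearchParams,
    ) -> str:
        self.calls.append(db)
        subjects: List[Tuple[str, int]] = []
        for fname in db.files:
            if fname not in self.universe:
                raise KeyError(f"unknown database volume {fname!r}")
            subjects.extend(self.universe[fname])
        n = sum(slen for _, slen in subjects)
        if n != db.n or len(subjects) != db.N:
            raise DomainError(
                f"profile sizes (n={db.n}, N={db.N}) disagree with volume "
                f"contents (n={n}, N={len(subjects)})"
            )
        kp = BLASTN_PARAMS if program == "blastn" else BLASTP_PARAMS
        results = []
        for qid, qseq in queries:
            results.append(
                self._search_one(qid, len(qseq), subjects, db, program, params, kp)
            )
        return result_io.write_result(results, dialect="xml")

    def _search_one(
        self, qid, m, subjects, db, program, params, kp
    ) -> SearchResult:
        if program == "blastn":
            l = oracle_length_adjustment(kp, m, db.n, db.N)
            m_eff, n_eff = m - l, db.n - db.N * l
        else:
            # Spouge family: the finite-size area term is emulated as the
            # plain query length, so e-values are exactly linear in n.
            l, m_eff, n_eff = 0, m, db.n
        hits = []
        for sid, slen in subjects:
            if not self.pair_hits(qid, sid):
                continue
            top_score = self.pair_score(qid, sid)
            n_hsps = 1 + _hash_u32(str(self.seed), "nhsp", qid, sid) % self.max_hsps
            hsps = []
            for j in range(n_hsps):
                score = top_score - 7 * j
                log_e = math.fsum(
                    (
                        math.log(kp.K),
                        math.log(m_eff),
                        math.log(n_eff),
                        -kp.lambda_ * score,
                    )
                )
                if self.zero_round and log_e < ZERO_ROUND_LOG_THRESHOLD:
                    ev = EValue.from_linear(0.0)
                else:
                    ev = EValue(log_e=log_e)
                align_len = max(
                    8, min(m, slen, 10 + _hash_u32(str(self.seed), "al", qid, sid, str(j)) % 40)
                )
                mism = _hash_u32(str(self.seed), "id", qid, sid, str(j)) % 4
                hsps.append(
                    Hsp(
                        raw_score=score,
                        bit_score=float(
                            f"{(kp.lambda_ * score - math.log(kp.K)) / math.log(2):.4f}"
                        ),
                        evalue=ev,
                        q_start=1,
                        q_end=align_len,
                        s_start=1 + j,
                        s_end=j + align_len,
                        identity=align_len - min(mism, align_len),
                        align_len=align_len,
                        gaps=0,
                    )
                )
            hits.append(
                Hit(subject_id=sid, subject_def=sid, subject_len=slen, hsps=hsps)
            )
        hits = sort_hits(hits)[: 2 * params.max_target_seqs]
        return SearchResult(
            program=program,
            query=QueryProfile(query_id=qid, m=m),
            db=db,
            params=params,
            hits=hits,
            stats=StatisticsBlock(
                db_num=db.N,
                db_len=db.n,
                hsp_len=l,
                eff_space=m_eff * n_eff,
                kappa=kp.K,
                lambda_=kp.lambda_,
                entropy=kp.H,
            ),
        )


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

_NT_ALPHABET = "ACGT"
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScenarioSpec:
    """Shape of one synthetic study scenario.

    ``mode`` is "temporal" (a database lineage whose snapshots are strictly
    nested by volume list, like a public database growing between searches)
    or "spatial" (pairwise-disjoint taxon partitions searched separately).
    ``snapshot_n_targets`` optionally pins each snapshot's exact cumulative
    residue total, for scenarios that mirror printed database-size
    timelines.  Defaults are desk-scale: everything runs in well under a
    second per scenario.
    """

    seed: int = 0
    molecule: str = "nucleotide"  # nucleotide -> blastn, protein -> blastp
    mode: str = "temporal"
    n_steps: int = 3  # snapshots (temporal) or partitions (spatial)
    n_queries: int = 3
    query_len_range: Tuple[int, int] = (120, 800)
    subjects_per_step: int = 12
    subject_len_range: Tuple[int, int] = (150, 2500)
    snapshot_n_targets: Optional[Sequence[int]] = None
    hit_rate: float = 0.6
    deep_rate: float = 0.0
    zero_round_parts: bool = False
    max_target_seqs: int = 500

    @property
    def program(self) -> str:
        return "blastn" if self.molecule == "nucleotide" else "blastp"


@dataclass
class ScenarioBundle:
    """On-disk layout of one generated scenario."""

    spec: ScenarioSpec
    root: Path
    queries: List[Query]
    queries_fasta: Path
    universe: Dict[str, List[Tuple[str, int]]]
    snapshots: List[DatabaseProfile]  # temporal: nested; spatial: disjoint parts
    union: DatabaseProfile
    part_profiles: List[DatabaseProfile]  # what each stored part was searched on
    part_paths: List[Path]
    reference_path: Path
    executor: MockExecutor


def _random_seq(rng: Random, length: int, alphabet: str) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _subject_lengths(
    rng: Random, count: int, lo: int, hi: int, total: Optional[int]
) -> List[int]:
    if total is None:
        return [rng.randint(lo, hi) for _ in range(count)]
    if total < count:
        raise DomainError(f"cannot place {total} residues into {count} subjects")
    lengths = []
    remaining = total
    for i in range(count - 1):
        slots_left = count - i - 1
        cap = remaining - slots_left
        length = max(1, min(rng.randint(lo, hi), cap))
        lengths.append(length)
        remaining -= length
    lengths.append(remaining)
    return lengths


def generate_scenario(spec: ScenarioSpec, outdir) -> ScenarioBundle:
    """Materialize a scenario: queries, volume catalogs, per-part result
    files, and a whole-database reference result file.

    All files are reproducible byte-for-byte for a given spec (the content
    depends only on the spec's fields, ``seed`` included).
    """
    if spec.mode not in ("temporal", "spatial"):
        raise DomainError(f"unknown scenario mode {spec.mode!r}")
    if spec.snapshot_n_targets is not None:
        targets = list(spec.snapshot_n_targets)
        if len(targets) != spec.n_steps or any(
            b <= a for a, b in zip(targets, targets[1:])
        ):
            raise DomainError("snapshot_n_targets must be one increasing total per step")
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = Random(spec.seed)
    alphabet = _NT_ALPHABET if spec.molecule == "nucleotide" else _AA_ALPHABET

    queries: List[Query] = [
        (f"q{i:02d}", _random_seq(rng, rng.randint(*spec.query_len_range), alphabet))
        for i in range(spec.n_queries)
    ]
    queries_fasta = root / "queries.fasta"
    with queries_fasta.open("w", encoding="utf-8") as fh:
        for qid, seq in queries:
            fh.write(f">{qid}\n")
            for ofs in range(0, len(seq), 70):
                fh.write(seq[ofs : ofs + 70] + "\n")

    # one new volume of subjects per step
    universe: Dict[str, List[Tuple[str, int]]] = {}
    step_profiles: List[DatabaseProfile] = []
    prev_total = 0
    for step in range(spec.n_steps):
        fname = f"vol{step:02d}"
        step_total = None
        if spec.snapshot_n_targets is not None:
            step_total = list(spec.snapshot_n_targets)[step] - prev_total
            prev_total += step_total
        lengths = _subject_lengths(
            rng, spec.subjects_per_step, *spec.subject_len_range, step_total
        )
        universe[fname] = [
            (f"s{step:02d}_{i:03d}", length) for i, length in enumerate(lengths)
        ]
        step_profiles.append(
            DatabaseProfile(
                db_id="syntheticdb",
                n=sum(lengths),
                N=len(lengths),
                files=(fname,),
                molecule=spec.molecule,
                timestamp=f"t{step}",
            )
        )

    if spec.mode == "temporal":
        snapshots = []
        for step in range(spec.n_steps):
            grown = step_profiles[: step + 1]
            snapshots.append(
                DatabaseProfile(
                    db_id="syntheticdb",
                    n=sum(p.n for p in grown),
                    N=sum(p.N for p in grown),
                    files=tuple(f for p in grown for f in p.files),
                    molecule=spec.molecule,
                    timestamp=f"t{step}",
                )
            )
        union = snapshots[-1]
        # the first part is the first snapshot; later parts are the deltas
        part_profiles = [snapshots[0]] + [
            compute_delta(snapshots[i - 1], snapshots[i]).profile()
            for i in range(1, spec.n_steps)
        ]
    else:
        snapshots = step_profiles
        union = DatabaseProfile(
            db_id="syntheticdb",
            n=sum(p.n for p in step_profiles),
            N=sum(p.N for p in step_profiles),
            files=tuple(f for p in step_profiles for f in p.files),
            molecule=spec.molecule,
        )
        part_profiles = list(step_profiles)

    for i, snap in enumerate(snapshots):
        save_db_profile(snap, root / f"db_{snap.timestamp or i}.json")

    params = _SEARCH_PARAMS[spec.program]
    params = SearchParams(
        max_target_seqs=spec.max_target_seqs,
        expect=params.expect,
        matrix=params.matrix,
        match=params.match,
        mismatch=params.mismatch,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
    )
    part_executor = MockExecutor(
        universe,
        spec.seed,
        hit_rate=spec.hit_rate,
        deep_rate=spec.deep_rate,
        zero_round=spec.zero_round_parts,
    )
    ref_executor = MockExecutor(
        universe,
        spec.seed,
        hit_rate=spec.hit_rate,
        deep_rate=spec.deep_rate,
        zero_round=False,
    )

    part_paths = []
    for i, profile in enumerate(part_profiles):
        doc = part_executor(queries, profile, spec.program, params)
        path = root / f"result_part{i}.xml"
        path.write_text(doc, encoding="utf-8")
        part_paths.append(path)
    reference_path = root / "reference.xml"
    reference_path.write_text(
        ref_executor(queries, union, spec.program, params), encoding="utf-8"
    )

    return ScenarioBundle(
        spec=spec,
        root=root,
        queries=queries,
        queries_fasta=queries_fasta,
        universe=universe,
        snapshots=snapshots,
        union=union,
        part_profiles=part_profiles,
        part_paths=part_paths,
        reference_path=reference_path,
        executor=ref_executor,
    )
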