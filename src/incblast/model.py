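"""In-memory model of a BLAST search result: hits, HSPs, statistics block.

A :class:`SearchResult` is one query's ranked list of hits against one
database instance, together with the statistics block (database size,
length adjustment, Karlin parameters) under which its e-values were
computed.  Each hit is a subject sequence carrying one or more high-scoring
pairs (HSPs: locally-optimal gapped alignments); the hit's reported score
and e-value are those of its best HSP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from .stats import (
    DatabaseProfile,
    DomainError,
    EValue,
    QueryProfile,
)

__all__ = [
    "Hsp",
    "Hit",
    "StatisticsBlock",
    "SearchParams",
    "SearchResult",
    "hit_sort_key",
    "sort_hits",
    "results_equal",
]


@dataclass
class Hsp:
    """One high-scoring pair: a locally-optimal gapped local alignment.

    Coordinates are 1-based inclusive exactly as BLAST emits them; for
    minus-strand nucleotide hits BLAST's reversed subject coordinates are
    preserved untouched.
    """

    raw_score: Optional[int]
    bit_score: float
    evalue: EValue
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: int
    align_len: int
    gaps: int = 0
    positive: Optional[int] = None
    q_frame: Optional[int] = None
    s_frame: Optional[int] = None
    qseq: Optional[str] = None
    hseq: Optional[str] = None
    midline: Optional[str] = None

    def __post_init__(self) -> None:
        if self.align_len < self.identity or self.identity < 0:
            raise DomainError(
                f"need align_len >= identity >= 0, got "
                f"align_len={self.align_len}, identity={self.identity}"
            )


@dataclass
class Hit:
    """A subject sequence with its HSPs against one query."""

    subject_id: str
    subject_def: str
    subject_len: int
    hsps: List[Hsp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.hsps:
            raise DomainError(f"hit {self.subject_id!r} has no HSPs")

    @property
    def best_hsp(self) -> Hsp:
        """Highest-scoring HSP (ties: smallest e-value)."""
        return min(
            self.hsps,
            key=lambda h: (
                -(h.raw_score if h.raw_score is not None else h.bit_score),
                h.evalue.log_e,
            ),
        )

    @property
    def raw_score(self) -> Optional[int]:
        return self.best_hsp.raw_score

    @property
    def evalue(self) -> EValue:
        """The hit's reported e-value: that of its highest-scoring HSP."""
        return self.best_hsp.evalue


@dataclass
class StatisticsBlock:
    """Per-result copy of the statistics the e-values were computed under."""

    db_num: Optional[int] = None  # N, number of sequences
    db_len: Optional[int] = None  # n, total residues/bases
    hsp_len: Optional[int] = None  # l, length adjustment
    eff_space: Optional[int] = None  # D, effective search space
    kappa: Optional[float] = None  # K
    lambda_: Optional[float] = None
    entropy: Optional[float] = None  # H


@dataclass(frozen=True)
class SearchParams:
    """Search parameters relevant to statistics and merging."""

    max_target_seqs: int = 500
    expect: float = 10.0
    matrix: Optional[str] = None  # protein scoring matrix name
    match: Optional[int] = None  # nucleotide match reward
    mismatch: Optional[int] = None  # nucleotide mismatch penalty
    gap_open: int = 0
    gap_extend: int = 0

    def scoring_key(self) -> Tuple:
        scoring = self.matrix.upper() if self.matrix else str(self.match)
        return (scoring, self.mismatch, self.gap_open, self.gap_extend)


def hit_sort_key(hit: Hit):
    """Ranking key: ascending e-value, then descending score, then subject id.

    E-values are compared at a quantization of 1e-6 in log space (well below
    any printed precision), so hits of equal significance rank by score and
    subject id deterministically instead of by floating-point round-off.
    """
    score = hit.raw_score
    if score is None:
        score = hit.best_hsp.bit_score
    log_e = hit.evalue.log_e
    if math.isfinite(log_e):
        log_e = round(log_e, 6)
    return (log_e, -score, hit.subject_id)


def sort_hits(hits: List[Hit]) -> List[Hit]:
    return sorted(hits, key=hit_sort_key)


@dataclass
class SearchResult:
    """One query's search result against one database instance."""

    program: str
    query: QueryProfile
    db: DatabaseProfile
    params: SearchParams
    hits: List[Hit]
    stats: StatisticsBlock

    def validate_sorted(self) -> None:
        """Check the merge-time ordering invariant on the hit list."""
        keys = [hit_sort_key(h) for h in self.hits]
        if keys != sorted(keys):
            raise DomainError("hits are not sorted by (e-value, -score, subject_id)")

    def with_hits(self, hits: List[Hit]) -> "SearchResult":
        return replace(self, hits=hits)


def _evalue_close(a: EValue, b: EValue, log_tol: float) -> bool:
    if a.zero_rounded or b.zero_rounded:
        return a.zero_rounded == b.zero_rounded
    return math.isclose(a.log_e, b.log_e, rel_tol=0.0, abs_tol=log_tol) or (
        a.log_e == b.log_e
    )


def results_equal(
    a: SearchResult,
    b: SearchResult,
    *,
    log_tol: float = 1e-9,
    bit_tol: float = 1e-4,
    compare_alignment_strings: bool = True,
    compare_stats: bool = True,
) -> bool:
    """Field-for-field comparison of two results.

    E-values compare in log space with absolute tolerance ``log_tol``
    (equivalent to the same relative tolerance on the linear value); bit
    scores with ``bit_tol``.  Used by round-trip and fidelity tests.
    """
    if (
        a.program != b.program
        or a.query != b.query
        or (a.db.db_id, a.db.n, a.db.N) != (b.db.db_id, b.db.n, b.db.N)
        or a.params != b.params
        or len(a.hits) != len(b.hits)
    ):
        return False
    if compare_stats and a.stats != b.stats:
        return False
    for ha, hb in zip(a.hits, b.hits):
        if (ha.subject_id, ha.subject_def, ha.subject_len) != (
            hb.subject_id,
            hb.subject_def,
            hb.subject_len,
        ):
            return False
        if len(ha.hsps) != len(hb.hsps):
            return False
        for pa, pb in zip(ha.hsps, hb.hsps):
            same = (
                pa.raw_score == pb.raw_score
                and abs(pa.bit_score - pb.bit_score) <= bit_tol
                and _evalue_close(pa.evalue, pb.evalue, log_tol)
                and (pa.q_start, pa.q_end, pa.s_start, pa.s_end)
                == (pb.q_start, pb.q_end, pb.s_start, pb.s_end)
                and (pa.identity, pa.align_len, pa.gaps)
                == (pb.identity, pb.align_len, pb.gaps)
            )
            if same and compare_alignment_strings:
                same = (pa.qseq, pa.hseq, pa.midline) == (pb.qseq, pb.hseq, pb.midline)
            if not same:
                return False
    return True
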