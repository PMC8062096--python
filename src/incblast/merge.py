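"""Recalibration and merging of partial search results.

Searching a query against disjoint parts of a database (or against an old
snapshot plus the newly added delta) yields per-part e-values computed
against the wrong search space.  This module recalibrates each part against
the union database and merges the parts into a single result ranked exactly
as one search of the whole database would rank it:

* Karlin-Altschul programs (blastn, tblastx): the length adjustment ``l`` is
  re-solved for the union database and every HSP e-value is recomputed from
  its raw score, ``E = K·m'·n'·e^(−λS)``.
* Spouge programs (blastp, blastx, tblastn): e-values are rescaled by the
  ratio of actual database lengths, ``E_total = E_part·n_total/n_part``;
  values an upstream tool had rounded to 0.0 are regenerated from their raw
  scores first.

Merged results retain 2 × ``max_target_seqs`` hits: merging over parts
enlarges the candidate pool beyond what a single truncated search reports,
and keeping the doubled list preserves the lower-ranked hits a plain search
would still have shown.  All parts are recalibrated against the same union
database and combined in one k-way ordered merge, so the operation is
associative and commutative up to the truncation boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .io import require_raw_scores
from .model import (
    Hit,
    Hsp,
    SearchResult,
    StatisticsBlock,
    hit_sort_key,
    sort_hits,
)
from .stats import (
    DatabaseProfile,
    DomainError,
    EValue,
    KarlinParams,
    SearchSpace,
    compute_length_adjustment,
    evalue_from_score,
    lookup_alpha_beta,
    rescale_evalue_spouge,
    statistics_family,
)

__all__ = [
    "MergePlanError",
    "MergePlan",
    "recalibrate",
    "merge",
    "union_profile",
    "FidelityReport",
    "compare_results",
]


class MergePlanError(ValueError):
    """The parts of a merge are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Recalibration of a single result against a larger database
# ---------------------------------------------------------------------------


def _karlin_params_for(result: SearchResult) -> KarlinParams:
    st = result.stats
    return lookup_alpha_beta(
        result.program,
        matrix=result.params.matrix,
        match=result.params.match,
        mismatch=result.params.mismatch,
        gap_open=result.params.gap_open,
        gap_extend=result.params.gap_extend,
        lambda_=st.lambda_,
        K=st.kappa,
        H=st.entropy,
    )


def _part_space(result: SearchResult) -> SearchSpace:
    """Reconstruct the search space the part's e-values were computed under."""
    st = result.stats
    if st.db_len is None or st.db_num is None:
        raise DomainError("statistics block lacks database sizes (db-len/db-num)")
    l = st.hsp_len if st.hsp_len is not None else 0
    return SearchSpace(
        l=l, m_eff=result.query.m - l, n_eff=st.db_len - st.db_num * l
    )


def recalibrate(result: SearchResult, union_db: DatabaseProfile) -> SearchResult:
    """Recompute a result's e-values as if it had been searched in ``union_db``.

    The statistics family is chosen by program; the statistics block is
    updated to the union database; hit e-values are re-derived from their
    best HSPs and the hit list re-sorted.  Raises :class:`DomainError` if the
    union database is smaller than the one the result was computed against.
    """
    st = result.stats
    if st.db_len is None or st.db_num is None:
        raise DomainError("statistics block lacks database sizes; cannot recalibrate")
    if union_db.n < st.db_len or union_db.N < st.db_num:
        raise DomainError(
            f"database shrank (union n={union_db.n}, N={union_db.N} vs part "
            f"n={st.db_len}, N={st.db_num}); correction is undefined"
        )
    family = statistics_family(result.program)
    if family == "karlin-altschul":
        new_hits, new_stats = _recalibrate_ka(result, union_db)
    else:
        new_hits, new_stats = _recalibrate_spouge(result, union_db)
    return replace(
        result,
        db=union_db,
        hits=sort_hits(new_hits),
        stats=new_stats,
    )


def _recalibrate_ka(
    result: SearchResult, union_db: DatabaseProfile
) -> Tuple[List[Hit], StatisticsBlock]:
    require_raw_scores(result)
    params = _karlin_params_for(result)
    space = compute_length_adjustment(params, result.query, union_db)
    hits = []
    for hit in result.hits:
        hsps = [
            replace(hsp, evalue=evalue_from_score(params, space, hsp.raw_score))
            for hsp in hit.hsps
        ]
        hits.append(replace(hit, hsps=hsps))
    stats = StatisticsBlock(
        db_num=union_db.N,
        db_len=union_db.n,
        hsp_len=space.l,
        eff_space=space.D,
        kappa=result.stats.kappa,
        lambda_=result.stats.lambda_,
        entropy=result.stats.entropy,
    )
    return hits, stats


def _recalibrate_spouge(
    result: SearchResult, union_db: DatabaseProfile
) -> Tuple[List[Hit], StatisticsBlock]:
    st = result.stats
    n_part = st.db_len
    part_space: Optional[SearchSpace] = None
    params: Optional[KarlinParams] = None

    def fix(hsp: Hsp) -> EValue:
        nonlocal part_space, params
        if hsp.evalue.zero_rounded:
            # Regenerate the true magnitude from the raw score against the
            # part search space, then apply the ratio; never rescale a 0.0.
            if hsp.raw_score is None:
                raise DomainError(
                    "zero-rounded e-value without a raw score cannot be regenerated"
                )
            if params is None:
                params = _karlin_params_for(result)
                part_space = _part_space(result)
            regenerated = evalue_from_score(params, part_space, hsp.raw_score)
            return rescale_evalue_spouge(regenerated, n_part, union_db.n)
        return rescale_evalue_spouge(hsp.evalue, n_part, union_db.n)

    hits = []
    for hit in result.hits:
        hsps = [replace(hsp, evalue=fix(hsp)) for hsp in hit.hsps]
        hits.append(replace(hit, hsps=hsps))
    eff_space = st.eff_space
    if eff_space is not None and n_part:
        # the FSC area term is database-size-linear through its scale factor
        eff_space = round(eff_space * union_db.n / n_part)
    stats = replace(
        st, db_num=union_db.N, db_len=union_db.n, eff_space=eff_space
    )
    return hits, stats


# ---------------------------------------------------------------------------
# Merge plan and k-way merge
# ---------------------------------------------------------------------------


def union_profile(
    profiles: Sequence[DatabaseProfile], db_id: Optional[str] = None
) -> DatabaseProfile:
    """Union of disjoint database parts: sizes add, volume lists concatenate."""
    files: List[str] = []
    seen = set()
    for p in profiles:
        for f in p.files:
            if f not in seen:
                seen.add(f)
                files.append(f)
    return DatabaseProfile(
        db_id=db_id if db_id is not None else profiles[0].db_id,
        n=sum(p.n for p in profiles),
        N=sum(p.N for p in profiles),
        files=tuple(files),
        molecule=profiles[0].molecule,
    )


@dataclass
class MergePlan:
    """Validated inputs of a k-way merge for one query."""

    parts: List[Tuple[SearchResult, DatabaseProfile]]
    union_db: DatabaseProfile
    retain: int  # 2 x max_target_seqs

    @classmethod
    def build(
        cls,
        parts: Sequence[Tuple[SearchResult, Optional[DatabaseProfile]]],
        *,
        union_db: Optional[DatabaseProfile] = None,
        max_target_seqs: Optional[int] = None,
    ) -> "MergePlan":
        """Validate parts and derive the union database and retention bound.

        Each part may carry an explicit :class:`DatabaseProfile`; when absent
        it is recovered from the result's own statistics block.  Parts must
        share program, query identity and scoring scheme, and their volume
        lists must be pairwise disjoint.
        """
        if not parts:
            raise MergePlanError("no parts to merge")
        resolved: List[Tuple[SearchResult, DatabaseProfile]] = []
        for result, profile in parts:
            if profile is None:
                st = result.stats
                if st.db_len is None or st.db_num is None:
                    raise MergePlanError(
                        f"part for db {result.db.db_id!r} carries no database "
                        "sizes; pass an explicit profile"
                    )
                profile = replace(result.db, n=st.db_len, N=st.db_num)
            resolved.append((result, profile))
        first = resolved[0][0]
        for result, _ in resolved[1:]:
            if result.program != first.program:
                raise MergePlanError(
                    f"mixed programs: {first.program} vs {result.program}"
                )
            if result.query != first.query:
                raise MergePlanError(
                    f"mixed queries: {first.query.query_id!r} vs "
                    f"{result.query.query_id!r}"
                )
            if result.params.scoring_key() != first.params.scoring_key():
                raise MergePlanError("parts use different scoring schemes")
        seen: Dict[str, int] = {}
        for i, (_, profile) in enumerate(resolved):
            for f in profile.files:
                if f in seen:
                    warnings.warn(
                        f"volume {f!r} appears in parts {seen[f]} and {i}; "
                        "parts are expected to be disjoint",
                        stacklevel=2,
                    )
                else:
                    seen[f] = i
        if union_db is None:
            union_db = union_profile([p for _, p in resolved])
        if max_target_seqs is None:
            max_target_seqs = first.params.max_target_seqs
        return cls(parts=resolved, union_db=union_db, retain=2 * max_target_seqs)


def merge(plan: MergePlan) -> SearchResult:
    """Merge per-part results into one result over the union database.

    Every part is recalibrated against the same union database, hits are
    pooled (a subject duplicated across parts keeps its better e-value, with
    a warning), ranked ascending by e-value with descending-score then
    lexicographic-subject tie-breaks, and truncated to 2 × max_target_seqs.
    """
    recalibrated = [recalibrate(result, plan.union_db) for result, _ in plan.parts]
    pool: Dict[str, Hit] = {}
    for part in recalibrated:
        for hit in part.hits:
            kept = pool.get(hit.subject_id)
            if kept is None:
                pool[hit.subject_id] = hit
            else:
                warnings.warn(
                    f"subject {hit.subject_id!r} found in more than one part; "
                    "keeping the better-e-value hit",
                    stacklevel=2,
                )
                if hit_sort_key(hit) < hit_sort_key(kept):
                    pool[hit.subject_id] = hit
    hits = sort_hits(list(pool.values()))[: plan.retain]
    base = recalibrated[0]
    return replace(base, db=plan.union_db, hits=hits)


# ---------------------------------------------------------------------------
# Fidelity comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FidelityReport:
    """How closely two results for the same query agree."""

    n_hits_a: int
    n_hits_b: int
    n_common: int
    hit_match_pct: float
    evalue_match_pct: float
    order_agreement_pct: float

    @property
    def identical(self) -> bool:
        return (
            self.hit_match_pct == 100.0
            and self.evalue_match_pct == 100.0
            and self.order_agreement_pct == 100.0
        )


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def compare_results(
    a: SearchResult, b: SearchResult, rel_tol: float = 1e-6
) -> FidelityReport:
    """Hit-set, e-value and ordering agreement between two results.

    ``rel_tol`` is a relative tolerance on linear e-values, applied as an
    absolute tolerance on their natural logarithms.  Order agreement is the
    longest-common-subsequence fraction of the shared hits' orderings.
    """
    if a.query.query_id != b.query.query_id:
        raise MergePlanError("results answer different queries")
    ids_a = [h.subject_id for h in a.hits]
    ids_b = [h.subject_id for h in b.hits]
    common = set(ids_a) & set(ids_b)
    widest = max(len(ids_a), len(ids_b))
    hit_match = 100.0 * len(common) / widest if widest else 100.0

    by_id_a = {h.subject_id: h for h in a.hits}
    by_id_b = {h.subject_id: h for h in b.hits}
    log_tol = abs(math.log1p(rel_tol))
    n_ev_ok = 0
    for sid in common:
        ea, eb = by_id_a[sid].evalue, by_id_b[sid].evalue
        if ea.zero_rounded or eb.zero_rounded:
            ok = ea.zero_rounded == eb.zero_rounded
        else:
            ok = abs(ea.log_e - eb.log_e) <= log_tol
        n_ev_ok += ok
    evalue_match = 100.0 * n_ev_ok / len(common) if common else 100.0

    seq_a = [sid for sid in ids_a if sid in common]
    seq_b = [sid for sid in ids_b if sid in common]
    if not common:
        order = 100.0
    elif seq_a == seq_b:
        order = 100.0
    else:
        order = 100.0 * _lcs_len(seq_a, seq_b) / len(common)

    return FidelityReport(
        n_hits_a=len(ids_a),
        n_hits_b=len(ids_b),
        n_common=len(common),
        hit_match_pct=hit_match,
        evalue_match_pct=evalue_match,
        order_agreement_pct=order,
    )
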