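import math
from random import Random

import pytest
from hypothesis import HealthCheck, settings

from incblast.model import Hit, Hsp, SearchParams, SearchResult, StatisticsBlock, sort_hits
from incblast.stats import DatabaseProfile, EValue, QueryProfile

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_search_result(
    rng: Random,
    *,
    program: str = "blastn",
    n_hits: int | None = None,
    tabular_safe: bool = False,
) -> SearchResult:
    """A random but internally consistent result for round-trip testing.

    ``tabular_safe`` restricts to fields the tabular column map carries
    (no alignment strings or positives, subject_def == subject_id).
    """
    m = rng.randint(50, 2000)
    n_hits = rng.randint(0, 6) if n_hits is None else n_hits
    n_db = rng.randint(10**4, 10**8)
    N_db = rng.randint(5, 500)
    lam, K, H = 0.625, 0.41, 0.78
    if program == "blastp":
        lam, K, H = 0.267, 0.041, 0.14
    hits = []
    for i in range(n_hits):
        slen = rng.randint(30, 5000)
        hsps = []
        for j in range(rng.randint(1, 3)):
            align_len = rng.randint(8, min(m, slen))
            identity = rng.randint(0, align_len)
            score = rng.randint(25, 400)
            log_e = math.log(K * m * n_db) - lam * score
            hsps.append(
                Hsp(
                    raw_score=score,
                    bit_score=float(f"{(lam * score - math.log(K)) / math.log(2):.4f}"),
                    evalue=EValue(log_e=log_e),
                    q_start=1,
                    q_end=align_len,
                    s_start=1,
                    s_end=align_len,
                    identity=identity,
                    align_len=align_len,
                    gaps=rng.randint(0, 3),
                    positive=None if tabular_safe else identity,
                    qseq=None if tabular_safe else "A" * align_len,
                    hseq=None if tabular_safe else "A" * align_len,
                    midline=None if tabular_safe else "|" * align_len,
                )
            )
        sid = f"subj{i:03d}"
        hits.append(
            Hit(
                subject_id=sid,
                subject_def=sid if tabular_safe else f"synthetic subject {i}",
                subject_len=slen,
                hsps=hsps,
            )
        )
    if program == "blastp":
        params = SearchParams(matrix="BLOSUM62", gap_open=11, gap_extend=1,
                              max_target_seqs=rng.choice([100, 500]))
        l = 0
    else:
        params = SearchParams(match=2, mismatch=-3, gap_open=5, gap_extend=2,
                              max_target_seqs=rng.choice([100, 500]))
        l = rng.randint(0, 20)
    return SearchResult(
        program=program,
        query=QueryProfile(query_id=f"query_{rng.randint(0, 999)}", m=m),
        db=DatabaseProfile(
            db_id="randomdb",
            n=n_db,
            N=N_db,
            molecule="protein" if program in ("blastp", "blastx") else "nucleotide",
        ),
        params=params,
        hits=sort_hits(hits),
        stats=StatisticsBlock(
            db_num=N_db,
            db_len=n_db,
            hsp_len=l,
            eff_space=(m - l) * (n_db - N_db * l),
            kappa=K,
            lambda_=lam,
            entropy=H,
        ),
    )


@pytest.fixture
def rng():
    return Random(20260921)
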