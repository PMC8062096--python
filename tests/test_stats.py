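"""Unit and property tests for the significance mathematics."""

import math
from random import Random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from incblast.fixtures import (
    BLASTN_PARAMS,
    oracle_evalue,
    oracle_length_adjustment,
    oracle_rescale,
)
from incblast.stats import (
    DatabaseProfile,
    DomainError,
    EValue,
    KarlinParams,
    QueryProfile,
    SearchSpace,
    ZeroRoundedEValueError,
    compute_length_adjustment,
    correct_evalue_ka,
    evalue_from_score,
    format_evalue,
    growth_fraction,
    lookup_alpha_beta,
    parse_evalue,
    percent_of,
    projected_speedup,
    rescale_evalue_spouge,
    statistics_family,
)


class TestKarlinParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambda_=0.0, K=0.41),
            dict(lambda_=0.6, K=0.0),
            dict(lambda_=0.6, K=0.4, H=-1.0),
            dict(lambda_=0.6, K=0.4, alpha=-0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            KarlinParams(**kwargs)


class TestLengthAdjustment:
    def test_zero_slope_fixed_point_is_the_intercept(self):
        # alpha = 0 makes the iteration constant at beta
        params = KarlinParams(lambda_=0.6, K=0.4, alpha=0.0, beta=7.0)
        space = compute_length_adjustment(
            params, QueryProfile("q", 100), DatabaseProfile("d", 10**5, 10)
        )
        assert space.l == 7
        assert space.m_eff == 93 and space.n_eff == 10**5 - 70

    def test_degenerate_single_residue_query_clamps_to_zero(self):
        space = compute_length_adjustment(
            BLASTN_PARAMS, QueryProfile("q", 1), DatabaseProfile("d", 10**6, 100)
        )
        assert space.l == 0 and space.m_eff == 1

    def test_empty_database_raises(self):
        with pytest.raises(DomainError):
            compute_length_adjustment(
                BLASTN_PARAMS, QueryProfile("q", 100), DatabaseProfile("d", 0, 0)
            )

    def test_blastn_default_case_matches_exhaustive_scan(self):
        space = compute_length_adjustment(
            BLASTN_PARAMS, QueryProfile("q", 1000), DatabaseProfile("d", 10**6, 100)
        )
        assert space.l == oracle_length_adjustment(BLASTN_PARAMS, 1000, 10**6, 100)
        assert space.D == space.m_eff * space.n_eff

    def test_solver_agrees_with_scan_across_random_instances(self):
        rng = Random(11)
        for _ in range(300):
            m = rng.randint(2, 1000)
            N = rng.randint(1, 1000)
            n = rng.randint(N, 10**7)
            params = KarlinParams(
                lambda_=rng.uniform(0.1, 1.5),
                K=rng.uniform(0.01, 0.8),
                H=rng.uniform(0.05, 1.5),
                alpha=rng.uniform(0.0, 3.0),
                beta=rng.uniform(-40.0, 10.0),
            )
            space = compute_length_adjustment(
                params, QueryProfile("q", m), DatabaseProfile("d", n, N)
            )
            assert space.l == oracle_length_adjustment(params, m, n, N)


class TestEvalueFromScore:
    def test_zero_score_gives_log_of_search_space(self):
        space = SearchSpace(l=0, m_eff=100, n_eff=1000)
        ev = evalue_from_score(BLASTN_PARAMS, space, 0)
        assert ev.log_e == pytest.approx(math.log(0.41 * 100 * 1000), abs=1e-12)

    def test_doubling_database_adds_ln2(self):
        s1 = SearchSpace(l=0, m_eff=950, n_eff=9 * 10**5)
        s2 = SearchSpace(l=0, m_eff=950, n_eff=18 * 10**5)
        e1 = evalue_from_score(BLASTN_PARAMS, s1, 60)
        e2 = evalue_from_score(BLASTN_PARAMS, s2, 60)
        assert e2.log_e - e1.log_e == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_direct_high_precision_evaluation(self):
        # K=0.41, lambda=0.625, m'=950, n'=9e5, S=60
        space = SearchSpace(l=50, m_eff=950, n_eff=9 * 10**5)
        ev = evalue_from_score(BLASTN_PARAMS, space, 60)
        expected = math.log(0.41) + math.log(950) + math.log(9e5) - 0.625 * 60
        assert ev.log_e == pytest.approx(expected, abs=1e-12)

    def test_huge_scores_never_underflow_to_zero(self):
        space = SearchSpace(l=0, m_eff=1000, n_eff=10**9)
        ev = evalue_from_score(BLASTN_PARAMS, space, 5000)
        assert math.isfinite(ev.log_e) and not ev.zero_rounded
        assert "e-" in format_evalue(ev) and not format_evalue(ev).startswith("0")


class TestAdditiveKarlinAltschulCorrection:
    def test_identical_spaces_leave_evalue_unchanged(self):
        ev = EValue(log_e=-12.0)
        assert correct_evalue_ka(BLASTN_PARAMS, ev, 60, 10**6, 10**6) is ev

    def test_doubled_space_doubles_the_evalue(self):
        space = SearchSpace(l=0, m_eff=900, n_eff=10**6)
        ev = evalue_from_score(BLASTN_PARAMS, space, 55)
        corrected = correct_evalue_ka(BLASTN_PARAMS, ev, 55, space.D, 2 * space.D)
        assert corrected.log_e == pytest.approx(ev.log_e + math.log(2), abs=1e-10)

    def test_shrinking_space_rejected(self):
        with pytest.raises(DomainError):
            correct_evalue_ka(BLASTN_PARAMS, EValue(log_e=-5.0), 60, 100, 99)

    def test_zero_rounded_input_refused(self):
        with pytest.raises(ZeroRoundedEValueError):
            correct_evalue_ka(BLASTN_PARAMS, EValue.from_linear(0.0), 60, 100, 200)

    @given(
        score=st.integers(min_value=20, max_value=500),
        m_eff=st.integers(min_value=10, max_value=2000),
        n_part=st.integers(min_value=10**3, max_value=10**7),
        extra=st.integers(min_value=0, max_value=10**8),
    )
    def test_additive_correction_equals_from_scratch(self, score, m_eff, n_part, extra):
        """Eq-3-style correction must agree with direct recomputation on the
        union search space to high relative precision."""
        space_part = SearchSpace(l=0, m_eff=m_eff, n_eff=n_part)
        space_total = SearchSpace(l=0, m_eff=m_eff, n_eff=n_part + extra)
        e_part = evalue_from_score(BLASTN_PARAMS, space_part, score)
        corrected = correct_evalue_ka(
            BLASTN_PARAMS, e_part, score, space_part.D, space_total.D
        )
        direct = evalue_from_score(BLASTN_PARAMS, space_total, score)
        assert corrected.log_e == pytest.approx(direct.log_e, abs=1e-10)
        assert corrected.log_e >= e_part.log_e  # monotone under growth


class TestSpougeRescaling:
    def test_identity_at_ratio_one(self):
        ev = EValue(log_e=-33.25)
        assert rescale_evalue_spouge(ev, 500, 500).log_e == ev.log_e

    def test_tripled_database_adds_ln3_exactly(self):
        ev = EValue(log_e=-33.25)
        out = rescale_evalue_spouge(ev, 10**6, 3 * 10**6)
        assert out.log_e == ev.log_e + math.log(3 * 10**6) - math.log(10**6)

    @given(
        log_e=st.floats(min_value=-400, max_value=5),
        a=st.integers(min_value=1, max_value=10**12),
        b=st.integers(min_value=1, max_value=10**12),
        c=st.integers(min_value=1, max_value=10**12),
    )
    def test_rescaling_composes_over_size_triples(self, log_e, a, b, c):
        ev = EValue(log_e=log_e)
        chained = rescale_evalue_spouge(rescale_evalue_spouge(ev, a, b), b, c)
        direct = rescale_evalue_spouge(ev, a, c)
        assert chained.log_e == pytest.approx(direct.log_e, abs=1e-9)

    def test_zero_rounded_input_refused_with_redirect(self):
        with pytest.raises(ZeroRoundedEValueError, match="raw score"):
            rescale_evalue_spouge(EValue.from_linear(0.0), 10, 20)

    def test_agrees_with_independent_oracle(self):
        rng = Random(5)
        for _ in range(200):
            ev = EValue(log_e=rng.uniform(-500, 3))
            a, b = rng.randint(1, 10**10), rng.randint(1, 10**10)
            assert rescale_evalue_spouge(ev, a, b).log_e == oracle_rescale(ev, a, b).log_e


class TestGrowthArithmetic:
    @pytest.mark.parametrize(
        "past,present,expected",
        [(44.5, 62.7, 40.8), (62.7, 84.1, 34.1), (50.0, 50.0, 0.0)],
    )
    def test_growth_fraction_at_printed_precision(self, past, present, expected):
        assert growth_fraction(past, present) == expected

    def test_growth_from_zero_rejected(self):
        with pytest.raises(DomainError):
            growth_fraction(0.0, 10.0)

    @pytest.mark.parametrize(
        "delta,expected", [(0.48, 3.08), (1.0, 2.0), (0.10, 11.0)]
    )
    def test_projected_speedup(self, delta, expected):
        assert round(projected_speedup(delta), 2) == expected

    def test_nonpositive_growth_rejected(self):
        with pytest.raises(DomainError):
            projected_speedup(0.0)

    def test_percent_of_fraction(self):
        assert percent_of(13171, 837942) == 1.57


class TestRoutingAndParameterProvenance:
    @pytest.mark.parametrize(
        "program,family",
        [
            ("blastn", "karlin-altschul"),
            ("tblastx", "karlin-altschul"),
            ("blastp", "spouge"),
            ("blastx", "spouge"),
            ("tblastn", "spouge"),
        ],
    )
    def test_program_to_statistics_family(self, program, family):
        assert statistics_family(program) == family

    def test_unknown_program_rejected(self):
        with pytest.raises(DomainError):
            statistics_family("hmmer")

    def test_known_scheme_found_in_bundled_table(self):
        kp = lookup_alpha_beta("blastn", match=2, mismatch=-3, gap_open=5, gap_extend=2)
        assert (kp.lambda_, kp.K, kp.alpha, kp.beta) == (0.625, 0.41, 0.8, -2)

    def test_statistics_block_values_take_precedence_over_table(self):
        kp = lookup_alpha_beta(
            "blastn", match=2, mismatch=-3, gap_open=5, gap_extend=2,
            lambda_=0.62, K=0.40,
        )
        assert (kp.lambda_, kp.K) == (0.62, 0.40)
        assert (kp.alpha, kp.beta) == (0.8, -2)

    def test_unknown_scheme_falls_back_to_ungapped_convention(self):
        with pytest.warns(UserWarning, match="ungapped convention"):
            kp = lookup_alpha_beta(
                "blastn", match=1, mismatch=-3, gap_open=2, gap_extend=1,
                lambda_=1.1, K=0.3, H=0.9,
            )
        assert kp.alpha == pytest.approx(1.1 / 0.9)
        assert kp.beta == 0.0


class TestEvalueSerialization:
    @pytest.mark.parametrize("log_e", [-1.5, -50.0, -180.1, -500.0, -2000.0, 1.2])
    def test_round_trip_preserves_log_even_below_float_floor(self, log_e):
        ev = EValue(log_e=log_e)
        text = format_evalue(ev)
        assert not text.startswith("0")
        assert parse_evalue(text).log_e == pytest.approx(log_e, abs=1e-10)

    def test_literal_zero_parses_as_zero_rounded(self):
        for text in ("0", "0.0", "0e+00"):
            ev = parse_evalue(text)
            assert ev.zero_rounded and ev.linear == 0.0

    def test_plain_decimal_and_scientific_agree(self):
        assert parse_evalue("0.001").log_e == pytest.approx(
            parse_evalue("1.0e-03").log_e, abs=1e-12
        )
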