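"""Flag engine: per-check behavior, policy overrides, and engine invariants."""

import pytest

from botscreen import (
    FlagCode,
    FlagPolicy,
    Severity,
    build_context,
    evaluate_all,
    evaluate_cohort,
)
from botscreen.errors import ConfigurationError
from botscreen.flags import (
    NOT_EVALUABLE,
    check_age_consistency,
    check_attention,
    check_comorbid_excess,
    check_email_similarity,
    check_fast_completion,
    check_honeypot,
    check_matrix_patterns,
    check_open_text,
)

from conftest import make_record

POLICY = FlagPolicy()


def ctx(*records):
    return build_context(list(records))


class TestHoneypot:
    @pytest.mark.parametrize("answer", ["", "   ", "\t\n"])
    def test_empty_or_whitespace_passes(self, answer):
        assert check_honeypot(make_record(honeypot_response=answer), POLICY) is None

    def test_any_answer_is_red(self):
        f = check_honeypot(make_record(honeypot_response="USA"), POLICY)
        assert f.code is FlagCode.HONEYPOT and f.severity is Severity.RED


class TestAttention:
    @pytest.mark.parametrize("answer", ["fair", "Fair", "FAIR", " fair "])
    def test_instructed_label_passes_case_insensitively(self, answer):
        assert check_attention(make_record(attention_response=answer),
                               POLICY) is None

    def test_other_label_is_red(self):
        f = check_attention(make_record(attention_response="good"), POLICY)
        assert f.code is FlagCode.ATTENTION and f.severity is Severity.RED

    def test_expected_label_missing_from_scale_is_config_error(self):
        bad = FlagPolicy(attention_expected="splendid")
        with pytest.raises(ConfigurationError, match="splendid"):
            check_attention(make_record(), bad)


class TestAgeConsistency:
    @pytest.mark.parametrize("ages, flagged", [
        ((54, 54), False),
        ((54, 54, 55), False),  # a birthday between items is tolerated
        ((54, 24), True),
        ((54, 56), True),
    ])
    def test_spread_against_tolerance(self, ages, flagged):
        result = check_age_consistency(make_record(age_responses=ages), POLICY)
        if flagged:
            assert result.code is FlagCode.AGE_INCONSISTENT
            assert result.severity is Severity.ORANGE
        else:
            assert result is None

    def test_single_answer_is_not_evaluable_not_clean(self):
        result = check_age_consistency(make_record(age_responses=(54,)), POLICY)
        assert result is NOT_EVALUABLE and result is not None


class TestComorbidExcess:
    @pytest.mark.parametrize("n_selected, flagged",
                             [(13, True), (12, False), (0, False)])
    def test_only_full_checklist_flags(self, n_selected, flagged):
        checklist = tuple([True] * n_selected + [False] * (13 - n_selected))
        result = check_comorbid_excess(make_record(comorbidity_checklist=checklist),
                                       POLICY)
        assert (result is not None) == flagged
        if flagged:
            assert result.severity is Severity.ORANGE


class TestMatrixPatterns:
    def test_perfect_alternation_is_zigzag(self):
        flags = check_matrix_patterns(
            make_record(matrix_blocks=((1, 5, 1, 5, 1),)), POLICY)
        assert [f.code for f in flags] == [FlagCode.MATRIX_ZIGZAG]
        assert flags[0].severity is Severity.ORANGE

    def test_constant_block_is_straightline(self):
        flags = check_matrix_patterns(make_record(matrix_blocks=((3, 3, 3, 3),)),
                                      POLICY)
        assert [f.code for f in flags] == [FlagCode.MATRIX_STRAIGHTLINE]
        assert flags[0].severity is Severity.YELLOW

    @pytest.mark.parametrize("block", [
        (2, 4, 3, 5, 1),        # irregular
        (1, 5, 1, 4, 1),        # alternating sign, unequal magnitude
        (1, 2, 3, 4, 5),        # monotone ramp
        (2, 4, 2, 4),           # zigzag but see below: length == min_len ok
    ])
    def test_non_patterns_and_boundaries(self, block):
        flags = check_matrix_patterns(make_record(matrix_blocks=(block,)), POLICY)
        if block == (2, 4, 2, 4):
            assert [f.code for f in flags] == [FlagCode.MATRIX_ZIGZAG]
        else:
            assert flags == []

    def test_short_blocks_never_flag(self):
        assert check_matrix_patterns(
            make_record(matrix_blocks=((1, 5, 1), (2, 2, 2))), POLICY) == []


class TestOpenText:
    def test_plain_english_passes(self):
        r = make_record()
        assert check_open_text(r, ctx(r), POLICY) is None

    def test_gibberish_ratio_flags(self):
        r = make_record(open_texts=("xqzvv bnnrp ttkkl",))
        f = check_open_text(r, ctx(r), POLICY)
        assert f.code is FlagCode.OPEN_TEXT and f.severity is Severity.ORANGE

    def test_verbatim_duplicate_flags_both_records(self):
        text = "the pain was worse after climbing the stairs today"
        a = make_record(record_id="A", open_texts=(text,))
        b = make_record(record_id="B", open_texts=(text,))
        context = ctx(a, b)
        assert check_open_text(a, context, POLICY).code is FlagCode.OPEN_TEXT
        assert check_open_text(b, context, POLICY).code is FlagCode.OPEN_TEXT

    def test_non_english_arm_skips_dictionary_test(self):
        r = make_record(language_arm="it-IT",
                        open_texts=("ho male alle ginocchia dopo camminato",))
        assert check_open_text(r, ctx(r), POLICY) is None

    def test_two_token_answer_below_minimum_not_tested(self):
        r = make_record(open_texts=("zzzqq xxttr",))
        assert check_open_text(r, ctx(r), POLICY) is None


class TestEmailSimilarity:
    def test_digit_suffix_twins_flag_both_ways(self):
        a = make_record(record_id="A", email="ann.smith1991@example.com")
        b = make_record(record_id="B", email="ann.smith1992@example.com")
        context = ctx(a, b)
        fa = check_email_similarity(a, context, POLICY)
        fb = check_email_similarity(b, context, POLICY)
        assert fa.code is fb.code is FlagCode.EMAIL_SIMILAR
        assert fa.severity is Severity.YELLOW

    def test_unrelated_addresses_pass(self):
        a = make_record(record_id="A", email="giulia.ferrari@example.com")
        b = make_record(record_id="B", email="owen.dekker@post.example")
        context = ctx(a, b)
        assert check_email_similarity(a, context, POLICY) is None
        assert check_email_similarity(b, context, POLICY) is None

    def test_single_record_cohort_cannot_flag(self):
        a = make_record(record_id="A", email="x@y.com")
        assert check_email_similarity(a, ctx(a), POLICY) is None

    def test_shared_stem_with_long_digit_suffix(self):
        a = make_record(record_id="A", email="promo2024win88@x.com")
        b = make_record(record_id="B", email="promo2024win4512@x.com")
        context = ctx(a, b)
        assert check_email_similarity(a, context, POLICY) is not None


class TestFastCompletion:
    def _cohort(self, times):
        return [make_record(record_id=f"R{i}", completion_seconds=t)
                for i, t in enumerate(times)]

    def test_record_at_median_passes(self):
        cohort = self._cohort([600, 580, 600, 620, 640])
        context = build_context(cohort)
        assert check_fast_completion(cohort[0], context, POLICY) is None

    def test_far_below_median_flags(self):
        cohort = self._cohort([60, 600, 590, 610, 620])
        context = build_context(cohort)
        f = check_fast_completion(cohort[0], context, POLICY)
        assert f.code is FlagCode.FAST_COMPLETION and f.severity is Severity.YELLOW

    def test_small_cohort_skipped(self):
        cohort = self._cohort([60, 600, 600, 600])
        context = build_context(cohort)
        assert check_fast_completion(cohort[0], context, POLICY) is None


class TestEvaluateAll:
    def test_clean_record_has_empty_flagset(self):
        r = make_record()
        fs = evaluate_all(r, ctx(r))
        assert fs.flags == () and fs.counts == {Severity.YELLOW: 0,
                                                Severity.ORANGE: 0,
                                                Severity.RED: 0}

    def test_attention_plus_comorbid_is_one_red_one_orange(self):
        r = make_record(attention_response="good",
                        comorbidity_checklist=tuple([True] * 13))
        fs = evaluate_all(r, ctx(r))
        assert fs.counts[Severity.RED] == 1 and fs.counts[Severity.ORANGE] == 1

    def test_bot_profile_counts(self):
        r = make_record(honeypot_response="USA", attention_response="good",
                        matrix_blocks=((1, 5, 1, 5, 1, 5),))
        fs = evaluate_all(r, ctx(r))
        assert fs.counts == {Severity.RED: 2, Severity.ORANGE: 1,
                             Severity.YELLOW: 0}

    def test_policy_override_changes_severity(self):
        policy = FlagPolicy(severities={**{c: s for c, s in
                                           FlagPolicy().severities.items()},
                                        FlagCode.ATTENTION: Severity.YELLOW})
        r = make_record(attention_response="good")
        fs = evaluate_all(r, ctx(r), policy)
        assert fs.counts[Severity.YELLOW] == 1 and fs.counts[Severity.RED] == 0

    def test_counts_conserve_flag_tally(self, stress_cohort):
        for fs in evaluate_cohort(stress_cohort[:200]):
            assert sum(fs.counts.values()) == len(fs.flags)
            assert len({f.code for f in fs.flags}) == len(fs.flags)

    def test_cohort_checks_are_symmetric(self, stress_cohort):
        flagsets = evaluate_cohort(stress_cohort[:300])
        by_id = {fs.record_id: fs for fs in flagsets}
        for fs in flagsets:
            for f in fs.flags:
                if f.code is FlagCode.EMAIL_SIMILAR:
                    # evidence names the partner record: it must flag back
                    partner = f.evidence.rsplit("record ", 1)[1].rstrip(")")
                    codes = {g.code for g in by_id[partner].flags}
                    assert FlagCode.EMAIL_SIMILAR in codes


def test_policy_rejects_unknown_or_incomplete_mappings():
    with pytest.raises(ValueError):
        FlagPolicy(severities={"NOT_A_CODE": "red"})
    with pytest.raises(ValueError):
        FlagPolicy(severities={FlagCode.HONEYPOT: Severity.RED})
    with pytest.raises(ValueError):
        FlagPolicy(pattern_min_len=2)
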