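"""Synthetic-cohort generator: defaults, determinism, and calibration."""

import numpy as np
import pytest

from botscreen import (
    BehaviorParams,
    CohortConfig,
    default_params,
    generate_cohort,
    generate_eda,
    remuneration,
    write_records,
)
from botscreen.cohort import SCENARIOS
from botscreen.errors import ConfigurationError
from botscreen.flags import _is_zigzag, english_words, tokenize


class TestDefaultParams:
    def test_pre_safeguard_bots_are_english_arm_only(self):
        _, params = default_params("pre_safeguard")
        assert params["bot"].arm_weights["en-US"] == 1.0

    def test_post_safeguard_bot_prevalence(self):
        config, _ = default_params("post_safeguard")
        assert config.class_mix["bot"] == pytest.approx(18 / 147)
        assert config.n_total == 147

    def test_post_safeguard_attention_failure_rate(self):
        _, params = default_params("post_safeguard")
        assert params["bot"].attention_fail_prob == pytest.approx(15 / 18)
        assert params["bot"].combo_prob == pytest.approx(3 / 18)

    def test_unknown_scenario_lists_valid_ones(self):
        with pytest.raises(ConfigurationError) as exc:
            default_params("mid_safeguard")
        assert all(s in str(exc.value) for s in SCENARIOS)


class TestGenerateCohort:
    def test_probability_zero_events_never_occur(self):
        config = CohortConfig(seed=1, n_total=50,
                              class_mix={"legitimate": 1.0})
        clean = BehaviorParams()  # every anomaly probability is 0
        records, labels = generate_cohort(config, {"legitimate": clean})
        assert len(records) == 50
        assert all(r.honeypot_response == "" for r in records)
        assert all(r.attention_response == "fair" for r in records)
        assert all(max(r.age_responses) - min(r.age_responses) <= 1
                   for r in records)

    def test_probability_one_zigzag_in_every_bot(self):
        config = CohortConfig(seed=2, n_total=20, class_mix={"bot": 1.0})
        params = {"bot": BehaviorParams(zigzag_prob=1.0)}
        records, _ = generate_cohort(config, params)
        assert len(records) == 20
        assert all(any(_is_zigzag(b, 4) for b in r.matrix_blocks)
                   for r in records)

    def test_zero_records_requested_is_empty_not_error(self):
        config = CohortConfig(seed=3, n_total=0, class_mix={"legitimate": 1.0})
        records, labels = generate_cohort(config, {"legitimate": BehaviorParams()})
        assert records == [] and labels == []

    def test_same_seed_same_config_byte_identical(self, tmp_path):
        config, params = default_params("post_safeguard")
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_records(generate_cohort(config, params)[0], a)
        write_records(generate_cohort(config, params)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self):
        config, params = default_params("post_safeguard")
        r1, _ = generate_cohort(config, params)
        r2, _ = generate_cohort(config.model_copy(update={"seed": 1}), params)
        assert r1 != r2

    def test_mean_bot_count_matches_binomial_expectation(self):
        """Post-safeguard defaults at n=147: bot count ~ Binomial(147, 18/147),
        so the mean over seeds must sit within 3 MC standard errors of 18."""
        config, params = default_params("post_safeguard")
        n_seeds = 100
        counts = []
        for seed in range(n_seeds):
            _, labels = generate_cohort(config.model_copy(update={"seed": seed}),
                                        params)
            counts.append(sum(1 for l in labels if l.klass == "bot"))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(counts.mean() - 18.0) <= 3 * se

    def test_records_are_valid_and_ordered_by_arrival(self):
        from botscreen import validate_record

        config, params = default_params("post_safeguard")
        records, _ = generate_cohort(config, params)
        assert all(validate_record(r) == [] for r in records)
        starts = [r.started_at for r in records]
        assert starts == sorted(starts)


ANOMALY_PROBES = {
    "honeypot_fill_prob": lambda r: r.honeypot_response != "",
    "attention_fail_prob": lambda r: r.attention_response != "fair",
    "all_comorbid_prob": lambda r: all(r.comorbidity_checklist),
    "zigzag_prob": lambda r: any(_is_zigzag(b, 4) for b in r.matrix_blocks),
    "gibberish_prob": lambda r: any(
        sum(t in english_words() for t in tokenize(t_)) / max(len(tokenize(t_)), 1)
        < 0.5 for t_ in r.open_texts),
}


def test_anomaly_prevalence_converges_to_parameters():
    """At n=5,000 each independent anomaly's frequency sits within 3 binomial
    standard errors of its class parameter."""
    probs = {"honeypot_fill_prob": 0.3, "attention_fail_prob": 0.25,
             "all_comorbid_prob": 0.2, "zigzag_prob": 0.15,
             "gibberish_prob": 0.1}
    n = 5000
    config = CohortConfig(seed=41, n_total=n, class_mix={"bot": 1.0})
    records, _ = generate_cohort(config, {"bot": BehaviorParams(**probs)})
    for name, probe in ANOMALY_PROBES.items():
        p = probs[name]
        observed = sum(probe(r) for r in records) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se, (name, observed, p)


class TestGenerateEda:
    def _cohort(self, n=30, seed=7):
        config = CohortConfig(seed=seed, n_total=n, class_mix={"legitimate": 1.0})
        return generate_cohort(config, {"legitimate": BehaviorParams()})

    def test_point_mass_one_answers_every_prompt(self):
        records, labels = self._cohort()
        params = {"legitimate": BehaviorParams(prompt_beta_a=1.0, prompt_beta_b=0.0)}
        sessions = generate_eda(records, labels, params, seed=1)
        assert all(s.n_responded == 28 for s in sessions)

    def test_point_mass_zero_misses_everything_and_earns_two_dollars(self):
        records, labels = self._cohort()
        params = {"legitimate": BehaviorParams(prompt_beta_a=0.0, prompt_beta_b=1.0)}
        sessions = generate_eda(records, labels, params, seed=1)
        assert all(s.n_responded == 0 for s in sessions)
        assert all(remuneration(s).amount_usd == 2 for s in sessions)

    def test_beta_9_3_cohort_mean_near_three_quarters(self):
        records, labels = self._cohort(n=100, seed=9)
        params = {"legitimate": BehaviorParams(prompt_beta_a=9.0, prompt_beta_b=3.0)}
        sessions = generate_eda(records, labels, params, seed=2)
        mean = np.mean([s.n_responded / 28 for s in sessions])
        # rate sd ~ sqrt(ab/((a+b)^2(a+b+1))) = 0.12 -> SE over 100 ~ 0.0125
        assert abs(mean - 0.75) < 3 * 0.013 + 0.01

    def test_enrolled_condition_drawn_from_record_conditions(self):
        records, labels = self._cohort()
        sessions = generate_eda(records, labels,
                                {"legitimate": BehaviorParams()}, seed=3)
        by_id = {r.record_id: r for r in records}
        assert all(s.enrolled_condition in by_id[s.record_id].conditions
                   for s in sessions)
        assert all(p.initiation_delay_seconds is None or
                   0 <= p.initiation_delay_seconds <= 7200
                   for s in sessions for p in s.prompts)


def test_config_requires_exactly_one_size_mode():
    with pytest.raises(ValueError):
        CohortConfig(seed=0, n_total=10, duration_hours=48.0)
    with pytest.raises(ValueError):
        CohortConfig(seed=0)


def test_mixture_profile_probabilities_validated():
    with pytest.raises(ValueError):
        BehaviorParams(anomaly_mixture=True, attention_fail_prob=0.9,
                       combo_prob=0.3)
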