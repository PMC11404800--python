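from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, settings

from botscreen import BehaviorParams, CohortConfig, SurveyRecord, default_params

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

_T0 = datetime(2022, 5, 4, 9, 0, tzinfo=timezone.utc)


def make_record(**overrides) -> SurveyRecord:
    """A fully valid, flag-free baseline record; override fields per test."""
    completion = overrides.pop("completion_seconds", 600.0)
    started = overrides.pop("started_at", _T0)
    base = dict(
        record_id="R1",
        language_arm="en-US",
        started_at=started,
        submitted_at=started + timedelta(seconds=completion),
        email="ruth.holm@example.com",
        conditions=("asthma",),
        months_with_condition=24,
        symptoms_per_week=5,
        comorbidity_checklist=tuple([True] + [False] * 12),
        age_responses=(54, 54, 54),
        honeypot_response="",
        attention_response="fair",
        matrix_blocks=((2, 4, 3, 5, 1, 2), (1, 3, 2, 2, 4, 1, 3, 2)),
        open_texts=("my knees ache after walking",
                    "i rest and take my medication"),
        completion_seconds=completion,
    )
    base.update(overrides)
    return SurveyRecord(**base)


@pytest.fixture(scope="session")
def post_defaults() -> tuple[CohortConfig, dict[str, BehaviorParams]]:
    return default_params("post_safeguard")


@pytest.fixture(scope="session")
def stress_cohort():
    """A 1,000-record cohort exercising every anomaly type and all arms."""
    from botscreen import generate_cohort

    noisy = BehaviorParams(
        honeypot_fill_prob=0.15, attention_fail_prob=0.2,
        age_inconsistency_prob=0.15, all_comorbid_prob=0.15,
        zigzag_prob=0.2, straightline_prob=0.2, gibberish_prob=0.2,
        canned_text_prob=0.15, email_cluster_prob=0.15,
        completion_median_s=200.0, completion_sigma=0.8,
        arm_weights={"en-US": 0.7, "it-IT": 0.1, "nl-NL": 0.1, "sv-SE": 0.1})
    quiet = BehaviorParams(
        attention_fail_prob=0.05, age_inconsistency_prob=0.05,
        straightline_prob=0.05,
        arm_weights={"en-US": 0.4, "it-IT": 0.2, "nl-NL": 0.2, "sv-SE": 0.2})
    config = CohortConfig(
        scenario="post_safeguard", seed=97, n_total=1000,
        class_mix={"bot": 0.5, "legitimate": 0.5, "careless": 0.0})
    records, labels = generate_cohort(config, {"bot": noisy, "legitimate": quiet})
    return records
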