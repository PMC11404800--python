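"""Published enrollment counts from the multinational symptom-monitoring
study whose screening procedure this package implements.

These are the printed stage counts of the study's two launches: the
unprotected initial launch (overwhelmed by bots within 48 hours) and the
safeguarded relaunch.  They serve as fixed arithmetic inputs for funnel
reporting and as the reference conditions for the synthetic-cohort defaults.
Note the report itself is internally inconsistent on one count: manual
inspection is described both as finding 17 invalid records (11.6%) and 18
fraudulent cases (12.2%) out of 147; both identities are kept.
"""

from __future__ import annotations

from .funnel import percent, responses_per_hour

INITIAL_LAUNCH = {
    "responses": 411,
    "hours": 48,
    "registered": 265,
    "passed_inspection": 7,
    "passed_verification": 2,
}

RELAUNCH = {
    "responses": 147,
    "fraudulent": 18,          # as summarized
    "invalid_at_inspection": 17,  # as reported in detail
    "valid": 127,
    "registered": 81,
    "pv_not_completed": 16,
    "pv_completed": 65,
    "gift_cards_redeemed": 51,
}


def reported_percentages() -> dict[str, float]:
    """Recompute every printed funnel percentage from its printed counts."""
    i, r = INITIAL_LAUNCH, RELAUNCH
    return {
        "pct_registered_initial_launch": percent(i["registered"], i["responses"]),
        "pct_passed_inspection_initial_launch": percent(i["passed_inspection"],
                                                        i["responses"]),
        "pct_passed_verification_initial_launch": percent(i["passed_verification"],
                                                          i["responses"]),
        "pct_fraudulent_relaunch": percent(r["fraudulent"], r["responses"]),
        "pct_invalid_relaunch_inspection": percent(r["invalid_at_inspection"],
                                                   r["responses"]),
        "pct_valid_relaunch": percent(r["valid"], r["responses"]),
        "pct_registered_relaunch": percent(r["registered"], r["valid"]),
        "pct_payment_verification_not_completed": percent(r["pv_not_completed"],
                                                          r["registered"]),
        "pct_gift_cards_redeemed": percent(r["gift_cards_redeemed"],
                                           r["pv_completed"]),
    }


def initial_launch_rate() -> float:
    """Intake rate of the unprotected launch, responses per hour."""
    return responses_per_hour(INITIAL_LAUNCH["responses"], INITIAL_LAUNCH["hours"])
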