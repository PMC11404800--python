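"""End-to-end orchestration: simulate -> flag -> screen -> follow-up -> funnel.

The pipeline models the *safeguarded* procedure: every baseline record is
inspected, only invited records can register for the EMA app, and every
registered participant faces the payment-verification survey after two
weeks.  All randomness derives from the single cohort seed through named
substreams, so one integer reproduces the entire run byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    BehaviorParams,
    CohortConfig,
    generate_cohort,
    generate_eda,
    generate_payment,
)
from .flags import FlagPolicy, FlagSet, evaluate_cohort
from .funnel import FunnelReport, build_funnel
from .records import EDASession, GroundTruthLabel, SurveyRecord
from .screening import (
    Decision,
    FinalStatus,
    InspectionOutcome,
    PaymentVerification,
    PVResult,
    decide_baseline,
    final_status,
    verify_payment,
)

_SUBSTREAMS = {"registration": 1, "eda": 2, "payment": 3}


def _sub_seed(seed: int, stream: str) -> int:
    """A stable, independent 31-bit seed for a named pipeline stage."""
    state = np.random.SeedSequence([seed, _SUBSTREAMS[stream]]).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


@dataclass
class PipelineResult:
    config: CohortConfig
    records: list[SurveyRecord]
    labels: list[GroundTruthLabel]
    flagsets: list[FlagSet]
    outcomes: dict[str, InspectionOutcome]
    registered: set[str]
    sessions: list[EDASession]
    payments: list[PaymentVerification]
    pv_results: dict[str, PVResult]
    statuses: dict[str, FinalStatus]
    funnel: FunnelReport


def run_pipeline(config: CohortConfig,
                 params: dict[str, BehaviorParams],
                 policy: FlagPolicy | None = None) -> PipelineResult:
    """Run the full screened-enrollment pipeline for one synthetic cohort."""
    policy = policy or FlagPolicy()
    records, labels = generate_cohort(config, params)
    klass_of = {l.record_id: l.klass for l in labels}

    flagsets = evaluate_cohort(records, policy)
    outcomes = {fs.record_id: decide_baseline(fs) for fs in flagsets}

    reg_rng = np.random.default_rng(_sub_seed(config.seed, "registration"))
    invited = [r for r in records
               if outcomes[r.record_id].decision is Decision.INVITE]
    registered = {r.record_id for r in invited
                  if reg_rng.random() < params[klass_of[r.record_id]].registration_prob}

    reg_records = [r for r in records if r.record_id in registered]
    sessions = generate_eda(reg_records, labels, params,
                            _sub_seed(config.seed, "eda"))
    payments = generate_payment(sessions, labels, params,
                                _sub_seed(config.seed, "payment"))
    session_of = {s.record_id: s for s in sessions}
    pv_results = {pv.record_id: verify_payment(pv, session_of[pv.record_id])
                  for pv in payments}

    statuses = {
        r.record_id: final_status(outcomes[r.record_id],
                                  r.record_id in registered,
                                  pv_results.get(r.record_id))
        for r in records
    }
    hours = config.duration_hours if config.duration_hours else config.window_hours
    funnel = build_funnel(statuses, sessions, hours)
    return PipelineResult(config, records, labels, flagsets, outcomes,
                          registered, sessions, payments, pv_results,
                          statuses, funnel)
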