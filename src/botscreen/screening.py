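"""Exclusion rules and enrollment status.

A record is a *reasonable exclusion* at baseline when it has

  (a) any red flag,
  (b) two or more orange flags, or
  (c) four or more flags of any severity, at least one of which is orange;

and an enrolled participant is additionally excluded when they

  (d) fail the post-study payment verification (a second CAPTCHA plus recall
      of the condition and symptom they reported on for two weeks).

The thresholds are intentionally conservative: it should be more likely to
include a convincing fraudulent response than to exclude a legitimate one.
Rule (c) counts flags of every severity, yellows included — red alone already
triggers (a), so (c) only adds information when soft flags accumulate.
Non-completion of payment verification is *not* treated as failure: those
participants simply forgo the incentive, and their longitudinal data stand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConsistencyError
from .flags import FlagSet, Severity
from .records import EDASession


class Rule(enum.StrEnum):
    A_ANY_RED = "A_any_red"
    B_TWO_ORANGE = "B_two_orange"
    C_FOUR_FLAGS_ONE_ORANGE = "C_four_flags_one_orange"
    D_PAYMENT_FAILED = "D_payment_failed"


class Decision(enum.StrEnum):
    INVITE = "invite"
    EXCLUDE = "exclude"


class PVResult(enum.StrEnum):
    PASS = "pass"
    FAIL = "fail"
    NOT_COMPLETED = "not_completed"


class FinalStatus(enum.StrEnum):
    """Mutually exclusive, exhaustive end states for any baseline record."""

    EXCLUDED_BASELINE = "excluded_baseline"
    INVITED_NOT_REGISTERED = "invited_not_registered"
    ENROLLED = "enrolled"
    ENROLLED_PAYMENT_FAILED = "enrolled_payment_failed"
    ENROLLED_VERIFICATION_NOT_COMPLETED = "enrolled_verification_not_completed"
    COMPLETED_VERIFIED = "completed_verified"


#: Statuses that count as "excluded" when scoring the safeguards: flagged at
#: baseline inspection, or unmasked by the payment-verification recall test.
EXCLUDED_STATUSES = frozenset(
    {FinalStatus.EXCLUDED_BASELINE, FinalStatus.ENROLLED_PAYMENT_FAILED})

#: Statuses implying the participant registered for the EMA app.
REGISTERED_STATUSES = frozenset(
    {FinalStatus.ENROLLED, FinalStatus.ENROLLED_PAYMENT_FAILED,
     FinalStatus.ENROLLED_VERIFICATION_NOT_COMPLETED, FinalStatus.COMPLETED_VERIFIED})


@dataclass(frozen=True)
class InspectionOutcome:
    record_id: str
    decision: Decision
    triggered_rules: frozenset[Rule]
    flag_counts: dict[Severity, int]


@dataclass(frozen=True)
class PaymentVerification:
    """Raw answers to the post-study payment verification survey."""

    record_id: str
    completed: bool
    second_captcha_passed: bool | None = None
    recalled_condition: str | None = None
    recalled_symptom: str | None = None


def decide_baseline(flagset: FlagSet) -> InspectionOutcome:
    """Apply exclusion rules (a)-(c) to a complete flag set.

    Every rule that fires is reported, not just the first: a record can
    trigger (a), (b) and (c) simultaneously, and the audit trail should say
    so.  Excludes iff at least one rule fires.
    """
    counts = flagset.counts
    red = counts[Severity.RED]
    orange = counts[Severity.ORANGE]
    total = len(flagset)

    rules: set[Rule] = set()
    if red >= 1:
        rules.add(Rule.A_ANY_RED)
    if orange >= 2:
        rules.add(Rule.B_TWO_ORANGE)
    if total >= 4 and orange >= 1:
        rules.add(Rule.C_FOUR_FLAGS_ONE_ORANGE)

    decision = Decision.EXCLUDE if rules else Decision.INVITE
    return InspectionOutcome(flagset.record_id, decision, frozenset(rules), counts)


def verify_payment(pv: PaymentVerification, session: EDASession) -> PVResult:
    """Score the payment verification survey against the EMA session on file.

    Pass requires the second CAPTCHA plus correct recall of both the enrolled
    condition and the chosen symptom (case-insensitive).  A participant who
    never opened the survey is ``NOT_COMPLETED`` — no gift card, but their
    data are retained.
    """
    if pv.record_id != session.record_id:
        raise ConsistencyError(
            f"payment verification for {pv.record_id!r} checked against "
            f"session {session.record_id!r}")
    if not pv.completed:
        return PVResult.NOT_COMPLETED

    def norm(s: str | None) -> str:
        return (s or "").strip().lower()

    ok = (bool(pv.second_captcha_passed)
          and norm(pv.recalled_condition) == norm(session.enrolled_condition)
          and norm(pv.recalled_symptom) == norm(session.chosen_symptom))
    return PVResult.PASS if ok else PVResult.FAIL


def final_status(outcome: InspectionOutcome, registered: bool,
                 pv_result: PVResult | None = None) -> FinalStatus:
    """Collapse inspection, registration, and payment verification into one
    end state per record.

    ``pv_result=None`` for a registered participant means verification is
    pending/unscored and yields plain ``ENROLLED``.  Supplying a pv result
    for an unregistered record is a consistency error.
    """
    if not registered and pv_result is not None:
        raise ConsistencyError(
            f"payment verification supplied for unregistered record "
            f"{outcome.record_id!r}")
    if outcome.decision is Decision.EXCLUDE:
        return FinalStatus.EXCLUDED_BASELINE
    if not registered:
        return FinalStatus.INVITED_NOT_REGISTERED
    if pv_result is None:
        return FinalStatus.ENROLLED
    return {
        PVResult.PASS: FinalStatus.COMPLETED_VERIFIED,
        PVResult.FAIL: FinalStatus.ENROLLED_PAYMENT_FAILED,
        PVResult.NOT_COMPLETED: FinalStatus.ENROLLED_VERIFICATION_NOT_COMPLETED,
    }[pv_result]
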