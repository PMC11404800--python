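"""Enrollment-funnel accounting, adherence summaries, and remuneration.

Percentages are rounded half-up to one decimal, matching how enrollment
reports conventionally print conversion rates; `round()`'s banker's rounding
would disagree on exact .05 boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ConsistencyError, UndefinedRateError
from .records import EDASession, PROMPTS_PER_SESSION
from .screening import REGISTERED_STATUSES, FinalStatus

#: Loss-aversion incentive: participants start with $30 in an electronic
#: bank and lose $1 per missed prompt (28 prompts scheduled, so the floor
#: a participant can reach by missing everything is $2).
STARTING_BALANCE_USD = 30
DEDUCTION_PER_MISS_USD = 1

#: "At least 75% of prompts" with 28 scheduled means >= ceil(0.75 * 28) = 21.
ADHERENCE_THRESHOLD = math.ceil(0.75 * PROMPTS_PER_SESSION)


def percent(numerator: int, denominator: int) -> float:
    """100 * n / d, rounded half-up to one decimal place."""
    if denominator <= 0:
        raise UndefinedRateError(f"percentage undefined for denominator "
                                 f"{denominator}")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def responses_per_hour(n: int, hours: float) -> float:
    """Average intake rate, rounded half-up to one decimal place."""
    if hours <= 0:
        raise UndefinedRateError(f"rate undefined for {hours} hours")
    q = Decimal(n) / Decimal(str(hours))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RemunerationStatement:
    record_id: str
    scheduled_prompts: int
    missed: int
    amount_usd: int


def remuneration(session: EDASession) -> RemunerationStatement:
    """Compute the loss-aversion payout for a completed EMA session."""
    if len(session.prompts) != PROMPTS_PER_SESSION:
        raise ConsistencyError(
            f"session {session.record_id!r} has {len(session.prompts)} prompts, "
            f"expected {PROMPTS_PER_SESSION}")
    missed = session.n_missed
    amount = max(0, STARTING_BALANCE_USD - DEDUCTION_PER_MISS_USD * missed)
    return RemunerationStatement(session.record_id, PROMPTS_PER_SESSION,
                                 missed, amount)


@dataclass(frozen=True)
class AdherenceSummary:
    """Prompt-response adherence over a set of EMA sessions."""

    per_record: dict[str, float]  # record_id -> responded proportion
    frac_ge1: float  # fraction responding to at least one prompt
    frac_ge75: float  # fraction responding to >= 75% of prompts


def adherence(sessions: list[EDASession]) -> AdherenceSummary:
    per_record = {s.record_id: s.n_responded / len(s.prompts) for s in sessions}
    n = len(sessions)
    if n == 0:
        return AdherenceSummary({}, 0.0, 0.0)
    ge1 = sum(1 for s in sessions if s.n_responded >= 1)
    ge75 = sum(1 for s in sessions if s.n_responded >= ADHERENCE_THRESHOLD)
    return AdherenceSummary(per_record, ge1 / n, ge75 / n)


@dataclass(frozen=True)
class FunnelReport:
    """Stage counts from responses received through verified completion.

    Counts are non-increasing along
    responses_received -> passed_inspection -> registered, and
    responded_ge75pct <= responded_ge1 <= registered.
    """

    responses_received: int
    passed_inspection: int
    invited: int
    registered: int
    responded_ge1: int
    responded_ge75pct: int
    payment_completed: int
    verified: int
    responses_per_hour: float | None
    conversions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "counts": {
                "responses_received": self.responses_received,
                "passed_inspection": self.passed_inspection,
                "invited": self.invited,
                "registered": self.registered,
                "responded_ge1": self.responded_ge1,
                "responded_ge75pct": self.responded_ge75pct,
                "payment_completed": self.payment_completed,
                "verified": self.verified,
            },
            "responses_per_hour": self.responses_per_hour,
            "conversions_pct": dict(self.conversions),
        }


def build_funnel(statuses: dict[str, FinalStatus],
                 sessions: list[EDASession],
                 hours: float | None = None) -> FunnelReport:
    """Derive the enrollment funnel purely from final statuses and sessions.

    Every participant who passed inspection was invited to the EMA app, so
    ``invited == passed_inspection``; both are kept because reports name the
    stages separately.
    """
    session_ids = {s.record_id for s in sessions}
    registered_ids = {rid for rid, st in statuses.items()
                      if st in REGISTERED_STATUSES}
    orphans = session_ids - set(statuses)
    if orphans:
        raise ConsistencyError(
            f"sessions without a final status: {sorted(orphans)[:5]}")

    received = len(statuses)
    passed = sum(1 for st in statuses.values()
                 if st is not FinalStatus.EXCLUDED_BASELINE)
    registered = len(registered_ids)
    enrolled_sessions = [s for s in sessions if s.record_id in registered_ids]
    ge1 = sum(1 for s in enrolled_sessions if s.n_responded >= 1)
    ge75 = sum(1 for s in enrolled_sessions
               if s.n_responded >= ADHERENCE_THRESHOLD)
    payment_completed = sum(1 for st in statuses.values()
                            if st in (FinalStatus.COMPLETED_VERIFIED,
                                      FinalStatus.ENROLLED_PAYMENT_FAILED))
    verified = sum(1 for st in statuses.values()
                   if st is FinalStatus.COMPLETED_VERIFIED)

    conversions: dict[str, float] = {}
    if received:
        conversions["passed_inspection/responses_received"] = percent(passed, received)
    if passed:
        conversions["registered/invited"] = percent(registered, passed)
    if registered:
        conversions["responded_ge1/registered"] = percent(ge1, registered)
        conversions["responded_ge75pct/registered"] = percent(ge75, registered)
        conversions["payment_completed/registered"] = percent(payment_completed,
                                                              registered)
        conversions["verified/registered"] = percent(verified, registered)

    rate = responses_per_hour(received, hours) if hours else None
    return FunnelReport(received, passed, passed, registered, ge1, ge75,
                        payment_completed, verified, rate, conversions)


def render_funnel_markdown(report: FunnelReport) -> str:
    """Human-readable funnel table for reports."""
    d = report.to_dict()
    lines = ["# Enrollment funnel", "", "| stage | n |", "|---|---|"]
    for k, v in d["counts"].items():
        lines.append(f"| {k} | {v} |")
    if report.responses_per_hour is not None:
        lines += ["", f"Responses per hour: {report.responses_per_hour}"]
    lines += ["", "| conversion | % |", "|---|---|"]
    for k, v in d["conversions_pct"].items():
        lines.append(f"| {k} | {v} |")
    return "\n".join(lines) + "\n"
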