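"""Canonical data model for baseline survey records, EMA prompt logs, and labels.

The records here cover only the fields the data-integrity safeguards touch:
trap questions (honeypot, attention check, repeated-age consistency check),
the comorbidity checklist, Likert matrix blocks, open-text answers, the
respondent's email, and survey timing.  They are deliberately permissive on
construction — :func:`validate_record` reports invariant violations as data
rather than raising, so that malformed rows can be surfaced without aborting
a file load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import NamedTuple

LANGUAGE_ARMS = ("en-US", "it-IT", "nl-NL", "sv-SE")
CONDITIONS = ("arthritis", "asthma", "COPD", "heart failure", "diabetes")

#: Length of the comorbidity checklist on the baseline survey.
N_COMORBIDITY_ITEMS = 13

#: Plausible adult age bounds for the repeated age question.
AGE_MIN, AGE_MAX = 18, 120

#: Twice-daily prompt schedule: 14 days x 2 slots.
PROMPTS_PER_SESSION = 28
PROMPT_SLOTS = ("11:00", "19:00")

#: Prompts expire after a two-hour response window.
RESPONSE_WINDOW_SECONDS = 7200

GROUND_TRUTH_CLASSES = ("legitimate", "bot", "careless")


@dataclass(frozen=True)
class SurveyRecord:
    """One baseline survey submission."""

    record_id: str
    language_arm: str
    started_at: datetime
    submitted_at: datetime
    email: str
    conditions: tuple[str, ...]
    months_with_condition: int
    symptoms_per_week: int
    comorbidity_checklist: tuple[bool, ...]
    age_responses: tuple[int, ...]
    honeypot_response: str
    attention_response: str
    matrix_blocks: tuple[tuple[int, ...], ...]
    open_texts: tuple[str, ...]
    completion_seconds: float


@dataclass(frozen=True)
class PromptEvent:
    """A single scheduled EMA prompt and whether it was answered in time."""

    day: int  # 1..14
    slot: str  # "11:00" or "19:00", participant-local
    responded: bool
    initiation_delay_seconds: float | None = None


@dataclass(frozen=True)
class EDASession:
    """Two weeks of twice-daily prompt outcomes for one enrolled participant."""

    record_id: str
    enrolled_condition: str
    chosen_symptom: str
    prompts: tuple[PromptEvent, ...]

    @property
    def n_responded(self) -> int:
        return sum(1 for p in self.prompts if p.responded)

    @property
    def n_missed(self) -> int:
        return len(self.prompts) - self.n_responded


@dataclass(frozen=True)
class GroundTruthLabel:
    """Respondent class label; present only for synthetic cohorts."""

    record_id: str
    klass: str  # one of GROUND_TRUTH_CLASSES


class Violation(NamedTuple):
    """A single invariant violation: which field broke which rule."""

    field: str
    rule: str
    detail: str


def validate_record(record: SurveyRecord, scale_width: int = 5) -> list[Violation]:
    """Check every record invariant; return an empty list iff all hold.

    Violations are data, not errors: callers decide whether to drop, repair,
    or report the offending record.  The function is pure and depends only on
    the record itself (plus the Likert scale width in use).
    """
    v: list[Violation] = []

    if record.language_arm not in LANGUAGE_ARMS:
        v.append(Violation("language_arm", "known_arm",
                           f"{record.language_arm!r} not in {LANGUAGE_ARMS}"))

    if record.submitted_at < record.started_at:
        v.append(Violation("submitted_at", "submitted_after_started",
                           f"{record.submitted_at} < {record.started_at}"))
    else:
        elapsed = (record.submitted_at - record.started_at).total_seconds()
        if abs(elapsed - record.completion_seconds) > 1.0:
            v.append(Violation("completion_seconds", "matches_timestamps_within_1s",
                               f"timestamps give {elapsed:.1f}s, field says "
                               f"{record.completion_seconds:.1f}s"))

    if record.completion_seconds <= 0:
        v.append(Violation("completion_seconds", "positive",
                           f"{record.completion_seconds}"))

    if not record.conditions:
        v.append(Violation("conditions", "nonempty", "no condition selected"))
    for c in record.conditions:
        if c not in CONDITIONS:
            v.append(Violation("conditions", "known_condition", f"{c!r}"))

    if record.months_with_condition < 0:
        v.append(Violation("months_with_condition", "nonnegative",
                           str(record.months_with_condition)))
    if record.symptoms_per_week < 0:
        v.append(Violation("symptoms_per_week", "nonnegative",
                           str(record.symptoms_per_week)))

    if len(record.comorbidity_checklist) != N_COMORBIDITY_ITEMS:
        v.append(Violation("comorbidity_checklist",
                           f"exactly_{N_COMORBIDITY_ITEMS}_items",
                           f"got {len(record.comorbidity_checklist)}"))

    if len(record.age_responses) < 2:
        v.append(Violation("age_responses", "at_least_2_responses",
                           f"got {len(record.age_responses)}"))
    for a in record.age_responses:
        if not (AGE_MIN <= a <= AGE_MAX):
            v.append(Violation("age_responses", f"in_[{AGE_MIN},{AGE_MAX}]", str(a)))
            break

    for bi, block in enumerate(record.matrix_blocks):
        bad = [x for x in block if not (1 <= x <= scale_width)]
        if bad:
            v.append(Violation("matrix_blocks", f"values_in_[1,{scale_width}]",
                               f"block {bi}: {bad}"))

    return v


def validate_session(session: EDASession) -> list[Violation]:
    """Check EMA-session invariants (28 prompts, delay/window consistency)."""
    v: list[Violation] = []
    if len(session.prompts) != PROMPTS_PER_SESSION:
        v.append(Violation("prompts", f"exactly_{PROMPTS_PER_SESSION}_prompts",
                           f"got {len(session.prompts)}"))
    if session.enrolled_condition not in CONDITIONS:
        v.append(Violation("enrolled_condition", "known_condition",
                           f"{session.enrolled_condition!r}"))
    for i, p in enumerate(session.prompts):
        if not (1 <= p.day <= 14):
            v.append(Violation("prompts", "day_in_[1,14]", f"prompt {i}: day {p.day}"))
        if p.slot not in PROMPT_SLOTS:
            v.append(Violation("prompts", "known_slot", f"prompt {i}: {p.slot!r}"))
        if p.responded:
            if p.initiation_delay_seconds is None:
                v.append(Violation("prompts", "responded_implies_delay",
                                   f"prompt {i}"))
            elif not (0 <= p.initiation_delay_seconds <= RESPONSE_WINDOW_SECONDS):
                v.append(Violation("prompts",
                                   f"delay_in_[0,{RESPONSE_WINDOW_SECONDS}]",
                                   f"prompt {i}: {p.initiation_delay_seconds}"))
        elif p.initiation_delay_seconds is not None:
            v.append(Violation("prompts", "unanswered_implies_no_delay",
                               f"prompt {i}"))
    return v
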