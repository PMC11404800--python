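"""Data-quality flag engine.

Each check inspects one baseline survey record — two of them additionally
look across the cohort (duplicate open text, look-alike emails) — and emits
at most one flag per flag code.  Severities follow a three-level taxonomy:

* ``yellow`` — unusual response,
* ``orange`` — suspicious response,
* ``red`` — definitive indicator of a fraudulent response.

Default severities: the honeypot and attention check are red (answering a
hidden field, or ignoring an explicit instruction, is near-certain evidence
of automation or inattention so gross it invalidates the record on its own);
the consistency-style indicators (inconsistent repeated age, all 13
comorbidities selected, zig-zag matrix pattern, anomalous open text) are
orange; the softer heuristics (look-alike email, straight-lined matrix,
unusually fast completion) are yellow.  All severities and thresholds are
overridable through :class:`FlagPolicy`.

Every check is a pure function of its inputs; cohort-context checks are
symmetric (if A flags against B, then B flags against A).
"""

from __future__ import annotations

import enum
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import edlib
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .records import N_COMORBIDITY_ITEMS, SurveyRecord


class Severity(enum.IntEnum):
    """Flag severity; totally ordered yellow < orange < red."""

    YELLOW = 1
    ORANGE = 2
    RED = 3

    def __str__(self) -> str:  # noqa: D105
        return self.name.lower()

    @classmethod
    def parse(cls, s: "str | Severity") -> "Severity":
        return s if isinstance(s, Severity) else cls[s.upper()]


class FlagCode(enum.StrEnum):
    HONEYPOT = "HONEYPOT"
    ATTENTION = "ATTENTION"
    AGE_INCONSISTENT = "AGE_INCONSISTENT"
    COMORBID_EXCESS = "COMORBID_EXCESS"
    MATRIX_ZIGZAG = "MATRIX_ZIGZAG"
    MATRIX_STRAIGHTLINE = "MATRIX_STRAIGHTLINE"
    OPEN_TEXT = "OPEN_TEXT"
    EMAIL_SIMILAR = "EMAIL_SIMILAR"
    FAST_COMPLETION = "FAST_COMPLETION"


DEFAULT_SEVERITIES: dict[FlagCode, Severity] = {
    FlagCode.HONEYPOT: Severity.RED,
    FlagCode.ATTENTION: Severity.RED,
    FlagCode.AGE_INCONSISTENT: Severity.ORANGE,
    FlagCode.COMORBID_EXCESS: Severity.ORANGE,
    FlagCode.MATRIX_ZIGZAG: Severity.ORANGE,
    FlagCode.MATRIX_STRAIGHTLINE: Severity.YELLOW,
    FlagCode.OPEN_TEXT: Severity.ORANGE,
    FlagCode.EMAIL_SIMILAR: Severity.YELLOW,
    FlagCode.FAST_COMPLETION: Severity.YELLOW,
}

#: Sentinel returned when a check's precondition is not met (e.g. fewer than
#: two age responses): distinct from "evaluated and found nothing".
NOT_EVALUABLE = object()


@dataclass(frozen=True)
class Flag:
    code: FlagCode
    severity: Severity
    evidence: str
    record_id: str


@dataclass(frozen=True)
class FlagSet:
    """All flags raised on one record, with severity tallies."""

    record_id: str
    flags: tuple[Flag, ...]

    @property
    def counts(self) -> dict[Severity, int]:
        c = {Severity.YELLOW: 0, Severity.ORANGE: 0, Severity.RED: 0}
        for f in self.flags:
            c[f.severity] += 1
        return c

    def __len__(self) -> int:
        return len(self.flags)


class FlagPolicy(BaseModel):
    """Severity assignments and tunable thresholds for every check.

    The exact severity-per-criterion mapping used in manual inspection is a
    judgment call; this object makes it explicit, auditable, and overridable.
    """

    severities: dict[FlagCode, Severity] = Field(
        default_factory=lambda: dict(DEFAULT_SEVERITIES))
    #: Max tolerated spread between repeated age answers (a birthday between
    #: survey items legitimately shifts the answer by one year).
    age_tolerance_years: int = 1
    #: Minimum matrix-block length for the pattern checks to be meaningful.
    pattern_min_len: int = 4
    #: OPEN_TEXT fires when the fraction of tokens found in the embedded
    #: English word list drops below this, over at least min_dict_tokens.
    dict_ratio_cutoff: float = 0.5
    min_dict_tokens: int = 3
    #: EMAIL_SIMILAR fires at normalized edit distance <= cutoff between
    #: local parts after stripping trailing digits.
    email_distance_cutoff: float = 0.2
    #: ... or when two local parts share a stem followed by >= this many digits.
    email_digit_suffix_len: int = 4
    #: FAST_COMPLETION fires below cutoff x cohort-median completion time,
    #: provided the cohort has at least fast_min_cohort records.
    fast_completion_cutoff: float = 0.3
    fast_min_cohort: int = 5
    #: Attention-check instruction: the label the respondent was told to pick.
    attention_expected: str = "fair"
    scale_labels: tuple[str, ...] = ("poor", "fair", "good", "very good", "excellent")

    @model_validator(mode="after")
    def _check(self) -> "FlagPolicy":
        self.severities = {FlagCode(k): Severity.parse(v)
                           for k, v in self.severities.items()}
        missing = [c for c in FlagCode if c not in self.severities]
        if missing:
            raise ValueError(f"severity not mapped for: {missing}")
        if self.pattern_min_len < 3:
            raise ValueError("pattern_min_len must be >= 3")
        for name in ("dict_ratio_cutoff", "email_distance_cutoff",
                     "fast_completion_cutoff"):
            x = getattr(self, name)
            if not (0 < x <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.age_tolerance_years < 0:
            raise ValueError("age_tolerance_years must be >= 0")
        return self


@lru_cache(maxsize=1)
def english_words() -> frozenset[str]:
    """Embedded ~500-word English list backing the dictionary-ratio check."""
    text = resources.files("botscreen.data").joinpath("wordlist.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


_TOKEN_RE = re.compile(r"[a-zA-Z']+")
_TRAILING_DIGITS_RE = re.compile(r"\d+$")
_STEM_SUFFIX_RE = re.compile(r"^(.*?)(\d+)$")


def tokenize(text: str) -> list[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def strip_trailing_digits(local: str) -> str:
    return _TRAILING_DIGITS_RE.sub("", local)


def email_local_part(email: str) -> str:
    return email.split("@", 1)[0].lower()


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer length (0 for two empties)."""
    if not a and not b:
        return 0.0
    return edlib.align(a, b)["editDistance"] / max(len(a), len(b))


@dataclass(frozen=True)
class CohortContext:
    """Cohort-level lookups needed by the duplicate-text, email-similarity,
    and fast-completion checks; build once per cohort."""

    n_records: int
    median_completion_seconds: float | None
    #: per open-text item index: text -> number of records giving exactly it
    text_counts: tuple[dict[str, int], ...]
    #: (record_id, stripped local part, raw local part) per record
    email_index: tuple[tuple[str, str, str], ...]


def build_context(records: list[SurveyRecord]) -> CohortContext:
    n_items = max((len(r.open_texts) for r in records), default=0)
    text_counts: list[Counter] = [Counter() for _ in range(n_items)]
    for r in records:
        for i, t in enumerate(r.open_texts):
            if t:
                text_counts[i][t] += 1
    emails = tuple(
        (r.record_id, strip_trailing_digits(email_local_part(r.email)),
         email_local_part(r.email))
        for r in records)
    median = (statistics.median(r.completion_seconds for r in records)
              if records else None)
    return CohortContext(
        n_records=len(records),
        median_completion_seconds=median,
        text_counts=tuple(dict(c) for c in text_counts),
        email_index=emails,
    )


def _flag(code: FlagCode, policy: FlagPolicy, record_id: str, evidence: str) -> Flag:
    return Flag(code, policy.severities[code], evidence, record_id)


def check_honeypot(record: SurveyRecord, policy: FlagPolicy) -> Flag | None:
    """Any non-whitespace answer to the hidden question indicates automation."""
    answer = record.honeypot_response.strip()
    if answer:
        return _flag(FlagCode.HONEYPOT, policy, record.record_id,
                     f"hidden question answered: {answer!r}")
    return None


def check_attention(record: SurveyRecord, policy: FlagPolicy) -> Flag | None:
    """The respondent was instructed which label to pick; a different label flags."""
    expected = policy.attention_expected.lower()
    if expected not in (s.lower() for s in policy.scale_labels):
        raise ConfigurationError(
            f"attention_expected {policy.attention_expected!r} is not on the "
            f"rating scale {policy.scale_labels}")
    if record.attention_response.strip().lower() != expected:
        return _flag(FlagCode.ATTENTION, policy, record.record_id,
                     f"instructed {policy.attention_expected!r}, "
                     f"answered {record.attention_response!r}")
    return None


def check_age_consistency(record: SurveyRecord, policy: FlagPolicy):
    """Repeated "what is your age?" answers must agree within the tolerance.

    Returns :data:`NOT_EVALUABLE` when fewer than two answers are present.
    """
    ages = record.age_responses
    if len(ages) < 2:
        return NOT_EVALUABLE
    spread = max(ages) - min(ages)
    if spread > policy.age_tolerance_years:
        return _flag(FlagCode.AGE_INCONSISTENT, policy, record.record_id,
                     f"age answers {list(ages)} differ by {spread} years "
                     f"(> {policy.age_tolerance_years})")
    return None


def check_comorbid_excess(record: SurveyRecord, policy: FlagPolicy) -> Flag | None:
    """Selecting every one of the 13 comorbidity checklist items is suspicious."""
    cl = record.comorbidity_checklist
    if len(cl) == N_COMORBIDITY_ITEMS and all(cl):
        return _flag(FlagCode.COMORBID_EXCESS, policy, record.record_id,
                     f"all {N_COMORBIDITY_ITEMS} comorbidity items selected")
    return None


def _is_zigzag(block: tuple[int, ...] | list[int], min_len: int) -> bool:
    if len(block) < min_len:
        return False
    diffs = [b - a for a, b in zip(block, block[1:])]
    if any(d == 0 for d in diffs):
        return False
    if len({abs(d) for d in diffs}) != 1:
        return False
    return all(d1 * d2 < 0 for d1, d2 in zip(diffs, diffs[1:]))


def _is_straightline(block: tuple[int, ...] | list[int], min_len: int) -> bool:
    return len(block) >= min_len and len(set(block)) == 1


def check_matrix_patterns(record: SurveyRecord, policy: FlagPolicy) -> list[Flag]:
    """Detect low-effort matrix patterns: perfect zig-zag and straight-lining.

    Zig-zag means consecutive differences of constant nonzero magnitude with
    strictly alternating sign across a whole block of length >= pattern_min_len.
    """
    out: list[Flag] = []
    for bi, block in enumerate(record.matrix_blocks):
        if _is_zigzag(block, policy.pattern_min_len):
            out.append(_flag(FlagCode.MATRIX_ZIGZAG, policy, record.record_id,
                             f"block {bi} alternates perfectly: {list(block)}"))
            break
    for bi, block in enumerate(record.matrix_blocks):
        if _is_straightline(block, policy.pattern_min_len):
            out.append(_flag(FlagCode.MATRIX_STRAIGHTLINE, policy, record.record_id,
                             f"block {bi} is constant: {list(block)}"))
            break
    return out


def check_open_text(record: SurveyRecord, context: CohortContext,
                    policy: FlagPolicy) -> Flag | None:
    """Flag gibberish (low dictionary-token ratio) or verbatim duplicates.

    The dictionary-ratio test applies only to the en-US arm (the embedded
    word list is English); duplicate detection applies to every arm.
    """
    if record.language_arm == "en-US":
        for text in record.open_texts:
            tokens = tokenize(text)
            if len(tokens) >= policy.min_dict_tokens:
                hits = sum(1 for t in tokens if t in english_words())
                ratio = hits / len(tokens)
                if ratio < policy.dict_ratio_cutoff:
                    return _flag(FlagCode.OPEN_TEXT, policy, record.record_id,
                                 f"dictionary ratio {hits}/{len(tokens)} < "
                                 f"{policy.dict_ratio_cutoff}: {text!r}")
    for i, text in enumerate(record.open_texts):
        if text and i < len(context.text_counts) \
                and context.text_counts[i].get(text, 0) >= 2:
            return _flag(FlagCode.OPEN_TEXT, policy, record.record_id,
                         f"answer to item {i} duplicated verbatim across records: "
                         f"{text!r}")
    return None


def check_email_similarity(record: SurveyRecord, context: CohortContext,
                           policy: FlagPolicy) -> Flag | None:
    """Flag look-alike email addresses within the cohort.

    Two records look alike when their local parts, after stripping trailing
    digits, are within the normalized edit-distance cutoff — or when both
    match a shared stem followed by a long (>= email_digit_suffix_len) digit
    run, the signature of machine-generated account batches.  Symmetric by
    construction.
    """
    local = email_local_part(record.email)
    stem = strip_trailing_digits(local)
    cutoff = policy.email_distance_cutoff
    m = _STEM_SUFFIX_RE.match(local)
    my_long_stem = (m.group(1) if m and len(m.group(2)) >= policy.email_digit_suffix_len
                    else None)
    for other_id, other_stem, other_local in context.email_index:
        if other_id == record.record_id:
            continue
        # length pruning: |len difference| already exceeds the cutoff
        longest = max(len(stem), len(other_stem))
        if longest and abs(len(stem) - len(other_stem)) / longest > cutoff:
            dist_ok = False
        else:
            dist_ok = normalized_edit_distance(stem, other_stem) <= cutoff
        if dist_ok:
            return _flag(FlagCode.EMAIL_SIMILAR, policy, record.record_id,
                         f"{local!r} resembles {other_local!r} (record {other_id})")
        if my_long_stem is not None:
            om = _STEM_SUFFIX_RE.match(other_local)
            if om and len(om.group(2)) >= policy.email_digit_suffix_len \
                    and om.group(1) == my_long_stem:
                return _flag(FlagCode.EMAIL_SIMILAR, policy, record.record_id,
                             f"{local!r} shares stem {my_long_stem!r}+digits with "
                             f"{other_local!r} (record {other_id})")
    return None


def check_fast_completion(record: SurveyRecord, context: CohortContext,
                          policy: FlagPolicy) -> Flag | None:
    """Flag completion times far below the cohort median.

    Skipped (returns None) when the cohort is too small for the median to be
    meaningful.  Note that fast responses to EMA push notifications are
    deliberately *not* flagged anywhere in this engine: prompt initiation
    delays showed no pattern separating bots from humans.
    """
    if context.n_records < policy.fast_min_cohort \
            or context.median_completion_seconds is None:
        return None
    threshold = policy.fast_completion_cutoff * context.median_completion_seconds
    if record.completion_seconds < threshold:
        return _flag(FlagCode.FAST_COMPLETION, policy, record.record_id,
                     f"{record.completion_seconds:.0f}s < "
                     f"{policy.fast_completion_cutoff} x cohort median "
                     f"{context.median_completion_seconds:.0f}s")
    return None


def evaluate_all(record: SurveyRecord, context: CohortContext,
                 policy: FlagPolicy | None = None) -> FlagSet:
    """Run every check on one record and collect the flags raised.

    Deterministic; at most one flag per code.  The not-evaluable marker from
    the age check is treated as "no flag" here (it cannot count against the
    respondent).
    """
    policy = policy or FlagPolicy()
    flags: list[Flag] = []
    for result in (
        check_honeypot(record, policy),
        check_attention(record, policy),
        check_age_consistency(record, policy),
        check_comorbid_excess(record, policy),
    ):
        if result is not None and result is not NOT_EVALUABLE:
            flags.append(result)
    flags.extend(check_matrix_patterns(record, policy))
    for result in (
        check_open_text(record, context, policy),
        check_email_similarity(record, context, policy),
        check_fast_completion(record, context, policy),
    ):
        if result is not None:
            flags.append(result)
    return FlagSet(record.record_id, tuple(flags))


def evaluate_cohort(records: list[SurveyRecord],
                    policy: FlagPolicy | None = None) -> list[FlagSet]:
    """Evaluate every record against the cohort context, in input order."""
    policy = policy or FlagPolicy()
    context = build_context(records)
    return [evaluate_all(r, context, policy) for r in records]
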