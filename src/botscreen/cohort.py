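"""Synthetic survey cohorts with ground-truth labels.

Generates baseline survey records for three respondent classes —
``legitimate``, ``careless`` (a human who rushes but is not fraudulent), and
``bot`` — whose anomaly structure mirrors the behaviors the data-integrity
safeguards were built to catch: filled honeypots, failed attention checks,
inconsistent repeated ages, all-13 comorbidity checklists, zig-zag or
straight-lined matrix blocks, gibberish or duplicated open text, clustered
look-alike emails, and implausibly fast completion.

Two scenarios ship as defaults:

* ``pre_safeguard`` — the unprotected launch: a bot flood arriving at
  ~8.5 responses/hour for 48 hours (all in the en-US arm) with roughly two
  legitimate respondents in the same window, and naive bots whose anomalies
  fire independently at high rates.
* ``post_safeguard`` — the relaunch behind an entry CAPTCHA: 147 expected
  records of which a fraction 18/147 are residual, sophisticated bots.  A
  residual bot is one of two profiles: with probability 15/18 it slips on
  the attention check alone, otherwise it presents the combination of
  excessive comorbidity, a zig-zag matrix block, and gibberish open text.
  The entry CAPTCHA itself is not simulated; its pass rate is already folded
  into the class mix.

Everything is driven by a single integer seed: same seed + same config gives
a byte-identical cohort.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .flags import _is_straightline, _is_zigzag, english_words
from .records import (
    CONDITIONS,
    LANGUAGE_ARMS,
    N_COMORBIDITY_ITEMS,
    PROMPTS_PER_SESSION,
    RESPONSE_WINDOW_SECONDS,
    EDASession,
    GroundTruthLabel,
    PromptEvent,
    SurveyRecord,
)
from .screening import PaymentVerification

SCENARIOS = ("pre_safeguard", "post_safeguard")

#: Hours offset from UTC used to localize each arm's timestamps (summer).
ARM_UTC_OFFSET_HOURS = {"en-US": -5, "it-IT": 2, "nl-NL": 2, "sv-SE": 2}

_STUDY_START = datetime(2022, 5, 4, 8, 0, tzinfo=timezone.utc)

SYMPTOMS = ("pain", "fatigue", "shortness of breath", "stiffness",
            "swelling", "dizziness", "cough", "thirst")

# Name pools are pruned so that no two distinct first.last stems fall within
# the default 0.2 normalized-edit-distance cutoff: organic addresses are
# dissimilar *by construction*, and any look-alike pair in a cohort is there
# because the cluster generator put it there.
_FIRST_NAMES = (
    "john", "peter", "emma", "luca", "marta", "ingrid", "kees", "joost",
    "giulia", "karin", "erik", "linda", "ruth", "carlo", "femke", "david",
    "elena", "hans", "mona", "nils", "vera", "owen", "remco", "teun", "wim",
    "ylva", "zoe", "bram",
)
_LAST_NAMES = (
    "jones", "brown", "rossi", "ferrari", "esposito", "bianchi", "devries",
    "jansen", "visser", "davis", "wilson", "moore", "taylor", "romano",
    "colombo", "ricci", "meyer", "smit", "mulder", "bos", "berg", "holm",
    "dekker", "peters", "king", "scott", "adams", "clark", "larsson",
    "eriksson", "conti", "greco",
)
_DOMAINS = ("example.com", "mailbox.org", "inbox.net", "post.example")

_HONEYPOT_ANSWERS = ("USA", "United States", "Canada", "UK", "India")
_WRONG_ATTENTION = ("good", "excellent", "poor", "very good")

#: Phrases a lazy submitter pastes verbatim; duplication across records is
#: the signal (the words themselves are ordinary English).
_CANNED_TEXTS = (
    "very good survey thank you for this study",
    "i feel good and the symptoms are fine",
    "this is a good study i like to help",
)

_GIBBERISH_CONSONANTS = list("bcdfghjklmnpqrstvwxz")


class BehaviorParams(BaseModel):
    """Per-class behavioral parameters; all probabilities in [0, 1].

    With ``anomaly_mixture=False`` every anomaly fires independently at its
    own rate.  With ``anomaly_mixture=True`` (sophisticated residual bots)
    the record draws one profile: attention-check failure alone with
    probability ``attention_fail_prob``, or — with probability
    ``combo_prob`` — the {all-comorbid, zig-zag, gibberish} combination;
    otherwise it presents clean.
    """

    honeypot_fill_prob: float = 0.0
    attention_fail_prob: float = 0.0
    age_inconsistency_prob: float = 0.0
    age_mismatch_min: int = 2  # years; >= tolerance+1 so the flag can fire
    age_mismatch_max: int = 30
    all_comorbid_prob: float = 0.0
    zigzag_prob: float = 0.0
    straightline_prob: float = 0.0
    gibberish_prob: float = 0.0
    canned_text_prob: float = 0.0
    email_cluster_prob: float = 0.0
    completion_median_s: float = 540.0
    completion_sigma: float = 0.45
    registration_prob: float = 0.64
    #: Per-participant prompt-response rate ~ Beta(a, b); a zero collapses
    #: the distribution to a point mass (b=0 -> always respond, a=0 -> never).
    prompt_beta_a: float = 0.6
    prompt_beta_b: float = 0.1
    pv_completion_prob: float = 0.8
    captcha_pass_prob: float = 1.0  # second CAPTCHA at payment verification
    recall_correct_prob: float = 0.98
    arm_weights: dict[str, float] = Field(
        default_factory=lambda: {a: 0.25 for a in LANGUAGE_ARMS})
    anomaly_mixture: bool = False
    combo_prob: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "BehaviorParams":
        for name in ("honeypot_fill_prob", "attention_fail_prob",
                     "age_inconsistency_prob", "all_comorbid_prob",
                     "zigzag_prob", "straightline_prob", "gibberish_prob",
                     "canned_text_prob", "email_cluster_prob",
                     "registration_prob", "pv_completion_prob",
                     "captcha_pass_prob", "recall_correct_prob", "combo_prob"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name}={x} outside [0, 1]")
        if self.prompt_beta_a < 0 or self.prompt_beta_b < 0 \
                or self.prompt_beta_a == self.prompt_beta_b == 0:
            raise ValueError("Beta parameters must be >= 0 and not both zero")
        if self.anomaly_mixture \
                and self.attention_fail_prob + self.combo_prob > 1 + 1e-12:
            raise ValueError("mixture profile probabilities exceed 1")
        bad = set(self.arm_weights) - set(LANGUAGE_ARMS)
        if bad:
            raise ValueError(f"unknown language arm(s): {bad}")
        total = sum(self.arm_weights.values())
        if total <= 0:
            raise ValueError("arm weights must have positive sum")
        self.arm_weights = {a: self.arm_weights.get(a, 0.0) / total
                            for a in LANGUAGE_ARMS}
        return self


class CohortConfig(BaseModel):
    """Cohort-level simulation settings.

    Exactly one of ``n_total`` (fixed intake, class mix as proportions) or
    ``duration_hours`` (Poisson intake, class mix as arrivals/hour) is set.
    """

    scenario: Literal["pre_safeguard", "post_safeguard"] = "post_safeguard"
    seed: int = 0
    n_total: int | None = None
    duration_hours: float | None = None
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {"legitimate": 1.0, "careless": 0.0, "bot": 0.0})
    #: Arrival window (hours) used for timestamps in n_total mode.
    window_hours: float = 2190.0  # ~3 months
    scale_width: int = 5
    matrix_block_sizes: tuple[int, ...] = (6, 8, 6)
    n_open_text_items: int = 2

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if (self.n_total is None) == (self.duration_hours is None):
            raise ValueError("set exactly one of n_total / duration_hours")
        if self.n_total is not None and self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if self.duration_hours is not None and self.duration_hours <= 0:
            raise ValueError("duration_hours must be > 0")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class mix entries must be nonnegative")
        if self.scale_width < 2:
            raise ValueError("scale_width must be >= 2")
        return self


def default_params(scenario: str) -> tuple[CohortConfig, dict[str, BehaviorParams]]:
    """Study-condition defaults for a scenario; everything is overridable.

    pre_safeguard: 48-hour bot flood at 8.5/h (en-US only, registration
    probability 0.645) plus ~2 legitimate arrivals.  post_safeguard: 147
    expected records, residual bot fraction 18/147, residual bots failing
    the attention check with probability 15/18 and otherwise presenting the
    comorbidity/zig-zag/gibberish combination.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; valid scenarios: {SCENARIOS}")

    legitimate = BehaviorParams(
        attention_fail_prob=0.02,  # an honest slip on a buried instruction
        age_inconsistency_prob=0.01,
        straightline_prob=0.01,
        completion_median_s=540.0, completion_sigma=0.45,
        registration_prob=81 / 127,
        prompt_beta_a=0.6, prompt_beta_b=0.1,
        pv_completion_prob=65 / 81,
        captcha_pass_prob=1.0, recall_correct_prob=0.98,
        arm_weights={"en-US": 10 / 81, "it-IT": 22 / 81,
                     "nl-NL": 25 / 81, "sv-SE": 24 / 81},
    )
    careless = BehaviorParams(
        attention_fail_prob=0.3,
        age_inconsistency_prob=0.15, age_mismatch_max=8,
        all_comorbid_prob=0.05,
        zigzag_prob=0.1, straightline_prob=0.3,
        gibberish_prob=0.05,
        completion_median_s=240.0, completion_sigma=0.5,
        registration_prob=0.6,
        prompt_beta_a=2.0, prompt_beta_b=1.0,
        pv_completion_prob=0.7,
        captcha_pass_prob=1.0, recall_correct_prob=0.7,
        arm_weights={"en-US": 10 / 81, "it-IT": 22 / 81,
                     "nl-NL": 25 / 81, "sv-SE": 24 / 81},
    )

    if scenario == "pre_safeguard":
        bot = BehaviorParams(
            honeypot_fill_prob=0.6,
            attention_fail_prob=0.9,
            age_inconsistency_prob=0.4,
            all_comorbid_prob=0.3,
            zigzag_prob=0.5, straightline_prob=0.2,
            gibberish_prob=0.7, canned_text_prob=0.3,
            email_cluster_prob=0.5,
            completion_median_s=120.0, completion_sigma=0.4,
            registration_prob=0.645,
            prompt_beta_a=5.0, prompt_beta_b=2.0,
            pv_completion_prob=0.9,
            captcha_pass_prob=0.5, recall_correct_prob=0.1,
            arm_weights={"en-US": 1.0},
        )
        config = CohortConfig(
            scenario="pre_safeguard", duration_hours=48.0,
            class_mix={"bot": 8.5, "legitimate": 2 / 48, "careless": 0.0})
    else:
        bot = BehaviorParams(
            anomaly_mixture=True,
            attention_fail_prob=15 / 18, combo_prob=3 / 18,
            completion_median_s=480.0, completion_sigma=0.4,
            registration_prob=0.5,
            prompt_beta_a=5.0, prompt_beta_b=2.0,
            pv_completion_prob=0.9,
            captcha_pass_prob=0.8, recall_correct_prob=0.15,
            arm_weights={"en-US": 1.0},
        )
        config = CohortConfig(
            scenario="post_safeguard", n_total=147,
            class_mix={"bot": 18 / 147, "legitimate": 129 / 147, "careless": 0.0})

    return config, {"legitimate": legitimate, "careless": careless, "bot": bot}


def _word_pool() -> list[str]:
    return sorted(english_words())


def _legit_sentence(rng: np.random.Generator, pool: list[str]) -> str:
    n = int(rng.integers(5, 11))
    return " ".join(pool[i] for i in rng.integers(0, len(pool), size=n))


def _gibberish(rng: np.random.Generator) -> str:
    words = []
    for _ in range(int(rng.integers(3, 6))):
        k = int(rng.integers(4, 8))
        words.append("".join(
            _GIBBERISH_CONSONANTS[i]
            for i in rng.integers(0, len(_GIBBERISH_CONSONANTS), size=k)))
    return " ".join(words)


def _random_block(rng: np.random.Generator, size: int, scale: int,
                  min_len: int = 4) -> tuple[int, ...]:
    """A mixed-response block, resampled to avoid accidental patterns."""
    while True:
        block = tuple(int(x) for x in rng.integers(1, scale + 1, size=size))
        if not _is_zigzag(block, min_len) and not _is_straightline(block, min_len):
            return block


def _zigzag_block(rng: np.random.Generator, size: int, scale: int) -> tuple[int, ...]:
    lo = int(rng.integers(1, scale))
    hi = int(rng.integers(lo + 1, scale + 1))
    pair = (lo, hi) if rng.random() < 0.5 else (hi, lo)
    return tuple(pair[i % 2] for i in range(size))


class _EmailFactory:
    """Unique-by-default addresses; look-alike clusters on demand.

    Cluster addresses share a stem and differ only in a 4-digit suffix —
    the signature of machine-generated account batches.  Organic addresses
    are guaranteed unique after digit-stripping so that legitimate
    respondents never collide by construction.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used_stems: set[str] = set()
        self.tags_by_base: dict[str, list[str]] = {}
        first = _FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]
        last = _LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]
        self.cluster_stems = [f"{first}{last}", f"{last}{first}"]

    def _fresh_tag(self, base: str) -> str:
        """3-letter disambiguation tag, kept position-wise distinct from any
        earlier tag on the same base name so tagged twins stay dissimilar."""
        rng = self.rng
        prior = self.tags_by_base.setdefault(base, [])
        while True:
            tag = "".join(chr(97 + int(rng.integers(26))) for _ in range(3))
            if all(sum(a == b for a, b in zip(tag, t)) == 0 for t in prior):
                prior.append(tag)
                return tag

    def organic(self) -> str:
        rng = self.rng
        first = _FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]
        last = _LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]
        stem = f"{first}.{last}"
        if stem in self.used_stems:
            stem = f"{first}.{last}.{self._fresh_tag(stem)}"
        self.used_stems.add(stem)
        local = stem
        if rng.random() < 0.3:  # short year-style suffix, < 4 digits
            local += str(int(rng.integers(1, 100)))
        domain = _DOMAINS[int(rng.integers(len(_DOMAINS)))]
        return f"{local}@{domain}"

    def clustered(self) -> str:
        stem = self.cluster_stems[int(self.rng.integers(len(self.cluster_stems)))]
        suffix = int(self.rng.integers(1000, 10000))
        domain = _DOMAINS[int(self.rng.integers(len(_DOMAINS)))]
        return f"{stem}{suffix}@{domain}"


def _draw_events(rng: np.random.Generator, p: BehaviorParams) -> dict[str, bool]:
    if p.anomaly_mixture:
        u = rng.random()
        attention = u < p.attention_fail_prob
        combo = (not attention) and u < p.attention_fail_prob + p.combo_prob
        return {
            "honeypot": rng.random() < p.honeypot_fill_prob,
            "attention": attention,
            "age_inconsistent": rng.random() < p.age_inconsistency_prob,
            "all_comorbid": combo,
            "zigzag": combo,
            "gibberish": combo,
            "straightline": rng.random() < p.straightline_prob,
            "canned": rng.random() < p.canned_text_prob,
            "email_cluster": rng.random() < p.email_cluster_prob,
        }
    return {
        "honeypot": rng.random() < p.honeypot_fill_prob,
        "attention": rng.random() < p.attention_fail_prob,
        "age_inconsistent": rng.random() < p.age_inconsistency_prob,
        "all_comorbid": rng.random() < p.all_comorbid_prob,
        "zigzag": rng.random() < p.zigzag_prob,
        "gibberish": rng.random() < p.gibberish_prob,
        "straightline": rng.random() < p.straightline_prob,
        "canned": rng.random() < p.canned_text_prob,
        "email_cluster": rng.random() < p.email_cluster_prob,
    }


def generate_cohort(config: CohortConfig,
                    params: dict[str, BehaviorParams],
                    ) -> tuple[list[SurveyRecord], list[GroundTruthLabel]]:
    """Sample a labeled cohort; deterministic given ``config.seed``.

    Records are ordered by arrival time and ids assigned in that order.
    Requesting zero records yields an empty cohort.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    classes = sorted(config.class_mix)
    missing = [k for k in classes
               if config.class_mix[k] > 0 and k not in params]
    if missing:
        raise ConfigurationError(f"no BehaviorParams for class(es): {missing}")

    if config.n_total is not None:
        weights = np.array([config.class_mix[k] for k in classes], dtype=float)
        if weights.sum() == 0:
            counts = np.zeros(len(classes), dtype=int)
        else:
            counts = rng.multinomial(config.n_total, weights / weights.sum())
        window = config.window_hours
    else:
        counts = np.array([rng.poisson(config.class_mix[k] * config.duration_hours)
                           for k in classes])
        window = config.duration_hours

    arrivals: list[tuple[float, str]] = []
    for klass, n in zip(classes, counts):
        for t in rng.uniform(0.0, window, size=int(n)):
            arrivals.append((float(t), klass))
    arrivals.sort()

    pool = _word_pool()
    emails = _EmailFactory(rng)
    arm_names = list(LANGUAGE_ARMS)
    records: list[SurveyRecord] = []
    labels: list[GroundTruthLabel] = []

    for i, (arrival_h, klass) in enumerate(arrivals):
        p = params[klass]
        ev = _draw_events(rng, p)
        rid = f"R{i:05d}"

        arm = arm_names[int(rng.choice(len(arm_names),
                                       p=[p.arm_weights[a] for a in arm_names]))]
        tz = timezone(timedelta(hours=ARM_UTC_OFFSET_HOURS[arm]))
        started = (_STUDY_START + timedelta(hours=arrival_h)).astimezone(tz)
        completion = round(float(np.exp(np.log(p.completion_median_s)
                                        + p.completion_sigma * rng.standard_normal())), 1)
        completion = max(completion, 10.0)
        submitted = started + timedelta(seconds=completion)

        if klass == "bot":
            base_age = int(rng.integers(20, 81))
        else:
            base_age = int(np.clip(round(rng.normal(55, 15)), 20, 90))
        ages = [base_age, base_age, base_age]
        if ev["age_inconsistent"]:
            delta = int(rng.integers(p.age_mismatch_min, p.age_mismatch_max + 1))
            idx = int(rng.integers(1, 3))
            ages[idx] = base_age - delta if base_age - delta >= 18 else base_age + delta

        n_cond = int(rng.integers(1, 4)) if klass == "bot" \
            else 1 + int(rng.random() < 0.3)
        conditions = tuple(sorted(
            np.asarray(CONDITIONS)[rng.choice(len(CONDITIONS), size=n_cond,
                                              replace=False)]))
        months = int(rng.integers(3, 241))
        symptoms_wk = int(rng.integers(3, 15))

        if ev["all_comorbid"]:
            checklist = tuple([True] * N_COMORBIDITY_ITEMS)
        else:
            checklist = tuple(bool(x) for x in
                              rng.random(N_COMORBIDITY_ITEMS) < 0.08)

        sizes = config.matrix_block_sizes
        blocks = [_random_block(rng, s, config.scale_width) for s in sizes]
        special = list(rng.permutation(len(sizes)))
        if ev["zigzag"] and sizes:
            bi = special.pop()
            blocks[bi] = _zigzag_block(rng, sizes[bi], config.scale_width)
        if ev["straightline"] and special:
            bi = special.pop()
            v = int(rng.integers(1, config.scale_width + 1))
            blocks[bi] = tuple([v] * sizes[bi])

        texts = [_legit_sentence(rng, pool) for _ in range(config.n_open_text_items)]
        if ev["canned"] and texts:
            texts[0] = _CANNED_TEXTS[int(rng.integers(len(_CANNED_TEXTS)))]
        if ev["gibberish"] and texts:
            texts[-1] = _gibberish(rng)

        email = emails.clustered() if ev["email_cluster"] else emails.organic()
        honeypot = (_HONEYPOT_ANSWERS[int(rng.integers(len(_HONEYPOT_ANSWERS)))]
                    if ev["honeypot"] else "")
        attention = (_WRONG_ATTENTION[int(rng.integers(len(_WRONG_ATTENTION)))]
                     if ev["attention"] else "fair")

        records.append(SurveyRecord(
            record_id=rid, language_arm=arm,
            started_at=started, submitted_at=submitted,
            email=email, conditions=conditions,
            months_with_condition=months, symptoms_per_week=symptoms_wk,
            comorbidity_checklist=checklist,
            age_responses=tuple(ages),
            honeypot_response=honeypot, attention_response=attention,
            matrix_blocks=tuple(blocks), open_texts=tuple(texts),
            completion_seconds=completion,
        ))
        labels.append(GroundTruthLabel(rid, klass))

    return records, labels


def _prompt_rate(rng: np.random.Generator, p: BehaviorParams) -> float:
    if p.prompt_beta_b == 0:
        return 1.0
    if p.prompt_beta_a == 0:
        return 0.0
    return float(rng.beta(p.prompt_beta_a, p.prompt_beta_b))


def generate_eda(records: list[SurveyRecord],
                 labels: list[GroundTruthLabel],
                 params: dict[str, BehaviorParams],
                 seed: int) -> list[EDASession]:
    """Simulate 28-prompt EMA sessions for registered participants.

    Each participant draws a personal response rate from their class's
    Beta(a, b); each of the 28 prompts is then answered independently at
    that rate, with an initiation delay uniform on the two-hour window.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    klass_of = {l.record_id: l.klass for l in labels}
    sessions: list[EDASession] = []
    for r in records:
        p = params[klass_of[r.record_id]]
        rate = _prompt_rate(rng, p)
        prompts = []
        for day in range(1, 15):
            for slot in ("11:00", "19:00"):
                responded = bool(rng.random() < rate)
                delay = (round(float(rng.uniform(0, RESPONSE_WINDOW_SECONDS)), 1)
                         if responded else None)
                prompts.append(PromptEvent(day, slot, responded, delay))
        enrolled = r.conditions[int(rng.integers(len(r.conditions)))]
        symptom = SYMPTOMS[int(rng.integers(len(SYMPTOMS)))]
        sessions.append(EDASession(r.record_id, enrolled, symptom, tuple(prompts)))
    assert all(len(s.prompts) == PROMPTS_PER_SESSION for s in sessions)
    return sessions


def generate_payment(sessions: list[EDASession],
                     labels: list[GroundTruthLabel],
                     params: dict[str, BehaviorParams],
                     seed: int) -> list[PaymentVerification]:
    """Simulate post-study payment-verification survey responses.

    Completion, the second CAPTCHA, and condition/symptom recall each follow
    the participant's class parameters; bots recall poorly, humans well.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    klass_of = {l.record_id: l.klass for l in labels}
    out: list[PaymentVerification] = []
    for s in sessions:
        p = params[klass_of[s.record_id]]
        if rng.random() >= p.pv_completion_prob:
            out.append(PaymentVerification(s.record_id, completed=False))
            continue
        captcha = bool(rng.random() < p.captcha_pass_prob)
        if rng.random() < p.recall_correct_prob:
            cond = s.enrolled_condition
        else:
            others = [c for c in CONDITIONS if c != s.enrolled_condition]
            cond = others[int(rng.integers(len(others)))]
        if rng.random() < p.recall_correct_prob:
            sym = s.chosen_symptom
        else:
            others = [x for x in SYMPTOMS if x != s.chosen_symptom]
            sym = others[int(rng.integers(len(others)))]
        out.append(PaymentVerification(s.record_id, completed=True,
                                       second_captcha_passed=captcha,
                                       recalled_condition=cond,
                                       recalled_symptom=sym))
    return out
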