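"""Independent brute-force re-implementations of every screening predicate.

These deliberately avoid the package's own helpers (edlib, the regex
tokenizer, the diff-based zig-zag test) so that agreement between the two
routes is informative.  Everything here favors obviousness over speed.
"""

from __future__ import annotations

import string
from collections import Counter

from botscreen import SurveyRecord


def oracle_honeypot(record: SurveyRecord) -> bool:
    return record.honeypot_response.strip() != ""


def oracle_attention(record: SurveyRecord, expected: str = "fair") -> bool:
    return record.attention_response.strip().lower() != expected


def oracle_age_inconsistent(record: SurveyRecord, tolerance: int = 1) -> bool | None:
    ages = record.age_responses
    if len(ages) < 2:
        return None  # not evaluable
    return max(abs(a - b) for a in ages for b in ages) > tolerance


def oracle_comorbid_excess(record: SurveyRecord) -> bool:
    cl = record.comorbidity_checklist
    return len(cl) == 13 and sum(cl) == 13


def oracle_zigzag(record: SurveyRecord, min_len: int = 4) -> bool:
    # a constant-magnitude, sign-alternating walk is exactly an alternation
    # between two distinct values, so test that formulation instead
    for block in record.matrix_blocks:
        if len(block) < min_len:
            continue
        a, b = block[0], block[1] if len(block) > 1 else block[0]
        if a != b and all(x == (a if i % 2 == 0 else b)
                          for i, x in enumerate(block)):
            return True
    return False


def oracle_straightline(record: SurveyRecord, min_len: int = 4) -> bool:
    return any(len(b) >= min_len and all(x == b[0] for x in b)
               for b in record.matrix_blocks)


def _oracle_tokens(text: str) -> list[str]:
    out = []
    for raw in text.lower().split():
        word = raw.strip(string.punctuation + string.digits)
        if word and all(c in string.ascii_lowercase + "'" for c in word):
            out.append(word)
    return out


def oracle_open_text(record: SurveyRecord, cohort: list[SurveyRecord],
                     words: frozenset[str], cutoff: float = 0.5,
                     min_tokens: int = 3) -> bool:
    if record.language_arm == "en-US":
        for text in record.open_texts:
            tokens = _oracle_tokens(text)
            if len(tokens) >= min_tokens:
                if sum(t in words for t in tokens) / len(tokens) < cutoff:
                    return True
    for other in cohort:
        if other.record_id == record.record_id:
            continue
        for i, text in enumerate(record.open_texts):
            if text and i < len(other.open_texts) and other.open_texts[i] == text:
                return True
    return False


def dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i in range(1, len(a) + 1):
        cur = [i] + [0] * len(b)
        for j in range(1, len(b) + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[-1]


def _strip_digits(local: str) -> str:
    while local and local[-1].isdigit():
        local = local[:-1]
    return local


def _distance_lower_bound(a: str, b: str) -> int:
    # edit distance >= length difference, and each edit fixes at most two
    # units of character-multiset mismatch
    ca, cb = Counter(a), Counter(b)
    multiset = sum((ca - cb).values()) + sum((cb - ca).values())
    return max(abs(len(a) - len(b)), (multiset + 1) // 2)


def oracle_email_similar(record: SurveyRecord, cohort: list[SurveyRecord],
                         cutoff: float = 0.2, suffix_len: int = 4) -> bool:
    local = record.email.split("@")[0].lower()
    stem = _strip_digits(local)

    def long_suffix_split(s: str) -> tuple[str, str] | None:
        i = len(s)
        while i > 0 and s[i - 1].isdigit():
            i -= 1
        return (s[:i], s[i:]) if len(s) - i >= suffix_len else None

    mine = long_suffix_split(local)
    for other in cohort:
        if other.record_id == record.record_id:
            continue
        olocal = other.email.split("@")[0].lower()
        ostem = _strip_digits(olocal)
        longest = max(len(stem), len(ostem))
        if longest == 0:
            return True
        if _distance_lower_bound(stem, ostem) / longest <= cutoff \
                and dp_levenshtein(stem, ostem) / longest <= cutoff:
            return True
        if mine is not None:
            theirs = long_suffix_split(olocal)
            if theirs is not None and theirs[0] == mine[0]:
                return True
    return False


def oracle_fast_completion(record: SurveyRecord, cohort: list[SurveyRecord],
                           cutoff: float = 0.3, min_cohort: int = 5) -> bool:
    if len(cohort) < min_cohort:
        return False
    times = sorted(r.completion_seconds for r in cohort)
    n = len(times)
    median = times[n // 2] if n % 2 else (times[n // 2 - 1] + times[n // 2]) / 2
    return record.completion_seconds < cutoff * median


def oracle_decide(n_yellow: int, n_orange: int, n_red: int) -> bool:
    """Direct transcription of exclusion rules (a)-(c); True = exclude."""
    if n_red >= 1:
        return True
    if n_orange >= 2:
        return True
    if n_yellow + n_orange + n_red >= 4 and n_orange >= 1:
        return True
    return False
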