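# Methods

This note documents the screening model, the synthetic-data generator that
stands in for unavailable participant data, the numerical conventions, and
the design choices that were genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The screening procedure

The pipeline models a safeguarded online enrollment flow for a two-week,
twice-daily symptom-monitoring (EMA) study:

1. **Baseline survey** with embedded trap questions: a honeypot (hidden
   country field), an attention check ("rate this question as 'fair'"),
   a repeated age question, a 13-item comorbidity checklist, Likert matrix
   blocks, and open-text symptom questions.
2. **Flag evaluation** (`botscreen.flags`): nine checks, each emitting at
   most one flag per record with a yellow/orange/red severity taken from a
   `FlagPolicy`. Two checks need cohort context (duplicate open text,
   look-alike emails); both are symmetric. Checks are pure functions;
   the whole evaluation is deterministic.
3. **Exclusion rules** (`botscreen.screening`): exclude iff any red, or
   ≥ 2 orange, or ≥ 4 flags with ≥ 1 orange. Every firing rule is recorded,
   not just the first, so the audit trail is complete. The thresholds are
   deliberately conservative: a single soft flag never excludes.
4. **Registration and EMA**: invited records register with a class-specific
   probability; registered participants receive 28 prompts (11:00 and
   19:00 local, 14 days) with a 7,200 s response window.
5. **Payment verification**: a second CAPTCHA plus recall of the enrolled
   condition and chosen symptom. Failure excludes (rule d); *non-completion
   does not* — those participants forgo the incentive but their
   longitudinal data stand.
6. **Reporting**: enrollment funnel, adherence, loss-aversion remuneration
   (start at $30, −$1 per missed prompt, floor $0 — unreachable with 28
   prompts, where the minimum is $2), and effectiveness metrics.

### Severity defaults

Honeypot and attention are red because either is near-certain evidence of
automation or invalidating inattention, and because exclusion via a single
flag is only possible for red flags under rules (a)–(c) — consistent with
most fraud being caught by the attention check alone. The
consistency-family indicators (age inconsistency, excessive comorbidity,
zig-zag, anomalous open text) are orange: suspicious alone, conclusive in
combination (rule b). Look-alike email, straight-lining, and fast
completion are yellow: individually common among honest respondents.
The exact mapping used in any given study is a judgment call, so the
policy object externalizes it rather than hard-coding it.

### Operationalized heuristics

- **Zig-zag** is formalized as consecutive differences of constant nonzero
  magnitude and strictly alternating sign across a whole block of length
  ≥ 4 (equivalently: perfect alternation between two distinct values).
  Straight-lining (all-identical block) is the standard companion
  heuristic at yellow.
- **Open text** uses an embedded ~460-word English list. An answer with
  ≥ 3 tokens and a dictionary-token ratio < 0.5 flags; so does an answer
  byte-identical to another record's answer to the same item. The
  dictionary test applies only to the en-US arm (the list is English);
  duplicate detection applies everywhere.
- **Email similarity**: local parts are lower-cased and trailing digits
  stripped; two records flag when the stems are within normalized
  Levenshtein distance 0.2 (edlib), or when both match a shared stem
  followed by ≥ 4 digits (machine-generated account batches).
- **Fast completion** compares against 0.3 × the cohort median and is
  skipped in cohorts of fewer than 5 records. EMA prompt *initiation
  delays are deliberately not a flag*: response-speed patterns to push
  notifications did not separate bots from humans, so the engine never
  uses them.
- The age check returns a distinct *not-evaluable* marker (not "no flag")
  when fewer than two age answers exist.

## The synthetic-cohort generator

Real participant-level data from the motivating study are not available,
so the generator emulates the documented behaviors with three labeled
respondent classes. Defaults encode the study conditions and are never
tuned per run; everything is overridable.

- **`legitimate`** — honeypot never filled (humans cannot see it);
  attention failure 0.02 (an honest slip on a buried instruction, so that
  guessing-pass behavior is representable); age inconsistency 0.01;
  completion time log-normal(median 540 s, σ 0.45); registration
  probability 81/127; per-participant prompt-response rate
  ~ Beta(0.6, 0.1) — chosen so the beta-binomial over 28 prompts gives
  ≈ 98% answering ≥ 1 prompt and ≈ 81% answering ≥ 21 (the reported
  retention profile); payment-survey completion 65/81; recall accuracy
  0.98 per field; language arms weighted by the reported enrolled-country
  counts (10/81 US, 22/81 IT, 25/81 NL, 24/81 SE).
- **`careless`** — a human who rushes but is not fraudulent: attention
  failure 0.3, straight-lining 0.3, moderate age slips, honest honeypot
  and email. The class exists to make specificity testing meaningful; the
  default class mixes give it weight 0.
- **`bot`**, *pre-safeguard*: naive flood arriving ~8.5/hour for 48 h
  (Poisson), en-US arm only, registration probability 0.645, anomalies
  firing independently at high rates (honeypot 0.6, attention 0.9,
  gibberish 0.7, zig-zag 0.5, email clusters 0.5, canned duplicate text
  0.3, median completion 120 s).
- **`bot`**, *post-safeguard*: residual sophisticated bots at expected
  prevalence 18/147 in a 147-record cohort. Each draws one of two
  profiles: with probability 15/18 it slips **only** on the attention
  check; with probability 3/18 it presents the combination of excessive
  comorbidity, a zig-zag block, and gibberish open text. The two-profile
  mixture (rather than independent per-anomaly draws) is a deliberate
  design choice: it reproduces the documented post-safeguard fraud
  signature — most cases identifiable by the attention check alone, the
  remainder only by a combination of orange indicators — exactly in
  expectation, which independent draws cannot do (an attention-failing
  bot would then frequently carry extra flags, and "sole identifier"
  attribution would be systematically diluted). Records remain
  independent of each other. Post-safeguard bots otherwise present clean:
  human-like completion times and unique emails.

The entry reCAPTCHA is modeled only through the class mix/arrival rates
(the 18/147 residual prevalence is *post-gate*); simulating it explicitly
would double-count its pass rate. The `captcha_pass_prob` parameter
applies to the second CAPTCHA at payment verification.

Organic email addresses are built from name pools pruned so that no two
distinct `first.last` stems fall within the 0.2 distance cutoff: look-alike
pairs occur in a synthetic cohort only when the cluster generator creates
them (shared stem + random 4-digit suffix), which keeps the generator's
ground truth aligned with what the email heuristic measures. Open-text
answers for humans are sentences sampled from the embedded word list;
gibberish is random consonant strings; canned duplicates come from a small
pool of ordinary-English phrases so that only duplication, not vocabulary,
triggers the flag.

All sampling flows from a single integer seed through named substreams
(cohort, registration, EMA, payment), so a run is reproducible
byte-for-byte.

### What the generator does not emulate

Real covariate structure (demographics, symptom trajectories), survey
content beyond the fields the safeguards touch, adversarial adaptation
(bots learning the attention check), multilingual text (non-English arms
carry English placeholder text; only the arm label and the skip rule for
the dictionary test are modeled), IP/geolocation and device signals, and
ad-delivery dynamics. Passing tests therefore demonstrate that the rules
behave as specified and that the pipeline recovers the parameters the
cohorts were generated with — not that these parameters describe any other
study population.

## Numerical conventions

- Percentages and intake rates round **half-up to one decimal**
  (`decimal.Decimal`), matching how enrollment reports print conversions;
  banker's rounding would disagree on exact .05 boundaries. The reported
  intake-rate pair "411 in 48 hours" is quoted elsewhere as ~8.5/hour;
  411/48 = 8.5625 prints as 8.6 at one decimal, which is what
  `responses_per_hour` returns.
- "At least 75% of prompts" is implemented as ≥ ⌈0.75 × 28⌉ = 21
  responses; how fractional thresholds were handled originally is
  unstated, and the ceiling is the strict reading.
- The relaunch invalid-data count is printed both as 17/147 (11.6%) and
  18/147 (12.2%) in the source report; both identities are kept
  (`botscreen.reference`) and no adjudication is attempted. Generator
  defaults use 18/147.
- Rule (c) counts flags of **all** severities (yellows included): red
  alone already triggers (a), so (c) only adds information when soft
  flags accumulate. Whether a record can fire (b) and (c) simultaneously
  is unstated; the engine reports every firing rule.
- "Identified by a single flag" is operationalized as *sole identifier*
  (the record is excluded and carries exactly that one flag); the weaker
  counterfactual notion *decisive* (removing the flag flips
  exclude → invite) is reported alongside. Payment-verification catches
  are attributed to a `PAYMENT` pseudo-code.
- CSV cells holding lists are pipe-delimited (matrix blocks
  semicolon-delimited between blocks); free-text cells are JSON-encoded so
  any character round-trips. JSON mirrors of every format exist.
- Likert scale width defaults to 5 and is configurable; the matrix block
  sizes default to (6, 8, 6).

## Problem sizes used in validation

The calibration suite runs 200 seeds of the default post-safeguard cohort
(n = 147) for the sole-attention-fraction and bot-count checks (3
Monte-Carlo-standard-error tolerance), a 1,000-record all-legitimate
cohort for the false-positive guard (< 5% excluded), a 5,000-record
single-class cohort for anomaly-prevalence convergence (3 binomial SEs),
an exhaustive 343-case enumeration for the decision rules, and 10,000
random flag multisets for monotonicity. These sizes give comfortable
statistical resolution for the effects being checked.

## Known limitations

- The flag set reflects one study's inspection criteria; other instruments
  will need different checks (the policy object and the check registry in
  `evaluate_all` are the extension points).
- Duplicate-text detection is exact-match only; paraphrased duplicates
  pass.
- The embedded word list is small by dictionary standards; unusual but
  legitimate English (technical jargon, dialect) could be tokenized as
  gibberish in real data. Enlarging the list is a drop-in change.
- The email heuristic ignores the domain part and cannot see across
  cohorts; a fraudster using one address per domain is invisible to it.
- With the default post-safeguard profiles, every synthetic bot carries a
  detectable signature, so simulated sensitivity is near 1; real
  sophisticated fraud includes profiles with no signature at all, which
  only payment verification (or nothing) would catch.
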