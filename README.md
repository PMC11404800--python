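# botscreen

Rule-based data-integrity screening for online survey research: fraud
flags, exclusion rules, enrollment-funnel accounting, and synthetic bot
cohorts.

## The problem

Studies that recruit through social media and let participants self-enroll
are routinely flooded by bots — programs (sometimes backed by phone farms)
that "complete" surveys to harvest gift-card incentives. In a multinational
symptom-monitoring study of adults with chronic conditions (arthritis,
asthma, COPD, heart failure, diabetes) that this package models, the
unprotected launch drew 411 baseline responses in 48 hours, over 99% of
them fraudulent; 265 of the submitters went on to register for the
twice-daily mobile assessment app. After an entry CAPTCHA and a screening
protocol were added, intake normalized to 147 responses in ~3 months, of
which manual inspection flagged 18 (12.2%) — 15 of them by a single
attention-check question.

`botscreen` is a reusable implementation of that screening protocol,
plus a calibrated synthetic-cohort generator for studying how well it
works. It is aimed at research teams running online longitudinal studies
(EMA/EDA designs in particular) who need an auditable, tunable screening
pipeline — and at methodologists who want to stress-test screening rules
against simulated fraud.

## The screening model

Each baseline record is evaluated against a set of data-quality checks,
each emitting at most one **flag** with a severity from a three-level
taxonomy — *yellow* (unusual), *orange* (suspicious), *red* (definitive
indicator of fraud):

| check | default severity | fires when |
|---|---|---|
| `HONEYPOT` | red | the hidden "In what country do you live?" field is answered |
| `ATTENTION` | red | the respondent does not "rate this question as 'fair'" |
| `AGE_INCONSISTENT` | orange | repeated "What is your age?" answers differ by > 1 year |
| `COMORBID_EXCESS` | orange | all 13 comorbidity checklist items are selected |
| `MATRIX_ZIGZAG` | orange | a matrix block alternates perfectly (constant step, alternating sign) |
| `OPEN_TEXT` | orange | dictionary-token ratio < 0.5, or an answer duplicated verbatim across records |
| `EMAIL_SIMILAR` | yellow | another local-part within normalized edit distance 0.2 after digit-stripping |
| `MATRIX_STRAIGHTLINE` | yellow | a matrix block is constant |
| `FAST_COMPLETION` | yellow | completion time < 0.3 × cohort median |

A record is excluded at baseline when it has **(a)** any red flag,
**(b)** ≥ 2 orange flags, or **(c)** ≥ 4 flags with at least one orange;
an enrolled participant is additionally excluded when they **(d)** fail
the post-study payment verification (second CAPTCHA + recall of the
condition and symptom they reported on for two weeks). Severities and
thresholds are explicit in `FlagPolicy` and fully overridable.

Around the rules sit: a synthetic-cohort generator with labeled
`legitimate` / `careless` / `bot` classes and pre-/post-safeguard default
scenarios; a 28-prompt EMA adherence simulator (11:00 and 19:00 prompts for
14 days, two-hour response window); loss-aversion remuneration
($30 starting balance, −$1 per missed prompt); enrollment-funnel reporting;
and effectiveness scoring (sensitivity/specificity, per-flag attribution
including counterfactual *decisiveness* and *sole-identifier* counts).

## Worked example

```python
import botscreen as bs

config, params = bs.default_params("post_safeguard")
result = bs.run_pipeline(config, params)

print("cohort:", len(result.records), "baseline responses")
bots = sum(1 for l in result.labels if l.klass == "bot")
print("ground truth: %d bots (%.1f%%)" % (bots, 100 * bots / len(result.records)))

excluded = [rid for rid, o in result.outcomes.items()
            if o.decision is bs.Decision.EXCLUDE]
print("excluded at baseline inspection:", len(excluded))

cm = bs.confusion(result.labels, result.statuses)
print("sensitivity: %.2f  specificity: %.2f" % (cm.sensitivity, cm.specificity))

attr = bs.attribution(result.flagsets, result.statuses)
att = attr["ATTENTION"]
print("attention check: flagged=%d decisive=%d sole-identifier=%d"
      % (att.n_flagged, att.n_decisive, att.n_sole_identifier))

f = result.funnel
print("funnel: received=%d invited=%d registered=%d verified=%d"
      % (f.responses_received, f.invited, f.registered, f.verified))
```

prints

```
cohort: 147 baseline responses
ground truth: 19 bots (12.9%)
excluded at baseline inspection: 19
sensitivity: 1.00  specificity: 0.97
attention check: flagged=16 decisive=16 sole-identifier=16
funnel: received=147 invited=128 registered=84 verified=64
```

Reading it: the seed-0 post-safeguard cohort of 147 drew 19 bots; all 19
were excluded at inspection (sensitivity 1.00), with 16 of them caught by
the attention check alone (sole identifier), while 4 legitimate
respondents were lost to screening or failed payment verification
(specificity 0.97). Of the 128 invited, 84 registered for the app and 64
finished with verified payment.

The same run is available from a shell:

```sh
botscreen run-all --scenario post_safeguard --seed 0 --out-dir out/
```

which writes `records.csv`, `labels.csv`, `flags.csv`, `decisions.csv`,
`eda_log.csv`, `payment.csv`, the funnel report (`report.json`/`.md`),
`metrics.json`, and a `manifest.json` with file hashes — byte-identical
across runs with the same seed. Per-stage subcommands (`simulate`,
`flag`, `screen`, `funnel`, `evaluate`, `compare`) operate on the same
files.

## Layout

- `botscreen.records` / `botscreen.io` — data model and CSV/JSON exchange
- `botscreen.cohort` — synthetic cohorts, EMA sessions, payment surveys
- `botscreen.flags` — the flag engine and `FlagPolicy`
- `botscreen.screening` — exclusion rules (a)–(d) and final statuses
- `botscreen.funnel` — percentages, remuneration, adherence, funnel
- `botscreen.evaluation` — confusion metrics, attribution, scenario sweeps
- `botscreen.cli` — the `botscreen` command

See `docs/methods.md` for the modeling assumptions and parameter
rationale.
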