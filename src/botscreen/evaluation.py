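"""Scoring the safeguard stack against ground truth.

Positive class = invalid respondent (``bot`` or ``careless``); a record
counts as *excluded* when its final status is ``excluded_baseline`` or
``enrolled_payment_failed``.  Rates with an empty class are reported as
``None`` (not applicable), never as 0/0.

"Identified by a single flag" is operationalized as *sole identifier*: the
record was excluded and that flag is the only one it carries.  The weaker
notion *decisive* (removing only this flag would flip exclude -> invite) is
reported alongside; sole-identifier <= decisive <= flagged always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import BehaviorParams, CohortConfig, default_params
from .errors import ConsistencyError
from .flags import FlagCode, FlagPolicy, FlagSet
from .pipeline import PipelineResult, run_pipeline
from .records import GroundTruthLabel
from .screening import Decision, EXCLUDED_STATUSES, FinalStatus, decide_baseline

INVALID_CLASSES = frozenset({"bot", "careless"})

#: Pseudo-code attributing exclusions achieved only by payment verification.
PAYMENT = "PAYMENT"


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels: list[GroundTruthLabel],
              statuses: dict[str, FinalStatus]) -> ConfusionSummary:
    """Cross ground truth with final exclusion; standard rate formulas."""
    label_of = {l.record_id: l.klass for l in labels}
    missing = set(statuses) - set(label_of)
    if missing or set(label_of) - set(statuses):
        raise ConsistencyError(
            f"labels and statuses disagree on record ids "
            f"(e.g. {sorted(missing or set(label_of) - set(statuses))[:5]})")
    tp = fp = tn = fn = 0
    for rid, st in statuses.items():
        invalid = label_of[rid] in INVALID_CLASSES
        excluded = st in EXCLUDED_STATUSES
        if invalid and excluded:
            tp += 1
        elif invalid:
            fn += 1
        elif excluded:
            fp += 1
        else:
            tn += 1

    def rate(a: int, b: int) -> float | None:
        return a / (a + b) if a + b else None

    return ConfusionSummary(tp, fp, tn, fn,
                            sensitivity=rate(tp, fn), specificity=rate(tn, fp),
                            ppv=rate(tp, fp), npv=rate(tn, fn))


@dataclass(frozen=True)
class AttributionCounts:
    n_flagged: int
    n_decisive: int
    n_sole_identifier: int


def attribution(flagsets: list[FlagSet],
                statuses: dict[str, FinalStatus] | None = None,
                ) -> dict[str, AttributionCounts]:
    """Per-flag-code attribution over a cohort's flag sets.

    Decisiveness is established counterfactually: re-run the baseline
    decision with just that flag removed and see whether exclude flips to
    invite.  When *statuses* is given, exclusions reached only through
    payment verification are attributed to the :data:`PAYMENT` pseudo-code.
    Deterministic and invariant to flag evaluation order.
    """
    flagged: dict[str, int] = {c.value: 0 for c in FlagCode}
    decisive: dict[str, int] = {c.value: 0 for c in FlagCode}
    sole: dict[str, int] = {c.value: 0 for c in FlagCode}

    for fs in flagsets:
        outcome = decide_baseline(fs)
        excluded = outcome.decision is Decision.EXCLUDE
        for flag in fs.flags:
            flagged[flag.code.value] += 1
            if not excluded:
                continue
            rest = tuple(f for f in fs.flags if f.code is not flag.code)
            counterfactual = decide_baseline(replace(fs, flags=rest))
            if counterfactual.decision is Decision.INVITE:
                decisive[flag.code.value] += 1
                if len(fs.flags) == 1:
                    sole[flag.code.value] += 1

    out = {c.value: AttributionCounts(flagged[c.value], decisive[c.value],
                                      sole[c.value])
           for c in FlagCode}

    if statuses is not None:
        baseline_excluded = {fs.record_id for fs in flagsets
                             if decide_baseline(fs).decision is Decision.EXCLUDE}
        zero_flags = {fs.record_id for fs in flagsets if not fs.flags}
        pay_ids = [rid for rid, st in statuses.items()
                   if st is FinalStatus.ENROLLED_PAYMENT_FAILED]
        n_pay = len(pay_ids)
        n_dec = sum(1 for rid in pay_ids if rid not in baseline_excluded)
        n_sole = sum(1 for rid in pay_ids
                     if rid not in baseline_excluded and rid in zero_flags)
        out[PAYMENT] = AttributionCounts(n_pay, n_dec, n_sole)

    return out


def sole_attention_fraction(result: PipelineResult) -> float | None:
    """Among baseline-excluded bots, the fraction whose only flag is the
    attention check; None when no bot was excluded at baseline."""
    bots = {l.record_id for l in result.labels if l.klass == "bot"}
    excluded_bots = [fs for fs in result.flagsets
                     if fs.record_id in bots
                     and decide_baseline(fs).decision is Decision.EXCLUDE]
    if not excluded_bots:
        return None
    sole = sum(1 for fs in excluded_bots
               if len(fs.flags) == 1 and fs.flags[0].code is FlagCode.ATTENTION)
    return sole / len(excluded_bots)


def _run_metrics(config: CohortConfig, params: dict[str, BehaviorParams],
                 policy: FlagPolicy | None, seed: int) -> dict[str, float | None]:
    cfg = config.model_copy(update={"seed": seed})
    res = run_pipeline(cfg, params, policy)
    n = len(res.records)
    invalid = sum(1 for l in res.labels if l.klass in INVALID_CLASSES)
    excluded = sum(1 for st in res.statuses.values() if st in EXCLUDED_STATUSES)
    cm = confusion(res.labels, res.statuses)
    fun = res.funnel
    conv = (fun.verified / fun.responses_received
            if fun.responses_received else None)
    return {
        "n_records": n,
        "fraud_prevalence": invalid / n if n else None,
        "exclusion_rate": excluded / n if n else None,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "verified_conversion": conv,
        "sole_attention_fraction": sole_attention_fraction(res),
    }


def scenario_compare(pre: tuple[CohortConfig, dict[str, BehaviorParams]] | None = None,
                     post: tuple[CohortConfig, dict[str, BehaviorParams]] | None = None,
                     n_seeds: int = 20,
                     base_seed: int = 0,
                     policy: FlagPolicy | None = None) -> pd.DataFrame:
    """Mean +/- sd of screening metrics per scenario over paired seeds.

    The same seed list drives both scenarios (common random numbers), so a
    pre/post contrast is a paired comparison.  Returns a tidy frame indexed
    by (scenario, metric) with columns mean, sd, n_runs, and the seed range.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    scenarios = {}
    scenarios["pre_safeguard"] = pre if pre is not None \
        else default_params("pre_safeguard")
    scenarios["post_safeguard"] = post if post is not None \
        else default_params("post_safeguard")

    seeds = [base_seed + k for k in range(n_seeds)]
    rows = []
    for name, (config, params) in scenarios.items():
        per_seed: dict[str, list[float]] = {}
        for seed in seeds:
            for metric, value in _run_metrics(config, params, policy, seed).items():
                if value is not None:
                    per_seed.setdefault(metric, []).append(float(value))
        for metric, values in per_seed.items():
            arr = np.asarray(values)
            rows.append({
                "scenario": name, "metric": metric,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n_runs": len(arr),
                "seed_min": seeds[0], "seed_max": seeds[-1],
            })
    return pd.DataFrame(rows).set_index(["scenario", "metric"])
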