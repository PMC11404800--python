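"""File I/O for survey records, EMA prompt logs, and ground-truth labels.

Two interchangeable on-disk representations are supported, chosen by file
suffix: a flat UTF-8 CSV (lists within a cell pipe-delimited, matrix blocks
additionally semicolon-delimited, free-text answers JSON-encoded so they can
hold any character) and a JSON mirror with native nesting.
CSV is the exchange default because a cohort fits one greppable file with no
binary dependency; JSON exists for texts that contain the CSV delimiters.

Round-trip identity (``read(write(x)) == x`` field-for-field) is guaranteed
for valid records and is property-tested.
"""

from __future__ import annotations

import csv
import json
import warnings
from datetime import datetime
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import RowParseWarning, SchemaError
from .records import (
    EDASession,
    GroundTruthLabel,
    PromptEvent,
    SurveyRecord,
    validate_record,
)

RECORD_COLUMNS = [
    "record_id", "language_arm", "started_at", "submitted_at", "email",
    "conditions", "months_with_condition", "symptoms_per_week",
    "comorbidity_checklist", "age_responses", "honeypot_response",
    "attention_response", "matrix_blocks", "open_texts", "completion_seconds",
]
EDA_COLUMNS = ["record_id", "enrolled_condition", "chosen_symptom",
               "day", "slot", "responded", "delay_s"]
LABEL_COLUMNS = ["record_id", "klass"]

_LIST_SEP = "|"
_BLOCK_SEP = ";"


class RowError(NamedTuple):
    """A skipped input row: 1-based line number and what went wrong."""

    line: int
    message: str


def _check_header(header: Iterable[str], required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _report(err: RowError, sink: list[RowError] | None) -> None:
    if sink is not None:
        sink.append(err)
    else:
        warnings.warn(f"line {err.line}: {err.message}", RowParseWarning, stacklevel=3)


def _record_to_row(r: SurveyRecord) -> dict[str, str]:
    return {
        "record_id": r.record_id,
        "language_arm": r.language_arm,
        "started_at": r.started_at.isoformat(),
        "submitted_at": r.submitted_at.isoformat(),
        "email": r.email,
        "conditions": _LIST_SEP.join(r.conditions),
        "months_with_condition": str(r.months_with_condition),
        "symptoms_per_week": str(r.symptoms_per_week),
        "comorbidity_checklist": _LIST_SEP.join(
            "1" if x else "0" for x in r.comorbidity_checklist),
        "age_responses": _LIST_SEP.join(str(a) for a in r.age_responses),
        "honeypot_response": r.honeypot_response,
        "attention_response": r.attention_response,
        "matrix_blocks": _BLOCK_SEP.join(
            _LIST_SEP.join(str(x) for x in b) for b in r.matrix_blocks),
        # free text may contain the list delimiters (or be empty), so this
        # one cell is JSON-encoded; the CSV writer quotes it as needed
        "open_texts": json.dumps(list(r.open_texts)),
        "completion_seconds": repr(float(r.completion_seconds)),
    }


def _row_to_record(row: dict[str, str]) -> SurveyRecord:
    def split(cell: str) -> list[str]:
        return cell.split(_LIST_SEP) if cell else []

    return SurveyRecord(
        record_id=row["record_id"],
        language_arm=row["language_arm"],
        started_at=datetime.fromisoformat(row["started_at"]),
        submitted_at=datetime.fromisoformat(row["submitted_at"]),
        email=row["email"],
        conditions=tuple(split(row["conditions"])),
        months_with_condition=int(row["months_with_condition"]),
        symptoms_per_week=int(row["symptoms_per_week"]),
        comorbidity_checklist=tuple(x == "1" for x in split(row["comorbidity_checklist"])),
        age_responses=tuple(int(a) for a in split(row["age_responses"])),
        honeypot_response=row["honeypot_response"],
        attention_response=row["attention_response"],
        matrix_blocks=tuple(
            tuple(int(x) for x in split(b))
            for b in row["matrix_blocks"].split(_BLOCK_SEP) if b),
        open_texts=tuple(json.loads(row["open_texts"])),
        completion_seconds=float(row["completion_seconds"]),
    )


def _record_to_json(r: SurveyRecord) -> dict:
    return {
        "record_id": r.record_id,
        "language_arm": r.language_arm,
        "started_at": r.started_at.isoformat(),
        "submitted_at": r.submitted_at.isoformat(),
        "email": r.email,
        "conditions": list(r.conditions),
        "months_with_condition": r.months_with_condition,
        "symptoms_per_week": r.symptoms_per_week,
        "comorbidity_checklist": list(r.comorbidity_checklist),
        "age_responses": list(r.age_responses),
        "honeypot_response": r.honeypot_response,
        "attention_response": r.attention_response,
        "matrix_blocks": [list(b) for b in r.matrix_blocks],
        "open_texts": list(r.open_texts),
        "completion_seconds": float(r.completion_seconds),
    }


def _json_to_record(d: dict) -> SurveyRecord:
    return SurveyRecord(
        record_id=d["record_id"],
        language_arm=d["language_arm"],
        started_at=datetime.fromisoformat(d["started_at"]),
        submitted_at=datetime.fromisoformat(d["submitted_at"]),
        email=d["email"],
        conditions=tuple(d["conditions"]),
        months_with_condition=int(d["months_with_condition"]),
        symptoms_per_week=int(d["symptoms_per_week"]),
        comorbidity_checklist=tuple(bool(x) for x in d["comorbidity_checklist"]),
        age_responses=tuple(int(a) for a in d["age_responses"]),
        honeypot_response=d["honeypot_response"],
        attention_response=d["attention_response"],
        matrix_blocks=tuple(tuple(int(x) for x in b) for b in d["matrix_blocks"]),
        open_texts=tuple(d["open_texts"]),
        completion_seconds=float(d["completion_seconds"]),
    )


def read_records(path: str | Path, scale_width: int = 5,
                 error_sink: list[RowError] | None = None) -> list[SurveyRecord]:
    """Read baseline survey records from CSV or JSON (by suffix).

    Rows that cannot be parsed, or that violate the record invariants, are
    skipped and reported — appended to *error_sink* when given, emitted as
    :class:`RowParseWarning` otherwise.  File order is preserved.  A missing
    required column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = []
        for i, d in enumerate(json.loads(path.read_text(encoding="utf-8"))):
            try:
                rec = _json_to_record(d)
            except (KeyError, TypeError, ValueError) as exc:
                _report(RowError(i + 1, f"unparseable entry: {exc}"), error_sink)
                continue
            bad = validate_record(rec, scale_width)
            if bad:
                _report(RowError(i + 1, "; ".join(
                    f"{w.field}: {w.rule} ({w.detail})" for w in bad)), error_sink)
                continue
            records.append(rec)
        return records

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, RECORD_COLUMNS, path)
        records = []
        for row in reader:
            line = reader.line_num
            try:
                rec = _row_to_record(row)
            except (KeyError, TypeError, ValueError) as exc:
                _report(RowError(line, f"unparseable row: {exc}"), error_sink)
                continue
            bad = validate_record(rec, scale_width)
            if bad:
                _report(RowError(line, "; ".join(
                    f"{w.field}: {w.rule} ({w.detail})" for w in bad)), error_sink)
                continue
            records.append(rec)
    return records


def write_records(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write records to CSV or JSON (by suffix); an empty list yields header only."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([_record_to_json(r) for r in records], indent=1),
                        encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RECORD_COLUMNS,
                                quoting=csv.QUOTE_MINIMAL)
        writer.writeheader()
        for r in records:
            writer.writerow(_record_to_row(r))


def write_eda(sessions: Iterable[EDASession], path: str | Path) -> None:
    """Write EMA sessions in long format: one row per scheduled prompt."""
    path = Path(path)
    sessions = list(sessions)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([
            {"record_id": s.record_id, "enrolled_condition": s.enrolled_condition,
             "chosen_symptom": s.chosen_symptom,
             "prompts": [{"day": p.day, "slot": p.slot, "responded": p.responded,
                          "delay_s": p.initiation_delay_seconds}
                         for p in s.prompts]}
            for s in sessions], indent=1), encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EDA_COLUMNS)
        for s in sessions:
            for p in s.prompts:
                writer.writerow([
                    s.record_id, s.enrolled_condition, s.chosen_symptom,
                    p.day, p.slot, "1" if p.responded else "0",
                    "" if p.initiation_delay_seconds is None
                    else repr(float(p.initiation_delay_seconds)),
                ])


def read_eda(path: str | Path) -> list[EDASession]:
    """Read EMA sessions; consecutive rows sharing record_id form one session."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return [
            EDASession(
                record_id=d["record_id"],
                enrolled_condition=d["enrolled_condition"],
                chosen_symptom=d["chosen_symptom"],
                prompts=tuple(PromptEvent(p["day"], p["slot"], p["responded"],
                                          p["delay_s"]) for p in d["prompts"]))
            for d in json.loads(path.read_text(encoding="utf-8"))
        ]
    sessions: list[EDASession] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, EDA_COLUMNS, path)
        current_id: str | None = None
        meta: tuple[str, str] | None = None
        prompts: list[PromptEvent] = []

        def flush() -> None:
            if current_id is not None:
                sessions.append(EDASession(current_id, meta[0], meta[1], tuple(prompts)))

        for row in reader:
            if row["record_id"] != current_id:
                flush()
                current_id = row["record_id"]
                meta = (row["enrolled_condition"], row["chosen_symptom"])
                prompts = []
            responded = row["responded"] == "1"
            delay = float(row["delay_s"]) if row["delay_s"] else None
            prompts.append(PromptEvent(int(row["day"]), row["slot"], responded, delay))
        flush()
    return sessions


def write_labels(labels: Iterable[GroundTruthLabel], path: str | Path) -> None:
    path = Path(path)
    labels = list(labels)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            [{"record_id": l.record_id, "klass": l.klass} for l in labels], indent=1),
            encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABEL_COLUMNS)
        for l in labels:
            writer.writerow([l.record_id, l.klass])


def read_labels(path: str | Path) -> list[GroundTruthLabel]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return [GroundTruthLabel(d["record_id"], d["klass"])
                for d in json.loads(path.read_text(encoding="utf-8"))]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, LABEL_COLUMNS, path)
        return [GroundTruthLabel(row["record_id"], row["klass"]) for row in reader]
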