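"""Cohort data model and CSV readers/writers.

Two bodies of data make up a cohort:

* **assessments** — one supervised assessment per participant per timepoint
  (``baseline`` at program start, ``final`` about five months later), holding
  the battery scores after best-of-trial reduction;
* **daily** — the self-reported daily questionnaire, one encoded answer per
  (participant, day, question, administration slot).

File schemas (UTF-8, "." decimal):

* ``assessments.csv``: ``participant_id, timepoint`` then one column per
  variable trial (``chair_sit_reach_1, chair_sit_reach_2`` for two-trial
  variables, plain ``moca`` for single-trial ones).  Empty cells are missing.
* ``daily.csv``: long format ``participant_id, day_index, slot, question_id,
  answer`` with raw labels or counts in ``answer``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .specs import (
    AssessmentVariableSpec,
    QuestionSpec,
    best_of,
    decode_answer,
    default_question_specs,
    default_variable_specs,
    encode_answer,
)

BASELINE = "baseline"
FINAL = "final"
TIMEPOINTS = (BASELINE, FINAL)

#: Default study window, in days.
DEFAULT_N_DAYS = 150


@dataclass
class AssessmentRecord:
    participant_id: str
    timepoint: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise DataError(
                f"participant {self.participant_id!r}: timepoint must be one of "
                f"{TIMEPOINTS}, got {self.timepoint!r}"
            )
        for var, val in self.values.items():
            if not math.isfinite(val):
                raise DataError(
                    f"participant {self.participant_id!r}, variable {var!r}: "
                    f"non-finite value {val!r}"
                )


@dataclass
class DailyRecord:
    """Answers for one participant on one day, keyed (answer_key, slot)."""

    participant_id: str
    day_index: int
    answers: dict[tuple[str, int], int] = field(default_factory=dict)


@dataclass
class CohortDataset:
    question_specs: dict[str, QuestionSpec]
    variable_specs: dict[str, AssessmentVariableSpec]
    assessments: list[AssessmentRecord]
    daily: list[DailyRecord]
    n_days: int = DEFAULT_N_DAYS

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers ------------------------------------------------------

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.assessments:
            seen.setdefault(rec.participant_id, None)
        for rec in self.daily:
            seen.setdefault(rec.participant_id, None)
        return list(seen)

    def assessment(self, participant_id: str, timepoint: str) -> AssessmentRecord | None:
        for rec in self.assessments:
            if rec.participant_id == participant_id and rec.timepoint == timepoint:
                return rec
        return None

    def validate(self) -> None:
        key_to_spec = answer_key_index(self.question_specs)
        seen: set[tuple[str, str]] = set()
        by_tp: dict[str, set[str]] = {tp: set() for tp in TIMEPOINTS}
        for rec in self.assessments:
            pair = (rec.participant_id, rec.timepoint)
            if pair in seen:
                raise DataError(f"duplicate assessment for {pair}")
            seen.add(pair)
            by_tp[rec.timepoint].add(rec.participant_id)
            for var in rec.values:
                if var not in self.variable_specs:
                    raise DataError(
                        f"participant {rec.participant_id!r}: unknown assessment "
                        f"variable {var!r}"
                    )
        orphans = by_tp[FINAL] - by_tp[BASELINE]
        if orphans:
            raise DataError(
                f"participants with a final but no baseline assessment: {sorted(orphans)}"
            )
        for rec in self.daily:
            if not 0 <= rec.day_index < self.n_days:
                raise DataError(
                    f"participant {rec.participant_id!r}: day_index {rec.day_index} "
                    f"outside the 0..{self.n_days - 1} study window"
                )
            for (key, slot), idx in rec.answers.items():
                spec = key_to_spec.get(key)
                if spec is None:
                    raise DataError(f"unknown question/answer key {key!r}")
                if not 0 <= slot < spec.administrations_per_day:
                    raise DataError(
                        f"question {key!r}: slot {slot} invalid for "
                        f"{spec.administrations_per_day} administration(s) per day"
                    )
                if not 0 <= idx <= spec.max_index:
                    raise DataError(
                        f"question {key!r}: encoded index {idx} outside "
                        f"0..{spec.max_index}"
                    )


def answer_key_index(question_specs: dict[str, QuestionSpec]) -> dict[str, QuestionSpec]:
    """Map answer_key -> a representative spec (shared keys must agree on scale)."""
    index: dict[str, QuestionSpec] = {}
    for spec in question_specs.values():
        prev = index.get(spec.answer_key)
        if prev is None:
            index[spec.answer_key] = spec
        elif (prev.scale, prev.max_count) != (spec.scale, spec.max_count):
            raise DataError(
                f"questions {prev.id!r} and {spec.id!r} share answer_key "
                f"{spec.answer_key!r} but disagree on the answer scale"
            )
    return index


# -- CSV readers -------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in frame.columns:
            raise DataError(f"{path}: missing required column {col!r}")


def read_assessment_csv(
    path, variable_specs: dict[str, AssessmentVariableSpec] | None = None
) -> list[AssessmentRecord]:
    """Read an assessment table, applying best-of-trial reduction per variable."""
    variable_specs = variable_specs or default_variable_specs()
    frame = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(frame, ["participant_id", "timepoint"], path)
    records: list[AssessmentRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in frame.iterrows():
        pid, tp = str(row["participant_id"]), str(row["timepoint"])
        if (pid, tp) in seen:
            raise DataError(f"{path}: duplicate (participant, timepoint) = ({pid}, {tp})")
        seen.add((pid, tp))
        values: dict[str, float] = {}
        for var, spec in variable_specs.items():
            cols = [var] if spec.repeats == 1 else [f"{var}_{i}" for i in (1, 2)]
            trials = [
                float(row[c])
                for c in cols
                if c in frame.columns and pd.notna(row[c])
            ]
            if trials:
                values[var] = best_of(trials, spec)
        records.append(AssessmentRecord(pid, tp, values))
    return records


def read_daily_csv(
    path,
    question_specs: dict[str, QuestionSpec] | None = None,
    n_days: int = DEFAULT_N_DAYS,
) -> list[DailyRecord]:
    """Read the long-format daily questionnaire table, encoding raw answers.

    ``question_id`` may be either a question id or its shared answer_key.
    """
    question_specs = question_specs or default_question_specs()
    key_index = answer_key_index(question_specs)
    frame = pd.read_csv(path, dtype={"participant_id": str, "question_id": str})
    _require_columns(frame, ["participant_id", "day_index", "slot", "question_id", "answer"], path)
    by_day: dict[tuple[str, int], DailyRecord] = {}
    for _, row in frame.iterrows():
        pid = str(row["participant_id"])
        day = int(row["day_index"])
        if not 0 <= day < n_days:
            raise DataError(
                f"{path}: participant {pid!r} day_index {day} outside 0..{n_days - 1}"
            )
        qid = str(row["question_id"])
        spec = question_specs.get(qid) or key_index.get(qid)
        if spec is None:
            raise DataError(f"{path}: unknown question_id {qid!r}")
        slot = int(row["slot"])
        if not 0 <= slot < spec.administrations_per_day:
            raise DataError(
                f"{path}: question {qid!r} slot {slot} invalid for "
                f"{spec.administrations_per_day} administration(s) per day"
            )
        raw = row["answer"]
        if pd.isna(raw):
            continue  # missing answer: recorded as absent, never as zero
        if spec.max_count is not None and not isinstance(raw, str):
            raw = int(raw)
        idx = encode_answer(raw, spec)
        rec = by_day.setdefault((pid, day), DailyRecord(pid, day))
        cell = (spec.answer_key, slot)
        if cell in rec.answers and rec.answers[cell] != idx:
            raise DataError(
                f"{path}: conflicting answers for participant {pid!r}, day {day}, "
                f"question {spec.answer_key!r}, slot {slot}"
            )
        rec.answers[cell] = idx
    return list(by_day.values())


def read_cohort(
    assessments_path,
    daily_path,
    question_specs: dict[str, QuestionSpec] | None = None,
    variable_specs: dict[str, AssessmentVariableSpec] | None = None,
    n_days: int = DEFAULT_N_DAYS,
) -> CohortDataset:
    question_specs = question_specs or default_question_specs()
    variable_specs = variable_specs or default_variable_specs()
    return CohortDataset(
        question_specs=question_specs,
        variable_specs=variable_specs,
        assessments=read_assessment_csv(assessments_path, variable_specs),
        daily=read_daily_csv(daily_path, question_specs, n_days),
        n_days=n_days,
    )


# -- CSV writers -------------------------------------------------------------

def write_assessment_csv(
    records: list[AssessmentRecord],
    variable_specs: dict[str, AssessmentVariableSpec],
    path,
) -> None:
    columns = ["participant_id", "timepoint"]
    for var, spec in variable_specs.items():
        columns += [var] if spec.repeats == 1 else [f"{var}_1", f"{var}_2"]
    rows = []
    for rec in sorted(records, key=lambda r: (r.participant_id, r.timepoint)):
        row: dict[str, object] = {"participant_id": rec.participant_id, "timepoint": rec.timepoint}
        for var, spec in variable_specs.items():
            if var in rec.values:
                # Post-reduction value goes in the first trial column.
                col = var if spec.repeats == 1 else f"{var}_1"
                row[col] = rec.values[var]
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_daily_csv(
    records: list[DailyRecord],
    question_specs: dict[str, QuestionSpec],
    path,
) -> None:
    key_index = answer_key_index(question_specs)
    rows = []
    for rec in sorted(records, key=lambda r: (r.participant_id, r.day_index)):
        for (key, slot), idx in sorted(rec.answers.items()):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "day_index": rec.day_index,
                    "slot": slot,
                    "question_id": key,
                    "answer": decode_answer(idx, key_index[key]),
                }
            )
    pd.DataFrame(
        rows, columns=["participant_id", "day_index", "slot", "question_id", "answer"]
    ).to_csv(path, index=False)


def write_summary_json(dataset: CohortDataset, path) -> None:
    participants = dataset.participants
    summary = {
        "n_participants": len(participants),
        "n_days": dataset.n_days,
        "n_assessments": len(dataset.assessments),
        "n_daily_records": len(dataset.daily),
        "n_questions": len(dataset.question_specs),
        "n_variables": len(dataset.variable_specs),
        "participants": sorted(participants),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
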