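"""Daily activity scoring.

The daily activity level of a coaching dimension is the weighted sum of the
encoded answers of its questions,

    activity(day) = sum_i  w_i * a_i ,

where ``w_i`` is the expert weight of question *i* (negative weights mark
detrimental behaviours: added salt/sugar, alcohol) and ``a_i`` the encoded
answer index.  Thrice-daily questions contribute one term per administration,
i.e. a day's total rather than its average.  Missing answers contribute 0 and
lower the cell's completeness; days with no record at all are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CohortDataset, DailyRecord
from .dimensions import DIMENSIONS, check_dimension
from .errors import DataError
from .specs import QuestionSpec, questions_for_dimension


@dataclass(frozen=True)
class DailyDimensionScore:
    participant_id: str
    day_index: int
    dimension: str
    value: float
    completeness: float


def _dimension_cells(
    question_specs: dict[str, QuestionSpec], dimension: str
) -> list[tuple[str, int, float]]:
    """(answer_key, slot, weight) cells making up one dimension's daily score."""
    cells = []
    for spec in questions_for_dimension(question_specs, dimension):
        for slot in spec.slots:
            cells.append((spec.answer_key, slot, float(spec.weight)))
    return cells


def daily_dimension_score(
    record: DailyRecord,
    question_specs: dict[str, QuestionSpec],
    dimension: str,
) -> DailyDimensionScore:
    """Score one participant-day for one dimension (weighted answer sum)."""
    check_dimension(dimension)
    cells = _dimension_cells(question_specs, dimension)
    value = 0.0
    answered = 0
    for key, slot, weight in cells:
        idx = record.answers.get((key, slot))
        if idx is not None:
            value += weight * idx
            answered += 1
    completeness = answered / len(cells) if cells else 0.0
    return DailyDimensionScore(
        record.participant_id, record.day_index, dimension, value, completeness
    )


class ActivityMatrix:
    """participant x day x dimension activity scores with per-cell completeness.

    Stored as one (participants, days) float array per dimension; NaN marks
    a missing day (no record, or completeness below the configured floor).
    """

    def __init__(
        self,
        participants: list[str],
        n_days: int,
        values: dict[str, np.ndarray],
        completeness: dict[str, np.ndarray],
    ) -> None:
        self.participants = list(participants)
        self.n_days = n_days
        self.values = values
        self.completeness = completeness
        self._row = {pid: i for i, pid in enumerate(self.participants)}

    @classmethod
    def from_dataset(
        cls, dataset: CohortDataset, completeness_floor: float = 0.0
    ) -> "ActivityMatrix":
        """Score every recorded day.

        ``completeness_floor`` drops days whose fraction of answered questions
        (for that dimension) falls below it; the default 0 keeps every
        recorded day, with unanswered questions contributing 0.
        """
        participants = dataset.participants
        row = {pid: i for i, pid in enumerate(participants)}
        shape = (len(participants), dataset.n_days)
        values = {dim: np.full(shape, np.nan) for dim in DIMENSIONS}
        completeness = {dim: np.full(shape, np.nan) for dim in DIMENSIONS}
        cells = {dim: _dimension_cells(dataset.question_specs, dim) for dim in DIMENSIONS}
        for rec in dataset.daily:
            i = row[rec.participant_id]
            for dim in DIMENSIONS:
                value = 0.0
                answered = 0
                for key, slot, weight in cells[dim]:
                    idx = rec.answers.get((key, slot))
                    if idx is not None:
                        value += weight * idx
                        answered += 1
                total = len(cells[dim])
                comp = answered / total if total else 0.0
                if comp >= completeness_floor and total:
                    values[dim][i, rec.day_index] = value
                completeness[dim][i, rec.day_index] = comp
        return cls(participants, dataset.n_days, values, completeness)

    def _check_participant(self, participant_id: str) -> int:
        if participant_id not in self._row:
            raise DataError(f"unknown participant {participant_id!r}")
        return self._row[participant_id]

    def activity_series(self, participant_id: str, dimension: str) -> pd.Series:
        """One participant's day-indexed activity series (NaN = missing day)."""
        check_dimension(dimension)
        i = self._check_participant(participant_id)
        return pd.Series(
            self.values[dimension][i],
            index=pd.RangeIndex(self.n_days, name="day_index"),
            name=f"{participant_id}/{dimension}",
        )

    def mean_activity(self, participant_id: str, dimension: str) -> float:
        """Mean over recorded days (NaN when the participant has no days)."""
        check_dimension(dimension)
        i = self._check_participant(participant_id)
        row = self.values[dimension][i]
        if np.all(np.isnan(row)):
            return float("nan")
        return float(np.nanmean(row))

    def to_long_frame(self) -> pd.DataFrame:
        """Long export: participant_id, day_index, dimension, value, completeness."""
        rows = []
        for dim in DIMENSIONS:
            vals, comp = self.values[dim], self.completeness[dim]
            for i, pid in enumerate(self.participants):
                recorded = ~np.isnan(comp[i])
                for d in np.nonzero(recorded)[0]:
                    rows.append((pid, int(d), dim, vals[i, d], comp[i, d]))
        return pd.DataFrame(
            rows, columns=["participant_id", "day_index", "dimension", "value", "completeness"]
        )
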