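"""System Usability Scale (SUS) arithmetic and questionnaire summaries.

The SUS is a 10-item questionnaire (answers 1-5; odd items positively
phrased, even items negatively phrased) scored per subject as

    score = 2.5 * [ sum_odd (a - 1)  +  sum_even (5 - a) ]   in [0, 100].

Published answer tables are often sorted per question to prevent subject
re-identification, which destroys the per-subject pairing.  The *mean* SUS
score survives: it is linear in the per-question means, so it can be
recovered exactly from the sorted multisets (``sus_mean_from_multisets``).
The across-subject standard deviation cannot.

``NINE_RATER_SUS_ANSWERS`` ships the per-question multisets from a
nine-subject usability evaluation of an older-adult coaching-analytics
dashboard, as a worked example and regression fixture; the companion
demographic and feature-questionnaire tables are included alongside.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import DataError

N_ITEMS = 10

#: Per-question answer multisets (items Q1..Q10, nine raters each, sorted
#: decreasingly; subject pairing unknown).
NINE_RATER_SUS_ANSWERS: dict[int, tuple[int, ...]] = {
    1: (5, 4, 4, 4, 4, 4, 4, 3, 3),
    2: (4, 4, 3, 2, 2, 2, 2, 2, 1),
    3: (5, 5, 4, 4, 4, 4, 4, 3, 3),
    4: (4, 4, 3, 3, 3, 2, 2, 2, 1),
    5: (5, 5, 5, 4, 4, 4, 4, 4, 3),
    6: (3, 3, 2, 2, 2, 2, 1, 1, 1),
    7: (4, 4, 4, 3, 3, 3, 3, 3, 3),
    8: (2, 2, 2, 2, 2, 1, 1, 1, 1),
    9: (4, 4, 4, 4, 4, 4, 4, 3, 2),
    10: (5, 3, 2, 2, 2, 2, 1, 1, 1),
}

#: Per-subject SUS totals reported alongside the multisets (sorted; used only
#: to cross-check the multiset-derived mean).
NINE_RATER_SUS_SUBJECT_SCORES: tuple[float, ...] = (
    82.5, 77.5, 77.5, 75.0, 72.5, 72.5, 72.5, 62.5, 47.5,
)

#: Rater exposure to digital technologies (sorted answers per question).
NINE_RATER_DEMOGRAPHICS: dict[str, tuple[float, ...]] = {
    "computer_hours_per_week": (60, 60, 50, 50, 50, 40, 35, 30, 10),
    "computer_literacy": (5, 4, 4, 4, 4, 4, 3, 3, 3),
    "visual_analytics_familiarity": (4, 4, 4, 3, 3, 3, 3, 2, 2),
}

#: Tool-specific feature questionnaire (1-5 agreement, sorted per question).
NINE_RATER_FEATURE_ANSWERS: dict[str, tuple[int, ...]] = {
    "grouping_easy_to_understand": (5, 5, 5, 5, 4, 4, 4, 4, 4),
    "graphs_differentiate_groups": (5, 5, 5, 5, 4, 4, 4, 4, 2),
    "evolution_graphs_valuable": (5, 5, 4, 4, 4, 4, 4, 4, 4),
    "would_use_daily": (5, 5, 5, 4, 4, 3, 3, 3, 2),
}


def _check_answer(a, item: int) -> int:
    ai = int(a)
    if ai != a or not 1 <= ai <= 5:
        raise DataError(f"SUS item {item}: answer must be an integer in 1..5, got {a!r}")
    return ai


def sus_score(answers) -> float:
    """SUS score of one subject's 10-item answer vector (odd items positive)."""
    answers = list(answers)
    if len(answers) != N_ITEMS:
        raise DataError(f"SUS needs exactly {N_ITEMS} answers, got {len(answers)}")
    total = 0
    for item, a in enumerate(answers, start=1):
        a = _check_answer(a, item)
        total += (a - 1) if item % 2 == 1 else (5 - a)
    return 2.5 * total


def sus_mean_from_multisets(multisets: dict[int, tuple[int, ...]] | list) -> float:
    """Mean SUS score from per-question answer multisets (pairing unknown).

    Exact: the mean score is 2.5*[sum_odd (mean_q - 1) + sum_even (5 - mean_q)],
    invariant to how answers are paired into subjects.
    """
    if isinstance(multisets, dict):
        items = [multisets[i] for i in range(1, N_ITEMS + 1)]
    else:
        items = list(multisets)
    if len(items) != N_ITEMS:
        raise DataError(f"SUS needs {N_ITEMS} answer multisets, got {len(items)}")
    sizes = {len(m) for m in items}
    if len(sizes) != 1:
        raise DataError(f"answer multisets have unequal sizes: {sorted(sizes)}")
    total = 0.0
    for item, answers in enumerate(items, start=1):
        m = sum(_check_answer(a, item) for a in answers) / len(answers)
        total += (m - 1) if item % 2 == 1 else (5 - m)
    return 2.5 * total


def summary_stats(values) -> tuple[float, float]:
    """(mean, sample sd); sd is NaN for a single value (flagged undefined)."""
    values = [float(v) for v in values]
    if not values:
        raise DataError("summary_stats: empty value list")
    mean = sum(values) / len(values)
    if len(values) == 1:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def read_sus_csv(path) -> dict:
    """Read SUS answers from CSV, auto-detecting the layout.

    Per-subject layout: columns ``subject_id, q1..q10`` -> returns
    ``{"layout": "subjects", "scores": {subject: score}, "mean": ...}``.
    Per-question layout: columns ``question_id, a1..aN`` (pairing unknown) ->
    returns ``{"layout": "questions", "mean": ...}``.
    """
    frame = pd.read_csv(path)
    cols = [c.strip().lower() for c in frame.columns]
    frame.columns = cols
    if "subject_id" in cols:
        qcols = [f"q{i}" for i in range(1, N_ITEMS + 1)]
        for c in qcols:
            if c not in cols:
                raise DataError(f"{path}: missing required column {c!r}")
        scores = {
            str(row["subject_id"]): sus_score([row[c] for c in qcols])
            for _, row in frame.iterrows()
        }
        mean, _sd = summary_stats(list(scores.values()))
        return {"layout": "subjects", "scores": scores, "mean": mean}
    if "question_id" in cols:
        acols = [c for c in cols if c.startswith("a")]
        if not acols:
            raise DataError(f"{path}: per-question layout needs answer columns a1..aN")
        multisets = {}
        for _, row in frame.iterrows():
            q = int(str(row["question_id"]).lstrip("qQ"))
            multisets[q] = tuple(int(row[c]) for c in acols if pd.notna(row[c]))
        return {"layout": "questions", "mean": sus_mean_from_multisets(multisets)}
    raise DataError(
        f"{path}: expected a 'subject_id' (per-subject) or 'question_id' "
        f"(per-question) column"
    )
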