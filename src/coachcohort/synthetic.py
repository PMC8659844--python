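"""Synthetic cohort generator with exported ground truth.

Emulates the structure of the study data — ~68 older adults followed for
~150 days, a baseline and a final assessment on the standard battery, and the
daily four-dimension questionnaire — so that every pipeline stage is testable
without the original cohort.  The generator plants:

* **groups** with baseline assessment shifts (in robust-sd units, applied in
  each variable's "better" direction) and per-dimension daily activity levels;
* **outlier participants** shifted far from everyone in random directions;
* **activity/improvement effects**: within a chosen group, a coefficient
  ``beta`` links a participant's realized mean activity in one dimension
  (standardized within the group) to their final-minus-baseline change in
  another — the "kept their nutrition up, improved physically" pattern;
* **daily noise**: an AR(1) process around each participant's activity level,
  plus a persistent per-participant level offset, inverted day by day into
  valid answer indices (greedy allocation by descending |weight|; only the
  resulting weighted-sum score matters downstream);
* **missingness**: each answer is dropped independently at a configured rate.

Marginal distributions are only order-of-magnitude realistic; the generator's
purpose is structural, not distributional, fidelity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BASELINE, FINAL, AssessmentRecord, CohortDataset, DailyRecord
from .dimensions import DIMENSIONS, ASSESSED_DIMENSIONS, PHYSICAL, COGNITIVE, SOCIAL, NUTRITIONAL
from .errors import ConfigError
from .scoring import ActivityMatrix
from .specs import (
    QuestionSpec,
    best_of,
    default_question_specs,
    default_variable_specs,
    questions_for_dimension,
)

#: Realistic location/scale per assessment variable (raw units), matching the
#: orders of magnitude of the standard instruments for this age group.
VARIABLE_BASE: dict[str, tuple[float, float]] = {
    "chair_stand": (12.5, 4.5),
    "arm_curl": (16.5, 5.0),
    "two_minute_step": (66.0, 25.0),
    "chair_sit_reach": (-4.5, 12.0),
    "back_scratch": (-10.0, 14.0),
    "foot_up_and_go": (6.3, 1.7),
    "moca": (25.5, 2.9),
    "mcs_a": (3.2, 2.2),
    "mai": (6.2, 1.1),
    "mna_mini": (4.2, 1.3),
}

#: Shared answer keys drawn once per day (Bernoulli 1/2), feeding every
#: dimension that references them.
_SHARED_KEYS = ("outside_house", "meal_outside_home", "been_to_shop", "prepared_own_food")


@dataclass
class GroupSpec:
    name: str
    proportion: float
    #: dimension (or variable id) -> baseline shift in robust-sd units,
    #: applied through each variable's orientation (positive = better).
    assessment_shift: dict[str, float] = field(default_factory=dict)
    #: dimension -> mean daily activity score.
    activity_level: dict[str, float] = field(default_factory=dict)
    #: dimension -> systematic baseline-to-final drift in sd units.
    improvement: dict[str, float] = field(default_factory=dict)


@dataclass
class EffectSpec:
    """Within ``group``, mean activity in ``activity_dimension`` (standardized
    within the group) shifts the final assessment of ``assessment_dimension``
    by ``beta`` robust-sd per unit."""

    group: str
    activity_dimension: str
    assessment_dimension: str
    beta: float


def default_groups() -> list[GroupSpec]:
    return [
        GroupSpec(
            "A",
            0.6,
            assessment_shift={NUTRITIONAL: -1.5, PHYSICAL: -1.5},
            activity_level={PHYSICAL: 12.0, COGNITIVE: 2.0, SOCIAL: 8.0, NUTRITIONAL: 35.0},
        ),
        GroupSpec(
            "B",
            0.4,
            assessment_shift={NUTRITIONAL: 1.5, PHYSICAL: 1.5},
            activity_level={PHYSICAL: 18.0, COGNITIVE: 3.0, SOCIAL: 12.0, NUTRITIONAL: 55.0},
        ),
    ]


@dataclass
class SyntheticConfig:
    n_participants: int = 68
    n_days: int = 150
    seed: int = 0
    groups: list[GroupSpec] = field(default_factory=default_groups)
    effects: list[EffectSpec] = field(
        default_factory=lambda: [EffectSpec("A", NUTRITIONAL, PHYSICAL, 0.5)]
    )
    #: AR(1) day-to-day correlation of the activity noise.
    ar1_rho: float = 0.6
    #: stationary sd of the AR(1) activity noise, per dimension (score units).
    activity_noise_sd: dict[str, float] = field(
        default_factory=lambda: {PHYSICAL: 4.0, COGNITIVE: 1.0, SOCIAL: 3.0, NUTRITIONAL: 8.0}
    )
    #: sd of the persistent per-participant activity level offset (score units).
    participant_activity_sd: dict[str, float] = field(
        default_factory=lambda: {PHYSICAL: 2.0, COGNITIVE: 0.5, SOCIAL: 1.5, NUTRITIONAL: 4.0}
    )
    #: within-group baseline spread, in units of each variable's base sd.
    baseline_noise_sd: float = 1.0
    #: trial-to-trial measurement noise for two-trial variables (base-sd units).
    trial_noise_sd: float = 0.15
    #: per-variable noise on the baseline-to-final change (base-sd units).
    change_noise_sd: float = 0.3
    #: probability that any individual daily answer is missing.
    answer_missing_rate: float = 0.05
    n_outliers: int = 6
    outlier_shift_sd: float = 5.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group is required")
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"group proportions must sum to 1, got {total}")
        if not 0 <= self.ar1_rho < 1:
            raise ConfigError(f"AR(1) rho must be in [0, 1), got {self.ar1_rho}")
        if not 0 <= self.answer_missing_rate <= 1:
            raise ConfigError("answer_missing_rate must be in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers >= self.n_participants:
            raise ConfigError("n_outliers must be in [0, n_participants)")


@dataclass
class GroundTruth:
    group_labels: dict[str, str]
    outlier_flags: dict[str, bool]
    effects: list[EffectSpec]
    #: realized mean activity per participant x dimension (post-missingness).
    mean_activity: pd.DataFrame

    def to_json(self, path) -> None:
        doc = {
            "group_labels": self.group_labels,
            "outlier_flags": self.outlier_flags,
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "mean_activity": {
                pid: {dim: self.mean_activity.loc[pid, dim] for dim in self.mean_activity.columns}
                for pid in self.mean_activity.index
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


# -- score-to-answer inversion ----------------------------------------------

def _dimension_cells(question_specs: dict[str, QuestionSpec], dimension: str):
    shared, exclusive = [], []
    for spec in questions_for_dimension(question_specs, dimension):
        target = shared if spec.answer_key in _SHARED_KEYS else exclusive
        for slot in spec.slots:
            target.append((spec, slot))
    return shared, exclusive


def _score_range(cells) -> tuple[float, float]:
    lo = sum(s.weight * s.max_index for s, _ in cells if s.weight < 0)
    hi = sum(s.weight * s.max_index for s, _ in cells if s.weight > 0)
    return lo, hi


def invert_score(target: float, cells) -> dict[tuple[str, int], int]:
    """Greedily allocate answer indices so the weighted sum approximates target.

    Cells are filled in descending |weight| order on the side (positive or
    negative weights) matching the target's sign; the target is clipped to the
    representable range first.  Any valid inverse is acceptable — downstream
    analysis only ever sees the weighted sum.
    """
    lo, hi = _score_range(cells)
    target = min(max(target, lo), hi)
    answers = {(s.answer_key, slot): 0 for s, slot in cells}
    side = [c for c in cells if (c[0].weight > 0) == (target >= 0) and c[0].weight != 0]
    side.sort(key=lambda c: -abs(c[0].weight))
    remaining = abs(target)
    for spec, slot in side:
        w = abs(spec.weight)
        take = min(spec.max_index, int(remaining // w))
        # Round up on the last usable cell when that lands closer to target.
        if take < spec.max_index and remaining - take * w > w / 2:
            take += 1
        answers[(spec.answer_key, slot)] = take
        remaining = max(0.0, remaining - take * w)
        if remaining == 0:
            break
    return answers


# -- generation --------------------------------------------------------------

def _group_counts(config: SyntheticConfig) -> list[int]:
    """Largest-remainder allocation of non-outlier participants to groups."""
    n = config.n_participants - config.n_outliers
    raw = [g.proportion * n for g in config.groups]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in range(n - sum(counts)):
        counts[remainders[i % len(raw)]] += 1
    return counts


def generate_cohort(config: SyntheticConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a cohort dataset and its planted ground truth.

    Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    question_specs = default_question_specs()
    variable_specs = default_variable_specs()
    cells = {dim: _dimension_cells(question_specs, dim) for dim in DIMENSIONS}

    # Validate activity targets against the representable score range.
    for group in config.groups:
        for dim, level in group.activity_level.items():
            shared, exclusive = cells[dim]
            lo, hi = _score_range(shared + exclusive)
            if not lo <= level <= hi:
                raise ConfigError(
                    f"group {group.name!r}: activity level {level} for dimension "
                    f"{dim!r} outside the representable score range [{lo}, {hi}]"
                )

    counts = _group_counts(config)
    width = len(str(config.n_participants))
    participants: list[str] = []
    group_of: dict[str, str] = {}
    outlier: dict[str, bool] = {}
    for gi, group in enumerate(config.groups):
        for _ in range(counts[gi]):
            pid = f"p{len(participants) + 1:0{width}d}"
            participants.append(pid)
            group_of[pid] = group.name
            outlier[pid] = False
    for _ in range(config.n_outliers):
        pid = f"p{len(participants) + 1:0{width}d}"
        participants.append(pid)
        group_of[pid] = "outlier"
        outlier[pid] = True
    groups_by_name = {g.name: g for g in config.groups}

    # Baseline latent values (raw units) and baseline records.
    latent: dict[str, dict[str, float]] = {}
    baselines: list[AssessmentRecord] = []
    for pid in participants:
        values: dict[str, float] = {}
        lat: dict[str, float] = {}
        for var, spec in variable_specs.items():
            mean, sd = VARIABLE_BASE[var]
            if outlier[pid]:
                shift = config.outlier_shift_sd * rng.choice([-1.0, 1.0])
            else:
                g = groups_by_name[group_of[pid]]
                shift = g.assessment_shift.get(var, g.assessment_shift.get(spec.dimension, 0.0))
            b = mean + spec.orientation * shift * sd + rng.normal(0, config.baseline_noise_sd * sd)
            lat[var] = b
            if spec.repeats == 2:
                trials = b + rng.normal(0, config.trial_noise_sd * sd, size=2)
                values[var] = best_of(trials, spec)
            else:
                values[var] = b
        latent[pid] = lat
        baselines.append(AssessmentRecord(pid, BASELINE, values))

    # Daily answers: AR(1) activity targets inverted into valid indices.
    daily: list[DailyRecord] = []
    for pid in participants:
        g = groups_by_name.get(group_of[pid])
        levels = {}
        for dim in DIMENSIONS:
            base = g.activity_level.get(dim, 0.0) if g is not None else (
                config.groups[0].activity_level.get(dim, 0.0)
            )
            levels[dim] = base + rng.normal(0, config.participant_activity_sd.get(dim, 0.0))
        noise = {}
        for dim in DIMENSIONS:
            s = config.activity_noise_sd.get(dim, 0.0)
            innov = s * np.sqrt(1 - config.ar1_rho**2)
            e = np.empty(config.n_days)
            e[0] = rng.normal(0, s) if s > 0 else 0.0
            steps = rng.normal(0, innov, size=config.n_days - 1) if s > 0 else np.zeros(config.n_days - 1)
            for d in range(1, config.n_days):
                e[d] = config.ar1_rho * e[d - 1] + steps[d - 1]
            noise[dim] = e
        for day in range(config.n_days):
            answers: dict[tuple[str, int], int] = {}
            shared_draw = {key: int(rng.integers(0, 2)) for key in _SHARED_KEYS}
            answers.update({(key, 0): val for key, val in shared_draw.items()})
            for dim in DIMENSIONS:
                shared, exclusive = cells[dim]
                shared_score = sum(
                    s.weight * shared_draw[s.answer_key] for s, _ in shared
                )
                target = levels[dim] + noise[dim][day] - shared_score
                answers.update(invert_score(target, exclusive))
            if config.answer_missing_rate > 0:
                keep = rng.random(len(answers)) >= config.answer_missing_rate
                answers = {
                    cell: val
                    for (cell, val), k in zip(sorted(answers.items()), keep)
                    if k
                }
            daily.append(DailyRecord(pid, day, answers))

    # Realized mean activity (through the actual scoring path, post-missingness).
    interim = CohortDataset(question_specs, variable_specs, baselines, daily, config.n_days)
    matrix = ActivityMatrix.from_dataset(interim)
    mean_activity = pd.DataFrame(
        {
            dim: [matrix.mean_activity(pid, dim) for pid in participants]
            for dim in DIMENSIONS
        },
        index=pd.Index(participants, name="participant_id"),
    )

    # Standardize realized activity within each group for the effect terms.
    zact = pd.DataFrame(0.0, index=mean_activity.index, columns=mean_activity.columns)
    for name in {**groups_by_name, "outlier": None}:
        members = [p for p in participants if group_of[p] == name]
        if not members:
            continue
        sub = mean_activity.loc[members]
        sd = sub.std(ddof=1)
        centered = sub - sub.mean()
        zact.loc[members] = centered.div(sd.replace(0.0, np.nan)).fillna(0.0)

    # Final assessments: baseline + drift + activity effects + noise.
    finals: list[AssessmentRecord] = []
    for pid in participants:
        g = groups_by_name.get(group_of[pid])
        values: dict[str, float] = {}
        for var, spec in variable_specs.items():
            mean, sd = VARIABLE_BASE[var]
            delta = g.improvement.get(spec.dimension, 0.0) if g is not None else 0.0
            if g is not None:
                for eff in config.effects:
                    if eff.group == g.name and eff.assessment_dimension == spec.dimension:
                        delta += eff.beta * float(zact.loc[pid, eff.activity_dimension])
            delta += rng.normal(0, config.change_noise_sd)
            f = latent[pid][var] + spec.orientation * delta * sd
            if spec.repeats == 2:
                trials = f + rng.normal(0, config.trial_noise_sd * sd, size=2)
                values[var] = best_of(trials, spec)
            else:
                values[var] = f
        finals.append(AssessmentRecord(pid, FINAL, values))

    dataset = CohortDataset(
        question_specs, variable_specs, baselines + finals, daily, config.n_days
    )
    truth = GroundTruth(group_of, outlier, list(config.effects), mean_activity)
    return dataset, truth


def write_cohort(dataset: CohortDataset, truth: GroundTruth, out_dir) -> None:
    """Write the cohort in the package's CSV schemas plus truth.json and specs.yaml."""
    from pathlib import Path

    from .dataset import write_assessment_csv, write_daily_csv
    from .specs import dump_specs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_assessment_csv(dataset.assessments, dataset.variable_specs, out / "assessments.csv")
    write_daily_csv(dataset.daily, dataset.question_specs, out / "daily.csv")
    dump_specs(dataset.question_specs, dataset.variable_specs, out / "specs.yaml")
    truth.to_json(out / "truth.json")
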