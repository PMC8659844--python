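"""Question and assessment-variable specifications.

Two small vocabularies drive the whole pipeline:

* :class:`QuestionSpec` — one daily-questionnaire question: its coaching
  dimension, answer scale and signed expert weight.  Qualitative answers are
  encoded to ordinal indices (Yes/No -> 1/0; ordered scales -> rank with the
  least category at 0); counts are clipped at the question's cap.
* :class:`AssessmentVariableSpec` — one baseline/final assessment variable
  (Fullerton battery item, MoCA, MCS-A, MAI, MNA mini): its dimension, its
  orientation (+1 higher-is-better, -1 lower-is-better, e.g. timed tests) and
  how many trials were recorded (the best of two is kept where applicable).

``default_question_specs()`` and ``default_variable_specs()`` reproduce the
study's daily questionnaire and assessment battery; both can be overridden
from a YAML file for other deployments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .dimensions import DIMENSIONS, PHYSICAL, COGNITIVE, SOCIAL, NUTRITIONAL, check_dimension
from .errors import ConfigError, DataError

YES_NO_SCALE = ("No", "Yes")
ACTIVITY_DURATION_SCALE = (
    "None",
    "Less than 1 h",
    "1-2 h",
    "2-3 h",
    "3-4 h",
    "More than 4 h",
)
FOOD_GROUP_SCALE = ("None", "Less", "Equal", "More", "All")
SOCIAL_PREFERENCE_SCALE = (
    "Decrease a lot",
    "Decrease a little",
    "Not change",
    "Increase a little",
    "Increase a lot",
)
SATIETY_SCALE = (
    "I ate too little",
    "I was just satisfied",
    "I ate slightly too much",
    "I ate too much",
)
MEAL_SCALE = ("Nothing", "Light meal", "Complete meal")


@dataclass(frozen=True)
class QuestionSpec:
    """One daily question.

    ``scale`` (ordered labels, least first) and ``max_count`` are mutually
    exclusive: a question is either ordinal or a bounded count.  ``answer_key``
    names the stored answer; questions that appear under two dimensions share
    one answer_key so a single response feeds both dimensions.
    """

    id: str
    dimension: str
    text: str
    weight: float
    scale: tuple[str, ...] | None = None
    max_count: int | None = None
    administrations_per_day: int = 1
    answer_key: str = ""

    def __post_init__(self) -> None:
        check_dimension(self.dimension)
        if (self.scale is None) == (self.max_count is None):
            raise ConfigError(
                f"question {self.id!r}: exactly one of scale/max_count must be set"
            )
        if self.scale is not None and len(self.scale) < 2:
            raise ConfigError(f"question {self.id!r}: ordered scale needs >=2 labels")
        if self.max_count is not None and self.max_count < 1:
            raise ConfigError(f"question {self.id!r}: max_count must be >=1")
        if self.administrations_per_day not in (1, 3):
            raise ConfigError(
                f"question {self.id!r}: administrations_per_day must be 1 or 3"
            )
        if not self.answer_key:
            object.__setattr__(self, "answer_key", self.id)

    @property
    def max_index(self) -> int:
        """Largest encodable answer index."""
        if self.scale is not None:
            return len(self.scale) - 1
        return int(self.max_count)  # type: ignore[arg-type]

    @property
    def slots(self) -> tuple[int, ...]:
        return tuple(range(self.administrations_per_day))


@dataclass(frozen=True)
class AssessmentVariableSpec:
    id: str
    dimension: str
    orientation: int = +1
    repeats: int = 1
    text: str = ""

    def __post_init__(self) -> None:
        check_dimension(self.dimension, assessed_only=True)
        if self.orientation not in (+1, -1):
            raise ConfigError(f"variable {self.id!r}: orientation must be +1 or -1")
        if self.repeats not in (1, 2):
            raise ConfigError(f"variable {self.id!r}: repeats must be 1 or 2")


def encode_answer(raw, spec: QuestionSpec) -> int:
    """Encode a raw answer to its nonnegative ordinal index.

    Ordered scales map to the rank of the label, least category = 0
    (Yes/No -> 1/0).  Counts are validated nonnegative and clipped at the
    question's cap.
    """
    if spec.scale is not None:
        if isinstance(raw, str):
            try:
                return spec.scale.index(raw)
            except ValueError:
                raise DataError(
                    f"question {spec.id!r}: unknown answer label {raw!r}; "
                    f"expected one of {list(spec.scale)}"
                ) from None
        # Already-encoded index: accepted if in range (round-trip convenience).
        idx = int(raw)
        if idx != raw or not 0 <= idx <= spec.max_index:
            raise DataError(
                f"question {spec.id!r}: index {raw!r} outside 0..{spec.max_index}"
            )
        return idx
    try:
        count = int(raw)
    except (TypeError, ValueError):
        raise DataError(
            f"question {spec.id!r}: expected a nonnegative count, got {raw!r}"
        ) from None
    if count != float(raw) or count < 0:
        raise DataError(
            f"question {spec.id!r}: expected a nonnegative integer count, got {raw!r}"
        )
    return min(count, spec.max_count)  # type: ignore[type-var]


def decode_answer(index: int, spec: QuestionSpec):
    """Inverse of :func:`encode_answer` (label for ordinal, int for counts)."""
    if spec.scale is not None:
        return spec.scale[index]
    return int(index)


def best_of(trials, spec: AssessmentVariableSpec) -> float:
    """Reduce recorded trials to the best one under the variable's orientation.

    Orientation +1 keeps the maximum, -1 (timed tests) the minimum.  A single
    trial is returned unchanged.
    """
    trials = [float(t) for t in trials]
    if not trials:
        raise DataError(f"variable {spec.id!r}: no trials supplied")
    if len(trials) > spec.repeats:
        raise DataError(
            f"variable {spec.id!r}: {len(trials)} trials exceed repeats={spec.repeats}"
        )
    for t in trials:
        if t != t or t in (float("inf"), float("-inf")):
            raise DataError(f"variable {spec.id!r}: non-finite trial value {t!r}")
    return max(trials) if spec.orientation > 0 else min(trials)


def default_question_specs() -> dict[str, QuestionSpec]:
    """The study's daily questionnaire (weights are the expert importances)."""
    q = [
        # Physical: light/moderate/vigorous activity duration, thrice daily.
        QuestionSpec("phys_light", PHYSICAL, "How much light physical activity have you performed?",
                     1, scale=ACTIVITY_DURATION_SCALE, administrations_per_day=3),
        QuestionSpec("phys_moderate", PHYSICAL, "How much moderate physical activity have you performed?",
                     2, scale=ACTIVITY_DURATION_SCALE, administrations_per_day=3),
        QuestionSpec("phys_vigorous", PHYSICAL, "How much vigorous physical activity have you performed?",
                     3, scale=ACTIVITY_DURATION_SCALE, administrations_per_day=3),
        # Cognitive: six yes/no engagement questions, four shared with other
        # dimensions (same stored answer, dimension-specific weight).
        QuestionSpec("cog_outside_house", COGNITIVE, "Have you been outside your house?",
                     1, scale=YES_NO_SCALE, answer_key="outside_house"),
        QuestionSpec("cog_meal_outside", COGNITIVE, "Have you eaten one or more meals outside of home?",
                     1, scale=YES_NO_SCALE, answer_key="meal_outside_home"),
        QuestionSpec("cog_shop", COGNITIVE, "Have you been to a shop?",
                     1, scale=YES_NO_SCALE, answer_key="been_to_shop"),
        QuestionSpec("cog_prepared_food", COGNITIVE, "Have you prepared your own food at least once?",
                     1, scale=YES_NO_SCALE, answer_key="prepared_own_food"),
        QuestionSpec("cog_artistic", COGNITIVE, "Have you practiced an artistic pastime?",
                     1, scale=YES_NO_SCALE),
        QuestionSpec("cog_reading", COGNITIVE, "Have you read anything?",
                     1, scale=YES_NO_SCALE),
        # Social
        QuestionSpec("soc_people_met", SOCIAL, "How many people have you met?",
                     3, max_count=4),
        QuestionSpec("soc_phone", SOCIAL, "How many people have you talked on the phone with?",
                     2, max_count=4),
        QuestionSpec("soc_texted", SOCIAL, "How many people have you texted?",
                     1, max_count=4),
        QuestionSpec("soc_outside_house", SOCIAL, "Have you been outside your house?",
                     2, scale=YES_NO_SCALE, answer_key="outside_house"),
        QuestionSpec("soc_shop", SOCIAL, "Have you been to a shop?",
                     2, scale=YES_NO_SCALE, answer_key="been_to_shop"),
        QuestionSpec("soc_preference", SOCIAL,
                     "Consider the social interactions you had, what would you prefer?",
                     2, scale=SOCIAL_PREFERENCE_SCALE),
        # Nutritional
        QuestionSpec("nut_meal_outside", NUTRITIONAL, "Have you eaten one or more meals outside of home?",
                     1, scale=YES_NO_SCALE, answer_key="meal_outside_home"),
        QuestionSpec("nut_prepared_food", NUTRITIONAL, "Have you prepared your own food at least once?",
                     1, scale=YES_NO_SCALE, answer_key="prepared_own_food"),
        QuestionSpec("nut_sugar", NUTRITIONAL, "How many times have you added sugar to anything you have eaten?",
                     -1, max_count=4),
        QuestionSpec("nut_salt", NUTRITIONAL,
                     "How many times have you added salt to anything you have eaten or drunk?",
                     -2, max_count=4),
        # No cap printed for water/alcohol/meal counts; 10/day is a generous
        # physiological bound for this cohort.
        QuestionSpec("nut_water", NUTRITIONAL, "How much water did you have? (unit: water glasses)",
                     2, max_count=10),
        QuestionSpec("nut_alcohol", NUTRITIONAL, "How many units of alcohol did you have?",
                     -2, max_count=10),
        QuestionSpec("nut_times_eaten", NUTRITIONAL, "How many times did you eat something during the day?",
                     1, max_count=10),
        QuestionSpec("nut_satiety", NUTRITIONAL, "How satisfied were you when you stopped eating?",
                     3, scale=SATIETY_SCALE),
        QuestionSpec("nut_veg_fruit", NUTRITIONAL, "Food groups: Vegetables and Fruits",
                     2, scale=FOOD_GROUP_SCALE, administrations_per_day=3),
        QuestionSpec("nut_dairy", NUTRITIONAL, "Food groups: Dairy Products",
                     1, scale=FOOD_GROUP_SCALE, administrations_per_day=3),
        QuestionSpec("nut_bread_cereal", NUTRITIONAL, "Food groups: Bread, Cereals and Potatoes",
                     1, scale=FOOD_GROUP_SCALE, administrations_per_day=3),
        QuestionSpec("nut_oils", NUTRITIONAL, "Food groups: Oils",
                     1, scale=FOOD_GROUP_SCALE, administrations_per_day=3),
        QuestionSpec("nut_meat_fish_eggs", NUTRITIONAL, "Food groups: Meat, Fish and Eggs",
                     2, scale=FOOD_GROUP_SCALE, administrations_per_day=3),
        QuestionSpec("nut_meal_type", NUTRITIONAL, "What have you eaten?",
                     3, scale=MEAL_SCALE),
    ]
    return {spec.id: spec for spec in q}


def default_variable_specs() -> dict[str, AssessmentVariableSpec]:
    """The assessment battery: Fullerton fitness items, MoCA, MCS-A, MAI, MNA mini.

    Foot Up and Go is a timed test (lower is better); the flexibility items
    (Chair Sit and Reach, Back Scratch) and Foot Up and Go were each run twice
    and reduced to the best trial.
    """
    v = [
        AssessmentVariableSpec("chair_stand", PHYSICAL, +1, 1, "Chair Stand"),
        AssessmentVariableSpec("arm_curl", PHYSICAL, +1, 1, "Arm Curl"),
        AssessmentVariableSpec("two_minute_step", PHYSICAL, +1, 1, "Two Minute Step"),
        AssessmentVariableSpec("chair_sit_reach", PHYSICAL, +1, 2, "Chair Sit and Reach"),
        AssessmentVariableSpec("back_scratch", PHYSICAL, +1, 2, "Back Scratch"),
        AssessmentVariableSpec("foot_up_and_go", PHYSICAL, -1, 2, "Foot Up and Go"),
        AssessmentVariableSpec("moca", COGNITIVE, +1, 1, "MoCA"),
        AssessmentVariableSpec("mcs_a", COGNITIVE, +1, 1, "MCS-A"),
        AssessmentVariableSpec("mai", COGNITIVE, +1, 1, "MAI"),
        AssessmentVariableSpec("mna_mini", NUTRITIONAL, +1, 1, "MNA mini"),
    ]
    return {spec.id: spec for spec in v}


def questions_for_dimension(
    question_specs: dict[str, QuestionSpec], dimension: str
) -> list[QuestionSpec]:
    check_dimension(dimension)
    return [s for s in question_specs.values() if s.dimension == dimension]


def variables_for_dimension(
    variable_specs: dict[str, AssessmentVariableSpec], dimension: str
) -> list[AssessmentVariableSpec]:
    check_dimension(dimension, assessed_only=True)
    return [s for s in variable_specs.values() if s.dimension == dimension]


# -- YAML round trip ---------------------------------------------------------

def dump_specs(question_specs, variable_specs, path) -> None:
    doc = {
        "questions": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(s).items()}
            for s in question_specs.values()
        ],
        "variables": [asdict(s) for s in variable_specs.values()],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_specs(path):
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "questions" not in doc or "variables" not in doc:
        raise ConfigError(f"{path}: expected a mapping with 'questions' and 'variables'")
    questions = {}
    for raw in doc["questions"]:
        raw = dict(raw)
        if raw.get("scale") is not None:
            raw["scale"] = tuple(raw["scale"])
        spec = QuestionSpec(**raw)
        questions[spec.id] = spec
    variables = {}
    for raw in doc["variables"]:
        spec = AssessmentVariableSpec(**raw)
        variables[spec.id] = spec
    return questions, variables
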