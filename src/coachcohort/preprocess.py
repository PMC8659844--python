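"""Robust standardization and the five-level weight vocabulary.

Assessment variables live on incommensurable scales (repetition counts,
seconds, screening scores), so before any between-participant comparison each
variable is z-standardized.  To keep gross outliers from biasing the location
and spread estimates, values outside the Tukey fences

    [Q1 - k*IQR,  Q3 + k*IQR]        (k = 1.5 by default)

are excluded when *fitting* the mean and sample standard deviation; the
outlying values themselves are still standardized and kept downstream.

The similarity weights users assign to dimensions/variables come from a
five-level vocabulary: very low=0, low=0.5, medium=1, high=1.5, very high=2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BASELINE, AssessmentRecord
from .errors import ConfigError, DataError
from .specs import AssessmentVariableSpec

#: The weight vocabulary for participant-similarity weighting.
WEIGHT_LEVELS: dict[str, float] = {
    "very low": 0.0,
    "low": 0.5,
    "medium": 1.0,
    "high": 1.5,
    "very high": 2.0,
}


def tukey_fences(values, k: float = 1.5) -> tuple[float, float]:
    """Tukey outlier fences (Q1 - k*IQR, Q3 + k*IQR), linear-interpolated quartiles."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise DataError(
            f"tukey_fences needs >=4 finite values to estimate quartiles, got {arr.size}"
        )
    if k < 0:
        raise ConfigError(f"Tukey multiplier k must be >=0, got {k}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


@dataclass
class VariableStandardization:
    mean: float
    std: float
    fences: tuple[float, float]
    n_used: int
    degenerate: bool = False


@dataclass
class StandardizationModel:
    """Per-variable robust moments, fitted on baseline values only."""

    variables: dict[str, VariableStandardization] = field(default_factory=dict)

    def standardize(self, variable: str, x: float) -> float:
        """z = (x - mean)/std; degenerate (zero-spread) variables map to 0."""
        if variable not in self.variables:
            raise DataError(f"standardization model has no variable {variable!r}")
        v = self.variables[variable]
        if v.degenerate:
            return 0.0
        return (x - v.mean) / v.std

    def non_degenerate(self) -> list[str]:
        return [var for var, v in self.variables.items() if not v.degenerate]

    # -- persistence ---------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            var: {
                "mean": v.mean,
                "std": v.std,
                "fences": list(v.fences),
                "n_used": v.n_used,
                "degenerate": v.degenerate,
            }
            for var, v in self.variables.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "StandardizationModel":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            {
                var: VariableStandardization(
                    mean=d["mean"],
                    std=d["std"],
                    fences=(d["fences"][0], d["fences"][1]),
                    n_used=d["n_used"],
                    degenerate=d["degenerate"],
                )
                for var, d in doc.items()
            }
        )


def fit_standardization(
    values_by_variable: dict[str, list[float]], k: float = 1.5
) -> StandardizationModel:
    """Fit per-variable mean/sample-std on the Tukey-clean subset.

    Variables whose clean subset has zero spread (or fewer than two values)
    are flagged degenerate: they standardize to 0 and are excluded from
    distances downstream.
    """
    model = StandardizationModel()
    for var, values in values_by_variable.items():
        arr = np.asarray(list(values), dtype=float)
        arr = arr[np.isfinite(arr)]
        lower, upper = tukey_fences(arr, k=k)
        clean = arr[(arr >= lower) & (arr <= upper)]
        if clean.size < 2:  # unreachable for k>=0, guarded anyway
            model.variables[var] = VariableStandardization(
                float(np.mean(arr)), 1.0, (lower, upper), int(clean.size), True
            )
            continue
        mean = float(np.mean(clean))
        std = float(np.std(clean, ddof=1))
        degenerate = not (std > 0.0)
        model.variables[var] = VariableStandardization(
            mean, std if not degenerate else 1.0, (lower, upper), int(clean.size), degenerate
        )
    return model


def fit_baseline_standardization(
    assessments: list[AssessmentRecord], k: float = 1.5
) -> StandardizationModel:
    """Fit the model on the cohort's baseline assessment values."""
    values: dict[str, list[float]] = {}
    for rec in assessments:
        if rec.timepoint != BASELINE:
            continue
        for var, val in rec.values.items():
            values.setdefault(var, []).append(val)
    if not values:
        raise DataError("no baseline assessment values to fit standardization on")
    return fit_standardization(values, k=k)


def standardize_records(
    records: list[AssessmentRecord], model: StandardizationModel
) -> pd.DataFrame:
    """Participant x variable z-value frame (NaN for missing variables).

    Degenerate variables are dropped; they carry no between-participant
    information.
    """
    variables = model.non_degenerate()
    rows = {}
    for rec in records:
        rows[rec.participant_id] = {
            var: model.standardize(var, rec.values[var])
            for var in variables
            if var in rec.values
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    return frame.reindex(columns=variables)


# -- weight vocabulary -------------------------------------------------------

@dataclass
class WeightConfig:
    """Similarity weights: one level per dimension, optional per-variable override."""

    dimension_levels: dict[str, str] = field(default_factory=dict)
    variable_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level in list(self.dimension_levels.values()) + list(self.variable_levels.values()):
            if level not in WEIGHT_LEVELS:
                raise ConfigError(
                    f"unknown weight level {level!r}; expected one of "
                    f"{list(WEIGHT_LEVELS)}"
                )


def resolve_weights(
    config: WeightConfig, variable_specs: dict[str, AssessmentVariableSpec]
) -> dict[str, float]:
    """Numeric weight per variable: dimension level unless overridden per variable.

    Unspecified dimensions default to "medium" (weight 1).
    """
    weights = {}
    for var, spec in variable_specs.items():
        level = config.variable_levels.get(
            var, config.dimension_levels.get(spec.dimension, "medium")
        )
        if level not in WEIGHT_LEVELS:
            raise ConfigError(f"unknown weight level {level!r} for variable {var!r}")
        weights[var] = WEIGHT_LEVELS[level]
    return weights
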