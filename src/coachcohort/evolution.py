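"""Pre/post improvement estimation and activity-trajectory views.

A participant's improvement in a dimension is the orientation-corrected
standardized change, averaged over the dimension's assessment variables:

    change(dim) = mean_v  orientation_v * (z_final,v - z_baseline,v)

so +1 means "one robust standard deviation better, on average".  Changes are
categorized (improved / same / worsened, with a +/- epsilon tolerance band
around zero) and shaded by magnitude relative to the cohort's largest
absolute change in that dimension — the green/yellow/red colour coding of the
evolution charts.

Daily activity series are noisy, so trajectory views apply a centered moving
window (mean, max or min) of odd width n, shrunk at the series boundaries,
with missing days excluded from the window statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BASELINE, FINAL, AssessmentRecord, CohortDataset
from .dimensions import ALL_PARTICIPANTS, ASSESSED_DIMENSIONS, check_dimension
from .errors import ConfigError, DataError
from .preprocess import StandardizationModel
from .scoring import ActivityMatrix
from .specs import AssessmentVariableSpec, variables_for_dimension

IMPROVED = "improved"
SAME = "same"
WORSENED = "worsened"

#: Category -> display colour of the evolution charts.
CATEGORY_COLORS = {IMPROVED: "green", SAME: "yellow", WORSENED: "red"}

#: Default tolerance band (standardized units) for "remained in the same state".
DEFAULT_EPSILON = 0.1


def improvement(
    baseline: AssessmentRecord,
    final: AssessmentRecord,
    model: StandardizationModel,
    variable_specs: dict[str, AssessmentVariableSpec],
    dimension: str,
) -> float:
    """Orientation-corrected standardized change for one participant/dimension."""
    check_dimension(dimension, assessed_only=True)
    changes = []
    for spec in variables_for_dimension(variable_specs, dimension):
        if spec.id not in model.variables or model.variables[spec.id].degenerate:
            continue
        if spec.id in baseline.values and spec.id in final.values:
            zb = model.standardize(spec.id, baseline.values[spec.id])
            zf = model.standardize(spec.id, final.values[spec.id])
            changes.append(spec.orientation * (zf - zb))
    if not changes:
        raise DataError(
            f"participant {baseline.participant_id!r}: no usable variables for "
            f"dimension {dimension!r}"
        )
    return float(np.mean(changes))


def categorize(change: float, epsilon: float, max_abs_change: float) -> tuple[str, float]:
    """(category, shade) for one change value.

    |change| <= epsilon -> "same" with shade 0; otherwise the sign decides
    improved/worsened and the shade is |change| / cohort max |change|.
    """
    if epsilon < 0:
        raise ConfigError(f"epsilon must be >= 0, got {epsilon}")
    if abs(change) <= epsilon:
        return SAME, 0.0
    shade = abs(change) / max_abs_change if max_abs_change > 0 else 0.0
    return (IMPROVED if change > 0 else WORSENED), min(shade, 1.0)


def improvement_profiles(
    dataset: CohortDataset,
    model: StandardizationModel,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Long frame: participant_id, dimension, change, category, shade.

    Covers every participant with both assessments; shades are relative to the
    cohort's max |change| within each dimension.
    """
    changes: list[tuple[str, str, float]] = []
    for rec in dataset.assessments:
        if rec.timepoint != BASELINE:
            continue
        final = dataset.assessment(rec.participant_id, FINAL)
        if final is None:
            continue
        for dim in ASSESSED_DIMENSIONS:
            try:
                delta = improvement(rec, final, model, dataset.variable_specs, dim)
            except DataError:
                continue
            changes.append((rec.participant_id, dim, delta))
    frame = pd.DataFrame(changes, columns=["participant_id", "dimension", "change"])
    if frame.empty:
        return frame.assign(category=pd.Series(dtype=str), shade=pd.Series(dtype=float))
    max_abs = frame.groupby("dimension")["change"].apply(lambda s: s.abs().max())
    cats, shades = [], []
    for _, row in frame.iterrows():
        cat, shade = categorize(row["change"], epsilon, max_abs[row["dimension"]])
        cats.append(cat)
        shades.append(shade)
    return frame.assign(category=cats, shade=shades)


def smooth(series, n: int, method: str = "mean") -> pd.Series:
    """Centered moving-window statistic of odd width n.

    Windows shrink at the boundaries; NaN (missing days) are excluded from the
    statistic; an all-missing window stays missing.  n=1 is the identity.
    """
    if method not in ("mean", "max", "min"):
        raise ConfigError(f"unknown smoothing method {method!r}; use mean/max/min")
    if n < 1 or n % 2 == 0:
        raise ConfigError(f"smoothing window must be an odd positive integer, got {n}")
    s = pd.Series(np.asarray(series, dtype=float)) if not isinstance(series, pd.Series) else series
    agg = {"mean": np.nanmean, "max": np.nanmax, "min": np.nanmin}[method]
    half = n // 2
    values = s.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        window = values[max(0, i - half) : i + half + 1]
        if np.any(~np.isnan(window)):
            out[i] = agg(window)
    return pd.Series(out, index=s.index, name=s.name)


@dataclass
class RangeFilter:
    """Optional closed interval on change per dimension (None bound = open)."""

    intervals: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim, (lo, hi) in self.intervals.items():
            check_dimension(dim, assessed_only=True)
            if lo is not None and hi is not None and lo > hi:
                raise ConfigError(f"dimension {dim!r}: interval [{lo}, {hi}] is empty-ordered")


def filter_by_ranges(profiles: pd.DataFrame, range_filter: RangeFilter) -> list[str]:
    """Participants whose change lies inside every specified interval.

    The brushing operation of the parallel-coordinates view.  Participants
    missing a filtered dimension are excluded by that filter.
    """
    keep = sorted(profiles["participant_id"].unique())
    for dim, (lo, hi) in range_filter.intervals.items():
        sub = profiles[profiles["dimension"] == dim].set_index("participant_id")["change"]
        selected = set()
        for pid in keep:
            if pid not in sub.index:
                continue
            x = sub[pid]
            if (lo is None or x >= lo) and (hi is None or x <= hi):
                selected.add(pid)
        keep = [pid for pid in keep if pid in selected]
    return keep


@dataclass
class TrajectoryView:
    """One evolution-chart panel: smoothed member series + improvement colours."""

    group: object  # cluster id or ALL_PARTICIPANTS
    activity_dimension: str
    color_dimension: str
    method: str
    window: int
    series: pd.DataFrame  # days x participants, smoothed
    colors: pd.DataFrame  # participant_id, change, category, shade, color

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.series.reset_index()
            .melt(id_vars="day_index", var_name="participant_id", value_name="value")
            .dropna(subset=["value"])
        )
        return long.merge(self.colors, on="participant_id", how="left")


def group_trajectories(
    group,
    clustering,
    matrix: ActivityMatrix,
    activity_dimension: str,
    color_dimension: str,
    profiles: pd.DataFrame,
    window: int = 7,
    method: str = "mean",
) -> TrajectoryView:
    """Smoothed activity series for one group, coloured by improvement elsewhere.

    ``group`` is a cluster id from ``clustering`` or the ``"all"`` token for
    the whole cohort (in which case ``clustering`` may be None).
    """
    check_dimension(activity_dimension)
    check_dimension(color_dimension, assessed_only=True)
    if group == ALL_PARTICIPANTS:
        members = list(matrix.participants)
    else:
        if clustering is None:
            raise DataError("a clustering is required unless group='all'")
        members = clustering.members(int(group))
    series = {}
    for pid in members:
        series[pid] = smooth(matrix.activity_series(pid, activity_dimension), window, method)
    frame = pd.DataFrame(series)
    frame.index.name = "day_index"
    sub = profiles[profiles["dimension"] == color_dimension].set_index("participant_id")
    colors = pd.DataFrame(
        {
            "participant_id": members,
            "change": [sub["change"].get(p, np.nan) for p in members],
            "category": [sub["category"].get(p, None) for p in members],
            "shade": [sub["shade"].get(p, np.nan) for p in members],
        }
    )
    colors["color"] = colors["category"].map(CATEGORY_COLORS)
    return TrajectoryView(
        group, activity_dimension, color_dimension, method, window, frame, colors
    )
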