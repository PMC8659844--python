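"""Two-step analysis workflow producing a static report bundle.

Step 1 reviews the assessment data (baseline vs final histograms per
variable); step 2 groups the participants by weighted similarity on the
baseline assessment and studies their evolution (dendrogram, group sizes,
standardized radar profiles, per-participant change axes with range brushing,
and smoothed activity trajectories coloured by improvement).

Everything is computed by the library modules; this module only orchestrates
and serialises.  ``learning`` mode adds explanatory text blocks to the report
JSON; ``pro`` mode omits them.  All figures are also emitted as plot-ready
CSV/JSON so downstream checks never parse pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hierarchy

from . import clustering as _clustering
from . import evolution as _evolution
from .dataset import BASELINE, FINAL, CohortDataset, read_cohort
from .dimensions import ALL_PARTICIPANTS, ASSESSED_DIMENSIONS, NUTRITIONAL, PHYSICAL
from .errors import CoachCohortError, ConfigError, DataError
from .preprocess import (
    WeightConfig,
    fit_baseline_standardization,
    resolve_weights,
    standardize_records,
)
from .scoring import ActivityMatrix

LEARNING_TEXTS = {
    "histograms": (
        "Each histogram overlays the baseline (first) and final (second) "
        "assessment distributions of one variable; a rightward shift of the "
        "final distribution suggests an overall improvement (for "
        "higher-is-better variables)."
    ),
    "dendrogram": (
        "The dendrogram records how participants merge into groups: the "
        "higher two branches join, the more dissimilar their members. Cutting "
        "at a dissimilarity threshold yields the flat groups below."
    ),
    "pie": (
        "Group sizes after the cut. Very small groups are flagged as "
        "outliers: participants too different from everyone else to support "
        "group-level insights."
    ),
    "radar": (
        "Per-group means of the standardized variables. Axes are comparable "
        "because every variable has robust mean 0 / sd 1 across the cohort."
    ),
    "parallel": (
        "One axis per coaching dimension showing each participant's "
        "standardized change (final - baseline, orientation-corrected). "
        "Positive is improvement. Restrict axis ranges to brush participants."
    ),
    "evolution": (
        "Daily activity of one dimension per group member, smoothed with a "
        "centered moving window; line colour encodes improvement in the "
        "selected dimension (green improved / yellow same / red worsened, "
        "darker = larger change)."
    ),
}


@dataclass
class RunConfig:
    assessments_path: str
    daily_path: str
    out_dir: str
    n_days: int = 150
    weights: WeightConfig = field(default_factory=WeightConfig)
    threshold: float = 0.5
    threshold_mode: str = "fraction"
    min_cluster_size: int = 3
    epsilon: float = _evolution.DEFAULT_EPSILON
    smoothing_window: int = 7
    smoothing_method: str = "mean"
    activity_dimension: str = NUTRITIONAL
    color_dimension: str = PHYSICAL
    mode: str = "learning"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("learning", "pro"):
            raise ConfigError(f"mode must be 'learning' or 'pro', got {self.mode!r}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be an odd positive integer")


def histogram_overlay(assessments, variable: str, bins="fd") -> dict:
    """Shared-edge histograms of one variable at the two timepoints.

    Bin edges follow the Freedman-Diaconis rule on the pooled timepoints
    (or a fixed count when ``bins`` is an integer).
    """
    base = [r.values[variable] for r in assessments if r.timepoint == BASELINE and variable in r.values]
    final = [r.values[variable] for r in assessments if r.timepoint == FINAL and variable in r.values]
    pooled = np.asarray(base + final, dtype=float)
    if pooled.size == 0:
        raise DataError(f"unknown or never-observed variable {variable!r}")
    edges = np.histogram_bin_edges(pooled, bins=bins)
    if len(edges) < 2 or edges[0] == edges[-1]:
        edges = np.histogram_bin_edges(pooled, bins=1)
    counts_base, _ = np.histogram(base, bins=edges)
    counts_final, _ = np.histogram(final, bins=edges)
    return {
        "variable": variable,
        "edges": [float(e) for e in edges],
        "baseline_counts": [int(c) for c in counts_base],
        "final_counts": [int(c) for c in counts_final],
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class _Stage:
    """Context manager labelling pipeline failures with their stage name."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise DataError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: RunConfig, dataset: CohortDataset | None = None) -> dict:
    """Run the full two-step workflow and write the report bundle.

    Returns the report dict (also written to ``<out_dir>/report.json``).
    Deterministic given the config and input data.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _Stage("ingest"):
        if dataset is None:
            dataset = read_cohort(
                config.assessments_path, config.daily_path, n_days=config.n_days
            )

    with _Stage("score"):
        matrix = ActivityMatrix.from_dataset(dataset)
        matrix.to_long_frame().to_csv(out / "activity.csv", index=False)

    with _Stage("standardize"):
        model = fit_baseline_standardization(dataset.assessments)
        model.to_json(out / "standardization.json")
        base_records = [r for r in dataset.assessments if r.timepoint == BASELINE]
        zframe = standardize_records(base_records, model)

    with _Stage("cluster"):
        weights = resolve_weights(config.weights, dataset.variable_specs)
        distances = _clustering.pairwise_distances(zframe, weights)
        tree = _clustering.agglomerate_average(distances)
        flat = _clustering.cut(
            tree, config.threshold, config.threshold_mode, config.min_cluster_size
        )
        flat.to_frame().to_csv(out / "clustering.csv", index=False)
        (out / "dendrogram.newick").write_text(tree.to_newick() + "\n")
        profiles_frame = _clustering.cluster_profiles(
            flat, zframe, ASSESSED_DIMENSIONS, dataset.variable_specs
        )

    with _Stage("evolve"):
        improvements = _evolution.improvement_profiles(dataset, model, config.epsilon)
        improvements.to_csv(out / "improvement_profiles.csv", index=False)
        views = {}
        for cid in flat.non_outlier_clusters():
            views[str(cid)] = _evolution.group_trajectories(
                cid, flat, matrix,
                config.activity_dimension, config.color_dimension,
                improvements, config.smoothing_window, config.smoothing_method,
            )
        views[ALL_PARTICIPANTS] = _evolution.group_trajectories(
            ALL_PARTICIPANTS, None, matrix,
            config.activity_dimension, config.color_dimension,
            improvements, config.smoothing_window, config.smoothing_method,
        )
        pd.concat(
            [v.to_long_frame().assign(group=str(g)) for g, v in views.items()],
            ignore_index=True,
        ).to_csv(out / "trajectories.csv", index=False)

    with _Stage("report"):
        histograms = {
            var: histogram_overlay(dataset.assessments, var)
            for var in sorted(dataset.variable_specs)
            if any(var in r.values for r in dataset.assessments)
        }
        report = {
            "config": {
                "threshold": config.threshold,
                "threshold_mode": config.threshold_mode,
                "min_cluster_size": config.min_cluster_size,
                "epsilon": config.epsilon,
                "smoothing_window": config.smoothing_window,
                "smoothing_method": config.smoothing_method,
                "activity_dimension": config.activity_dimension,
                "color_dimension": config.color_dimension,
                "mode": config.mode,
                "seed": config.seed,
            },
            "cohort": {
                "n_participants": len(dataset.participants),
                "n_days": dataset.n_days,
                "n_with_both_assessments": int(
                    sum(
                        1
                        for r in dataset.assessments
                        if r.timepoint == BASELINE
                        and dataset.assessment(r.participant_id, FINAL) is not None
                    )
                ),
            },
            "histograms": histograms,
            "clustering": {
                "threshold_used": flat.threshold_used,
                "max_height": tree.max_height,
                "n_clusters": flat.n_clusters,
                "sizes": {str(k): v for k, v in flat.sizes.items()},
                "proportions": {str(k): v for k, v in flat.proportions.items()},
                "outlier_flags": {str(k): v for k, v in flat.outlier_flags.items()},
                "labels": {p: int(c) for p, c in sorted(flat.labels.items())},
                "merges": tree.to_merge_json(),
            },
            "cluster_profiles": {
                str(cid): {v: float(profiles_frame.loc[cid, v]) for v in profiles_frame.columns}
                for cid in profiles_frame.index
            },
            "improvement": {
                "epsilon": config.epsilon,
                "profiles": [
                    {
                        "participant_id": row["participant_id"],
                        "dimension": row["dimension"],
                        "change": float(row["change"]),
                        "category": row["category"],
                        "shade": float(row["shade"]),
                    }
                    for _, row in improvements.iterrows()
                ],
            },
        }
        if config.mode == "learning":
            report["learning_texts"] = LEARNING_TEXTS
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")

    with _Stage("figures"):
        _render_figures(out, dataset, tree, flat, profiles_frame, improvements, views, histograms)

    return report


# -- figure rendering --------------------------------------------------------

def _save(fig, out: Path, name: str) -> None:
    fig.savefig(out / f"{name}.png", dpi=120)
    fig.savefig(out / f"{name}.svg")
    plt.close(fig)


def _render_figures(out, dataset, tree, flat, profiles_frame, improvements, views, histograms):
    # Histogram overlays (first 12 variables at most, one panel each).
    items = list(histograms.items())[:12]
    if items:
        ncols = 3
        nrows = int(np.ceil(len(items) / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
        for ax, (var, h) in zip(axes.ravel(), items):
            edges = np.asarray(h["edges"])
            centers = (edges[:-1] + edges[1:]) / 2
            width = np.diff(edges)
            ax.bar(centers, h["baseline_counts"], width=width, alpha=0.6, color="tab:blue", label="baseline")
            ax.bar(centers, h["final_counts"], width=width, alpha=0.6, color="tab:orange", label="final")
            ax.set_title(var, fontsize=9)
        for ax in axes.ravel()[len(items):]:
            ax.axis("off")
        axes[0, 0].legend(fontsize=8)
        fig.tight_layout()
        _save(fig, out, "histograms")

    # Dendrogram.
    if tree.merges:
        fig, ax = plt.subplots(figsize=(10, 4))
        _hierarchy.dendrogram(
            tree.to_linkage_matrix(), labels=tree.participant_ids,
            color_threshold=flat.threshold_used, ax=ax,
        )
        ax.axhline(flat.threshold_used, color="grey", ls="--", lw=1)
        ax.set_ylabel("dissimilarity")
        ax.tick_params(axis="x", labelsize=5)
        fig.tight_layout()
        _save(fig, out, "dendrogram")

    # Pie of group sizes.
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    labels = [
        f"Group {cid}" + (" (outlier)" if flat.outlier_flags[cid] else "")
        for cid in flat.sizes
    ]
    ax.pie(list(flat.sizes.values()), labels=labels, autopct="%1.1f%%", textprops={"fontsize": 7})
    fig.tight_layout()
    _save(fig, out, "pie")

    # Radar of standardized cluster profiles (non-outlier clusters).
    keep = [cid for cid in profiles_frame.index if not flat.outlier_flags[cid]]
    if keep and len(profiles_frame.columns) >= 3:
        variables = list(profiles_frame.columns)
        angles = np.linspace(0, 2 * np.pi, len(variables), endpoint=False)
        fig = plt.figure(figsize=(5, 5))
        ax = fig.add_subplot(projection="polar")
        for cid in keep:
            vals = profiles_frame.loc[cid].to_numpy()
            ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=f"Group {cid}")
        ax.set_xticks(angles)
        ax.set_xticklabels(variables, fontsize=6)
        ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.25, 1.1))
        fig.tight_layout()
        _save(fig, out, "radar")

    # Parallel coordinates of per-dimension change, coloured by cluster.
    if not improvements.empty:
        wide = improvements.pivot(index="participant_id", columns="dimension", values="change")
        wide = wide.reindex(columns=[d for d in ASSESSED_DIMENSIONS if d in wide.columns])
        fig, ax = plt.subplots(figsize=(6, 4))
        cmap = plt.get_cmap("tab10")
        xs = np.arange(len(wide.columns))
        for pid, row in wide.iterrows():
            cid = flat.labels.get(pid, 0)
            ax.plot(xs, row.to_numpy(), color=cmap(cid % 10), alpha=0.6, lw=1)
        ax.set_xticks(xs)
        ax.set_xticklabels(wide.columns)
        ax.axhline(0, color="grey", lw=0.8, ls=":")
        ax.set_ylabel("standardized change")
        fig.tight_layout()
        _save(fig, out, "parallel_coordinates")

    # Evolution lines per view.
    shade_floor = 0.25  # keep even "slight" changes visible
    for gname, view in views.items():
        fig, ax = plt.subplots(figsize=(7, 4))
        base_rgb = {"green": (0.0, 0.5, 0.0), "yellow": (0.8, 0.7, 0.0), "red": (0.8, 0.0, 0.0)}
        colors = view.colors.set_index("participant_id")
        for pid in view.series.columns:
            cat = colors.loc[pid, "category"]
            shade = colors.loc[pid, "shade"]
            rgb = base_rgb.get(colors.loc[pid, "color"], (0.4, 0.4, 0.4))
            alpha = shade_floor + (1 - shade_floor) * (0.0 if pd.isna(shade) else float(shade))
            ax.plot(view.series.index, view.series[pid], color=rgb, alpha=alpha, lw=1)
        ax.set_xlabel("day")
        ax.set_ylabel(f"{view.activity_dimension} activity ({view.method}, n={view.window})")
        ax.set_title(f"group {gname}: coloured by {view.color_dimension} improvement", fontsize=9)
        fig.tight_layout()
        _save(fig, out, f"evolution_group_{gname}")
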