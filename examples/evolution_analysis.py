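"""Relate in-program activity to pre/post improvement, per group.

The synthetic cohort plants a beta = 0.5 effect from nutritional activity to
physical improvement in group A only.  After grouping, the rank correlation
between member mean nutritional activity and physical change should be
strongly positive in the cluster matching group A and near zero in the other
— the pattern the coloured evolution chart is designed to surface.
"""

from scipy.stats import spearmanr

from coachcohort import (
    ActivityMatrix,
    BASELINE,
    SyntheticConfig,
    WeightConfig,
    agglomerate_average,
    cut,
    fit_baseline_standardization,
    generate_cohort,
    group_trajectories,
    improvement_profiles,
    pairwise_distances,
    resolve_weights,
    standardize_records,
)

dataset, truth = generate_cohort(SyntheticConfig(seed=42))
model = fit_baseline_standardization(dataset.assessments)
zframe = standardize_records(
    [r for r in dataset.assessments if r.timepoint == BASELINE], model
)
tree = agglomerate_average(
    pairwise_distances(zframe, resolve_weights(WeightConfig(), dataset.variable_specs))
)
flat = cut(tree, 0.35, "fraction")
matrix = ActivityMatrix.from_dataset(dataset)
profiles = improvement_profiles(dataset, model)

for cid in sorted(flat.non_outlier_clusters(), key=lambda c: -flat.sizes[c])[:2]:
    view = group_trajectories(
        cid, flat, matrix, "nutritional", "physical", profiles, window=7, method="mean"
    )
    members = list(view.series.columns)
    planted = [truth.group_labels[p] for p in members if not truth.outlier_flags[p]]
    majority = max(set(planted), key=planted.count)
    activity = [matrix.mean_activity(p, "nutritional") for p in members]
    change = view.colors.set_index("participant_id").loc[members, "change"]
    rho = spearmanr(activity, change).statistic
    n_improved = int((view.colors["category"] == "improved").sum())
    print(
        f"Group {cid} (planted '{majority}', n={len(members)}): "
        f"nutrition-activity vs physical-change Spearman rho = {rho:+.2f}; "
        f"{n_improved} members improved physically"
    )
print(
    "\nrho near +1 in the group carrying the planted effect means members who"
    "\nkept their nutritional activity up improved physically; rho near 0 in"
    "\nthe other group means no such relationship was planted or found."
)
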