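# Methods

`coachcohort` is an analytics engine for virtual-coaching programs with older
adult cohorts. A cohort consists of a supervised **assessment battery**
recorded at baseline and about five months later (Fullerton Functional
Fitness items, MoCA, MCS-A, MAI and the MNA mini screen) and a **daily
self-report questionnaire** covering four coaching dimensions: physical,
cognitive, social and nutritional. The package scores daily activity, groups
participants by weighted similarity on the baseline assessment, and relates
in-program activity to pre/post change. This note documents the model, its
assumptions, the tunable parameters, and the deliberate design choices.

## Answer encoding and daily activity scoring

Qualitative answers are mapped to nonnegative ordinal indices: Yes/No becomes
1/0, and ordered scales are ranked with the least category at 0 (e.g. the
activity-duration scale None → 0 up to "More than 4 h" → 5). Counts ("How
many people have you met?") are clipped at the question's cap — 4 where a cap
is stated; for water glasses, alcohol units and meals per day no cap is
stated, so a generous physiological bound of 10/day is used (configurable).
Two scales have no intrinsic "least" pole (the social-preference and satiety
questions); they are coded ascending from "Decrease a lot" = 0 and "I ate too
little" = 0 respectively, and the direction is configurable per question via
the scale order in `specs.yaml`.

The daily activity level of a dimension is the weighted sum of its encoded
answers,

```
activity_d(day) = Σ_i  w_i · a_i ,
```

with expert-assigned weights `w_i ∈ {−2, −1, 1, 2, 3}`; negative weights mark
detrimental behaviours (added sugar/salt, alcohol). Questions administered
three times a day (the physical-activity and food-group items) contribute one
term per administration, i.e. the day's **total** is scored, not its average
— summation is the natural reading of a weighted sum over question instances,
and it preserves linearity in the amount of reported activity. Four questions
appear under two dimensions (e.g. "Have you been outside your house?" is both
cognitive and social); a single stored answer feeds both dimensions with
dimension-specific weights.

Missing answers contribute 0 to the sum and lower the cell's *completeness*
(fraction of the dimension's question slots answered). Days below a
configurable completeness floor (default 0, i.e. keep everything) are marked
missing rather than imputed; no imputation is attempted anywhere.

## Robust standardization

Assessment variables are z-standardized before any between-participant
comparison. Location and spread are fitted per variable on the values inside
the Tukey fences `[Q1 − k·IQR, Q3 + k·IQR]` (linear-interpolation quartiles,
`k = 1.5`; both configurable), using the sample (n−1) standard deviation.
Outlying values are excluded **only from the fit**: they are still
standardized and kept downstream, where they typically surface as singleton
clusters. Variables with zero spread on the clean subset are flagged
degenerate, standardize to 0, and are excluded from distances and
improvement means.

The model is fitted on **baseline** values only; final-assessment values are
transformed with the same baseline model so that change scores are expressed
in comparable units (grouping operates on the first assessment, and a common
reference scale keeps "one sd of change" meaningful).

## Participant similarity and grouping

Similarity between participants `u, v` is the weighted Manhattan distance
over standardized baseline variables,

```
d(u, v) = Σ_i  w_i · |u_i − v_i| ,
```

with `w_i` resolved from a five-level vocabulary (very low = 0, low = 0.5,
medium = 1 — the default, high = 1.5, very high = 2) set per dimension and
optionally overridden per variable. When two participants miss different
variables, the sum runs over the shared variables and is rescaled by
(total weight)/(shared weight) so distances stay on a common scale (pairwise
deletion; with none shared the pair is rejected).

Groups come from average-linkage (UPGMA) agglomeration: repeatedly merge the
two clusters with the smallest mean pairwise inter-cluster distance, recording
that mean as the merge height. The agglomerator is implemented in-package so
its arithmetic is fully specified: cross-cluster averages are computed with
correctly-rounded summation (`math.fsum`), making heights independent of
member order, and ties on height are broken by the lexicographically smallest
node-id pair. Average linkage is monotone, so heights never decrease along
the merge sequence.

Cutting the dendrogram at a dissimilarity threshold yields the flat grouping.
The default threshold semantics is a **fraction of the maximum merge height**
(an absolute mode is provided): a normalized scale keeps one slider meaning
across weight settings, since scaling all weights by `c > 0` scales every
height by `c` but leaves every fractional cut unchanged. Cluster ids are
assigned by decreasing size (Group 0 is the largest). Clusters smaller than
`min_cluster_size` (default 3 — tiny groups of one or two participants) are
flagged as outlier groups and excluded from insight extraction, though never
from the output.

## Improvement estimation and evolution views

Per-dimension improvement is the orientation-corrected standardized change
averaged over the dimension's variables:

```
change(dim) = mean_v  orientation_v · (z_final,v − z_baseline,v) .
```

Orientations default to +1 (higher is better) for every variable except the
timed Foot Up and Go test (−1); all are configurable, and two-trial variables
(Chair Sit and Reach, Back Scratch, Foot Up and Go) are reduced to the best
trial under the same orientation before anything else. The within-dimension
aggregation is an unweighted mean over available variables; missing variables
are simply excluded.

Changes are categorized improved / same / worsened with a tolerance band
`|change| ≤ ε` for "same"; ε defaults to 0.1 standardized units — a band
small enough that a tenth of a robust sd counts as noise, large enough to
absorb measurement wobble — and is configurable. The colour *shade* is
`|change| / max_cohort |change|` within the dimension, so the cohort's
largest mover gets shade 1.

Daily activity series are smoothed for display with a centered moving window
of odd width `n` (default 7): mean, max or min. Windows shrink at the series
boundaries, missing days are excluded from the statistic, and an all-missing
window stays missing. Range brushing (the parallel-coordinates interaction)
selects participants whose change lies inside every specified closed
interval.

## Synthetic cohorts

The generator emulates the study's structure — 68 participants, a 150-day
window, two assessments, the full daily questionnaire — with planted ground
truth exported alongside:

* **Groups** (defaults: 60%/40%) with baseline shifts in robust-sd units
  applied through variable orientations; the default ±1.5 sd on the physical
  and nutritional dimensions puts 3 sd between the group centers, and 6
  additional outlier participants sit 5 sd away in random directions
  (mirroring the handful of tiny outlier groups real cohorts show).
* **Daily activity**: per participant, a persistent level offset plus an
  AR(1) noise process (ρ = 0.6, chosen so multi-day smoothing is meaningful;
  stationary sd per dimension of roughly a quarter of the group level). Each
  day's target score is inverted into valid answer indices by greedy
  allocation in descending |weight|; any valid inverse is acceptable because
  downstream analysis only ever sees the weighted sum. Shared-answer
  questions are drawn first (Bernoulli 1/2) and the residual target is
  allocated to the dimension-exclusive questions. Group activity levels
  outside the representable score range are rejected at configuration time.
* **Effects**: within a chosen group, final − baseline change in one
  dimension gains `β ×` (the participant's realized mean activity in another
  dimension, standardized within the group). The default plants β = 0.5 from
  nutritional activity to physical improvement in the low-nutrition group
  only — the pattern the grouped evolution view is designed to surface.
  Realized activity is measured through the actual scoring path (after
  missingness), so the planted association is exact by construction.
* **Missingness**: each answer is dropped independently at rate 0.05.

What the generator does **not** emulate: realistic marginal answer
distributions (greedy inversion concentrates answers on high-weight
questions), floor/ceiling effects of the clinical instruments, informative
missingness, drop-out, or seasonal trends. Passing recovery tests therefore
demonstrates the pipeline's correctness on data with the assumed structure,
not robustness to the messiness of real cohorts.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation (numpy default); fences need ≥ 4 finite
  values.
* Standard deviations: sample (n−1) throughout.
* Degenerate variables: standardize to 0, excluded from distances and
  improvement; a cohort where *all* variables are degenerate is rejected.
* Agglomeration ties: smallest node-id pair; deterministic and
  oracle-matchable.
* Cut semantics: merges with height ≤ cut height are applied; fraction 1.0
  therefore always yields a single cluster, and a threshold below the first
  merge yields all singletons.
* Shade with a zero cohort maximum: 0 (everyone "same").
* JSON report output is key-sorted, so identical configurations and data
  reproduce byte-identical reports.

## Problem sizes used in the test suite

Unit tests run on cohorts of 5–40 participants over 5–60 days; the
end-to-end recovery and association properties run the full pipeline at the
study scale (68 participants × 150 days), the association property over 50
generator seeds; the agglomeration oracle check covers 200 random instances
with n ≤ 8 (every third instance integer-valued to force height ties). These
sizes exercise every code path while keeping the whole suite within a few
minutes on one core.

## Known limitations

* The dissimilarity threshold is expressed on a normalized (fraction-of-max)
  scale by default; thresholds quoted on other scales need the absolute mode.
* No statistical tests accompany the group comparisons — the views are
  exploratory, and apparent activity/improvement associations are
  correlational.
* SUS standard deviations across subjects are not computable from
  per-question sorted multisets; only the mean is reported from that layout.
* Improvement requires both assessments; participants lacking a final
  assessment appear in grouping and activity views but not in change-based
  views.
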