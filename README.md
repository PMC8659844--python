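# coachcohort

Analytics for virtual-coaching programs with older adult cohorts. The package
is written for the analysts and caregivers who run such programs: it scores
each participant's **daily self-reported activity** in four coaching
dimensions (physical, cognitive, social, nutritional), **groups participants**
by similarity on their baseline assessment so coaching plans can be tailored
per group, and **relates in-program activity to pre/post change** between the
baseline and final assessments. A synthetic cohort generator with exported
ground truth makes every stage testable without real participant data.

## The model

**Daily activity.** Each dimension's daily activity level is a weighted sum of
encoded questionnaire answers,

```
activity_d(day) = Σ_i  w_i · a_i
```

where `a_i` is the answer index (Yes/No → 1/0; ordered scales ranked from the
least category at 0; counts clipped at their cap) and `w_i` is the expert
weight of question *i* (negative for detrimental behaviours such as added
salt or alcohol). Thrice-daily questions contribute one term per
administration.

**Grouping.** Assessment variables (Fullerton fitness battery, MoCA, MCS-A,
MAI, MNA mini) are z-standardized with moments fitted on the Tukey-clean
subset (outliers outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are excluded from the
fit, not from the data). Participant similarity is the weighted Manhattan
distance

```
d(u, v) = Σ_i  w_i · |u_i − v_i| ,    w_i ∈ {0, 0.5, 1, 1.5, 2}
```

with weights set per dimension from a five-level vocabulary (very low … very
high). Average-linkage (UPGMA) agglomeration builds a dendrogram; cutting it
at a dissimilarity threshold yields the flat groups, with tiny groups flagged
as outliers.

**Evolution.** Per-dimension improvement is the orientation-corrected
standardized change `mean_v orientation_v · (z_final − z_baseline)`,
categorized improved / same / worsened (tolerance band ε = 0.1 sd) and shaded
by magnitude relative to the cohort maximum. Activity trajectories are
smoothed with centered moving mean/max/min windows and coloured by
improvement — the chart that surfaces patterns like "members who kept their
nutrition up improved physically".

A utility module scores the 10-item System Usability Scale, including the
exact recovery of the mean score from per-question answer multisets when the
per-subject pairing has been destroyed by sorting.

## Worked example

`examples/group_participants.py` generates the default synthetic cohort (68
participants, 150 days, two planted groups 3 sd apart plus 6 planted
outliers), weights the physical variables low and cognitive/nutritional high,
and cuts the dendrogram at 30% of its maximum height:

```
max merge height: 34.81  (cut at 30% of it)
8 clusters:
  Group 0: 37 participants (54.4%)
  Group 1: 25 participants (36.8%)
  Group 2: 1 participants (1.5%) [outlier group]
  ...
planted-group purity of the 2 main clusters: 100%, 100%
```

The two large clusters recover the planted groups exactly; the six singletons
are the planted outliers. `examples/evolution_analysis.py` then shows the
planted nutrition→physical effect (β = 0.5 in group A only):

```
Group 0 (planted 'A', n=37): nutrition-activity vs physical-change Spearman rho = +0.96; ...
Group 1 (planted 'B', n=25): nutrition-activity vs physical-change Spearman rho = +0.07; ...
```

A strong positive rank correlation appears only in the group carrying the
planted effect. The other examples cover daily scoring
(`simulate_and_score.py`) and SUS arithmetic (`sus_scoring.py`, which prints
`mean SUS from per-question multisets: 71.1` for the nine-rater evaluation
tables shipped with the package).

## Command line

The same workflow is available as a thin CLI:

```
coachcohort --seed 7 simulate --out cohort/
coachcohort ingest  --assessments cohort/assessments.csv --daily cohort/daily.csv --out summary.json
coachcohort report  --assessments cohort/assessments.csv --daily cohort/daily.csv \
                    --threshold 0.35 --out report/
coachcohort sus --input sus_answers.csv
```

`report` writes `report.json`, plot-ready CSVs, a Newick dendrogram and
static PNG/SVG figures (histograms, dendrogram, pie, radar, parallel
coordinates, evolution lines). `--mode learning` (default) includes
explanatory text blocks in the report; `--mode pro` omits them. Exit codes:
0 ok, 1 data error, 2 configuration error.

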