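"""Score a System Usability Scale questionnaire from answer multisets.

Uses the nine-rater evaluation tables shipped with the package.  Published
SUS answers are often sorted per question to prevent re-identification; the
mean score survives that transformation exactly, the per-subject spread does
not.
"""

from coachcohort import NINE_RATER_SUS_ANSWERS, sus_mean_from_multisets, sus_score
from coachcohort.usability import NINE_RATER_SUS_SUBJECT_SCORES, summary_stats

mean = sus_mean_from_multisets(NINE_RATER_SUS_ANSWERS)
print(f"mean SUS from per-question multisets: {mean:.1f}")
print(f"mean of the published per-subject totals: "
      f"{summary_stats(NINE_RATER_SUS_SUBJECT_SCORES)[0]:.1f}  (cross-check)")

print(f"\na neutral rater (all 3s) scores {sus_score([3] * 10):.0f};")
print("68 is the conventional 'average usability' benchmark, so a mean in the")
print("low 70s corresponds to a 'good' rating.")
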