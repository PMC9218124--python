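"""Estimate rating-based discrimination thresholds and compare classes.

For each participant, trials are binarized against the mean rating at a
reference temperature (43 degC stepping up, 49 degC stepping down) and a
logistic regression gives the temperature at which the probability of
reporting a changed sensation reaches 0.5.  Participants who discriminate
every trial are credited with a half-degree step (43.5 / 48.5 degC).
"""

from painpsych import CohortConfig, generate_cohort
from painpsych.discrimination import compare_thresholds, discrimination_table
from painpsych.sensitivity_classes import classify_cohort

dataset, _ = generate_cohort(CohortConfig(seed=1))
assignments, _, _ = classify_cohort(dataset, seed=0)
labels = dict(zip(assignments.participant_id, assignments.class_label))

thresholds = discrimination_table(dataset)
summary = thresholds.groupby(["direction", "measure"])["threshold"].agg(["mean", "std"])
print(summary.round(3).to_string())
print(f"\nedge-rule participants (discriminate every trial): "
      f"{thresholds.edge_case.mean():.0%}")

comparisons = compare_thresholds(thresholds, labels)
for key, out in comparisons.items():
    kw = out["kruskal_wallis"]
    print(f"{key}: Kruskal-Wallis chi2({kw['df']}) = {kw['H']:.2f}, p = {kw['p']:.4f}")
print(
    "\nSmall ascending thresholds mean a participant reliably reports more "
    "pain after less than a degree of warming; class differences are tested "
    "nonparametrically with Dunn post-hocs behind each p value."
)
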