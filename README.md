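# painpsych

Analyses of individual differences in pain psychophysics and their (missing)
brain correlates, backed by a synthetic-data generator with full ground
truth.

Self-reported pain to a fixed noxious stimulus varies enormously across
healthy people. This package implements the analysis chain used to study
that variation and its relationship to evoked brain activity:

- **Sensitivity classes** — participants rated graded heat (35–49 °C, VAS
  0–10 for intensity and unpleasantness); mixtures of K = 1…5 diagonal
  Gaussians over the 14 mean-rating features are fitted by EM, and the model
  is chosen by a spurious-class rule (any class ≤ 10 % of participants is
  over-extraction) followed by minimum BIC, with
  `BIC = −2 log L + n_params ln n`.
- **Stevens power functions** — each class's stimulus–response curve follows
  `rating = exp(b·ln(T − 35) + c)`; `b` and `c` come from OLS in
  double-natural-log space with the slope F-test on (1, n−2) df.
- **Discrimination thresholds** — trials are binarized against the mean
  rating at a reference temperature (43 °C ascending / 49 °C descending); a
  per-participant logistic fit gives the 0.5-probability threshold
  `−intercept/slope`, with participants who discriminate every trial
  credited with a half-degree step (43.5 / 48.5 °C). Classes are compared
  with Kruskal–Wallis + Dunn tests.
- **Voxelwise group analyses** — on per-subject beta maps: covariate GLM
  (activation on mean-centered ratings), paired high-vs-low contrasts, and
  between-class F/t contrasts, all with permutation-based cluster inference
  at a |z| ≥ 3.1 forming threshold.
- **Multivariate analyses** — signature expression (dot product of a beta
  map with a fixed voxel-weight pattern) and LASSO-PCR (principal-component
  + L1 regression) prediction of ratings with nested 5×5-fold
  cross-validation and bootstrap weight inference.

The synthetic generator plants either a *coupled* regime (activation
proportional to each participant's rating) or a *dissociated* regime
(identical activation despite different ratings, with within-individual
intensity effects intact), so every pipeline stage is testable against
known truth without any data download.

## Worked example

```python
from painpsych import CohortConfig, generate_cohort
from painpsych.sensitivity_classes import classify_cohort
from painpsych.power_fit import class_power_table

dataset, truth = generate_cohort(CohortConfig(seed=1))   # 101 participants
assignments, best, models = classify_cohort(dataset, seed=0)
print(best.k)                                            # -> 3
labels = dict(zip(assignments.participant_id, assignments.class_label))
table, fits = class_power_table(dataset, labels)
print(table[table.measure == "intensity"].round(3).to_string(index=False))
```

prints

```
   class        measure  exponent  constant         F  df1  df2   p    R2
    High      intensity     2.866    -5.311   442.399    1    5 0.0 0.989
     Low      intensity     3.936    -9.876 19663.749    1    5 0.0 1.000
Moderate      intensity     4.453    -9.964 37070.106    1    5 0.0 1.000
```

Three classes are selected (the generator planted 23 High / 41 Moderate /
37 Low, recovered with adjusted Rand index 1.0). The High-sensitivity class
has the smallest exponent and the highest constant — it responds strongly to
mild stimuli and saturates near the top of the scale — and the fits recover
the generator's coefficients (High class planted at b = 2.93, c = −5.49).

Running the brain stage on the same cohort (`examples/05_brain_rating_dissociation.py`):

```
=== dissociated regime ===
covariate-GLM significant clusters : 0
signature paired t(100) = 50.77, expression-rating r(99) = 0.083
LASSO-PCR held-out r = -0.132, RMSE = 2.50 VAS units

=== coupled regime ===
covariate-GLM significant clusters : 1
signature paired t(100) = 50.77, expression-rating r(99) = 0.994
LASSO-PCR held-out r = 0.993, RMSE = 0.27 VAS units
```

Both regimes show the within-individual intensity effect (the paired
signature t); only the coupled regime shows any between-individual
rating–activation relationship. That contrast — strong stimulus coding with
no between-person coupling — is the dissociation the package is built to
study.

## Examples and CLI

`examples/` contains one short narrative script per capability (cohort
simulation, class recovery, power fits, discrimination thresholds, the
brain-rating dissociation). The same stages are runnable from a shell:

```sh
painpsych run-all --out results/ --seed 1
painpsych simulate --out results/ --seed 1      # or stage by stage
painpsych classify --out results/
```

`run-all` writes class assignments, power-fit and threshold tables,
per-modality cluster tables, signature and LASSO-PCR summaries, and a
`findings.json` stating per modality whether a rating–activation
relationship was detected (defaults: heat/cold dissociated — none;
auditory coupled — detected).

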