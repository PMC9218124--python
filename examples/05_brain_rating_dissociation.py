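"""Reproduce the brain-rating dissociation on synthetic beta maps.

Generates beta maps in two regimes — *dissociated* (planted activation
identical across participants) and *coupled* (activation proportional to
each participant's rating) — and runs the three between-individual analyses
on each: voxelwise covariate GLM with permutation cluster inference,
signature expression + correlation, and LASSO-PCR rating prediction.
"""

from painpsych import CohortConfig, generate_beta_maps, generate_cohort
from painpsych.mass_univariate import fit_covariate_glm, paired_contrast
from painpsych.multivariate_brain import (
    expression_tests,
    lasso_pcr_fit,
    signature_expression,
    signature_from_planted,
)

dataset, truth = generate_cohort(CohortConfig(seed=1))
mri = dataset[(dataset.session == "MRI") & (dataset.modality == "heat")
              & (dataset.stimulus_level == 48.0)]
ratings = (mri.groupby("participant_id")["intensity_rating"].mean()
           .reindex(truth.participant_ids).to_numpy())

for regime in ("dissociated", "coupled"):
    maps = generate_beta_maps(truth, regime, seed=2)
    glm = fit_covariate_glm(maps["high"], ratings, n_perm=500, seed=3)
    paired = paired_contrast(maps["high"], maps["low"], n_perm=500, seed=4)
    sig = signature_from_planted(truth, maps["high"])
    nps = expression_tests(
        signature_expression(maps["high"], sig),
        signature_expression(maps["low"], sig),
        ratings,
    )
    model = lasso_pcr_fit(maps["high"], ratings, n_repeats=2, seed=5)
    print(f"\n=== {regime} regime ===")
    print(f"covariate-GLM significant clusters : {glm.n_significant_clusters}")
    print(f"paired high-vs-low clusters        : {paired.n_significant_clusters}")
    print(f"signature paired t({nps['paired_t']['df']}) = "
          f"{nps['paired_t']['t']:.2f}, expression-rating "
          f"r({nps['correlation']['df']}) = {nps['correlation']['r']:.3f}")
    print(f"LASSO-PCR held-out r = {model.pred_r:.3f}, "
          f"RMSE = {model.rmse:.2f} VAS units")

print(
    "\nIn both regimes the within-individual intensity effect is detected "
    "(paired clusters, signature t).  Only the coupled regime shows "
    "between-individual coupling: covariate clusters, a large expression-"
    "rating r, and LASSO-PCR predictive skill.  The dissociated regime "
    "mirrors a cohort whose ratings differ while their evoked activation "
    "does not."
)
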