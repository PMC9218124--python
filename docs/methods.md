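# Methods

`painpsych` implements a complete psychophysics + brain-imaging analysis
chain for studies of individual differences in pain, together with a
synthetic-data generator that provides ground truth for every stage. This
note documents the models, the conventions chosen where the design was
genuinely open, and what the synthetic results do and do not show.

## The rating model

Perceived magnitude of contact heat follows a Stevens power law. For a
stimulus at temperature `T` above a 35 °C neutral baseline, the noiseless
mean VAS rating is

    rating(T) = exp(b · ln(T − 35) + c),        clipped to [0, 10]

with an exponent `b` and a log-space proportionality constant `c`. Natural
logarithms are used throughout: the canonical class coefficient pairs (for
example `b = 2.93`, `c = −5.49` for the most sensitive class) produce
plausible VAS values at 48 °C (≈ 7.6) only under natural log; base-10 would
give ≈ 0.006. Ratings at or below baseline are defined as 0 — the baseline
temperature is rated but never fitted.

Trial noise is placed on `log(rating + ε)` with `ε = 0.01`, preserving the
multiplicative error structure that makes the double-log regression the
natural estimator and keeping the generator exactly invertible in the
noiseless limit. The noise law of real ratings is unknown; log-normal is a
modeling convention, not an inference about any particular dataset.

### Cohort defaults

The default cohort emulates a three-class design: 101 participants split
23/41/37 into High / Moderate / Low pain-sensitivity classes, each class
with its own `(b, c)` pair for pain intensity and pain unpleasantness
(unpleasantness curves steeper and lower, as observed empirically).
Familiarization delivers 8 temperatures (35, 43–49 °C) × 4 repetitions;
MRI-session tasks deliver heat 17 × 48 °C + 4 × 47 °C, cold 4 × 0.5 °C +
1 × 3 °C, and auditory 5 × 90 dB + 2 × 80 dB. Cold uses `ΔT = 35 − T`;
auditory uses `ΔL = level − 60 dB` with class-independent defaults.

Two between-subject variance sources exist and their sizes matter:

- `between_subject_sd = 0.05` shifts each participant's heat constant `c`.
  This shift scales all 14 familiarization features jointly — a covariance
  structure a *diagonal* Gaussian mixture cannot represent — so it must stay
  small relative to trial noise (`rating_noise_sd = 0.25`) or the latent
  classes become unidentifiable and mixture selection over-extracts
  (scanning 0 → 0.15 showed over-extraction from ≈ 0.10). Heat
  between-individual variance therefore comes mostly from the class
  structure itself, which already spans nearly the whole VAS at 48 °C.
- `modality_between_sd = 0.7` gives each participant an independent
  log-scale sensitivity per non-heat modality. Cold and loudness sensitivity
  are not class-determined, and the wide resulting ranges (roughly a factor
  of two around the modality median) match what such tasks elicit
  empirically (simulated heat 48 °C ratings ≈ 3.9 ± 2.4, auditory 90 dB
  ≈ 1.3 ± 1.1 at the defaults).

### Beta maps

Brain data are per-subject contrast amplitudes ("beta maps") on a 16³ voxel
grid (3 × 3 × 4 mm voxels) with an ellipsoidal analysis mask (~1470 voxels)
and a contiguous 4³ effect blob at the center. Two regimes define the ground
truth of the brain–rating relationship:

- **coupled** — planted amplitude `k · rating_i` per participant
  (`k = coupling_gain`, default 2.0), so the voxelwise slope on ratings is
  exactly `k` and the amplitude–rating correlation is 1 in the noiseless
  limit;
- **dissociated** — planted amplitude `k · mean(rating)` identical for all
  participants (zero amplitude variance, zero rating correlation).

In both regimes the high-intensity map receives an extra `intensity_gap`
(default 1.0) at the effect voxels, so within-individual stimulus effects
exist regardless of regime — this is the dissociation the package is built
to study: within-individual effects without between-individual coupling.
IID Gaussian voxel noise (default sd 1.0) is added everywhere. The default
`coupling_gain = 2 × noise sd` makes coupled effects comfortably detectable
at n ≈ 100 while leaving the dissociated regime an exact null.

The generator does not simulate hemodynamics, motion, physiological noise,
spatial autocorrelation, or session-order effects. Passing tests on these
maps show the *statistical machinery* is correct and calibrated under IID
noise; they say nothing about preprocessing adequacy or smoothness-dependent
corrections on real fMRI data.

## Sensitivity classes

Participants are described by 14 features: mean intensity and mean
unpleasantness at each noxious familiarization temperature (43–49 °C; the
baseline is excluded). Mixtures of K = 1…5 diagonal Gaussians are fitted by
EM (20 k-means++ restarts, variance floor 1e-6, tolerance 1e-8, ≤ 500
iterations; `sklearn.mixture.GaussianMixture` is the engine). Model choice
applies two rules in order: any model whose smallest class holds ≤ 10 % of
participants is eliminated as over-extraction; among survivors the lowest
BIC wins, with

    BIC = −2 log L + n_params · ln(n),   n_params = (K − 1) + 2 K d.

The parameter count is stated explicitly because BIC comparisons depend on
it; the BIC identity is re-verified independently in tests. Hard assignment
is by maximum responsibility (ties to the lowest component index). Classes
are named Low/Moderate/High by the grand mean of their component mean
vector, making labels invariant to component permutation. Absolute BIC
values from other software will differ (feature parameterization and
covariance structure are conventions); the selection *logic* is the
contract. Diagonal covariance is used because full 14 × 14 covariances per
class are ill-conditioned at n ≈ 100.

## Power-function fits

Class stimulus–response curves are fitted by OLS of `ln(mean rating)` on
`ln(T − 35)` over the 7 noxious temperatures: slope = exponent `b`,
intercept = constant `c`, with the standard regression F for the slope on
(1, n − 2) df. The class curve uses the mean over participants of
per-participant mean ratings (averaged, then logged — whether pooling or
averaging is the "right" convention is unknowable from published per-class
curves; averaged-then-logged is declared here). Temperatures with mean
rating ≤ 0 are dropped with a warning rather than offset (offsets bias the
exponent); fewer than 3 fittable points is an error. A flat response is
reported as slope 0 with F = 0. Noiseless generator output is recovered to
machine precision; with log-noise sd 0.15 at the 7 × 4 design the median
exponent error is well under 0.3.

## Discrimination thresholds

For each participant, familiarization trials are binarized against the mean
rating at a reference temperature — 43 °C ascending (trials strictly
*higher* count as 1), 49 °C descending (strictly *lower*) — and a logistic
regression of the indicator on absolute temperature (°C) is fitted. The
threshold is the temperature at which the fitted probability of reporting a
change is 0.5, i.e. `−intercept/slope`; using absolute temperature as the
predictor makes the ratio a temperature directly. Ties with the reference
count as 0 ("strictly higher/lower").

Degenerate patterns get explicit rules:

- every indicator 1 → the participant resolves steps smaller than the 1 °C
  grid; the threshold is set half a degree from the reference (43.5 °C
  ascending, 48.5 °C descending) without fitting;
- every indicator 0 → censored half a degree beyond the far end of the
  comparison range (49.5 / 42.5 °C), flagged — keeping such participants in
  group comparisons rather than dropping them;
- complete or quasi-complete separation (MLE undefined) → the midpoint
  between the warmest all-0 and coolest all-1 temperature, or the empirical
  0.5-crossing of per-temperature proportions when no clean split exists,
  flagged.

Fitted thresholds are *not* clamped to the half-degree edge values; the
edge rule applies only to the all-discriminated pattern. Thresholds are
compared across sensitivity classes with Kruskal–Wallis and post-hoc Dunn
tests, Bonferroni-adjusted over the three pairwise comparisons (the
adjustment method is a declared choice; "adjusted p" alone does not pin one
down).

## Voxelwise group analyses

All second-level models are OLS on per-subject beta maps (a mixed-effects
variance weighting would need the first-level variance maps, which the
contrast-map interface deliberately does not require). Per-voxel t
statistics are mapped to z through the normal quantile transform of the t
CDF (clipped at |z| = 37). Cluster inference thresholds |z| ≥ 3.1 (default),
labels contiguous suprathreshold voxels with 6-connectivity (the most
conservative standard choice), splits clusters by sign, and compares
observed cluster sizes with a permutation null of the maximum cluster size:

- covariate GLM (beta on mean-centered rating): permute the covariate;
- paired high-vs-low contrast: flip difference signs;
- class F and pairwise t contrasts: permute class labels.

Corrected p uses the add-one estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`
with `n_perm = 1000` by default (≥ 100 enforced). Permutation replaces
Gaussian-random-field correction because GRF requires smoothness estimation
that is undefined on synthetic IID grids, and permutation is exact under
exchangeability.

Two cluster summaries are available. The default compares cluster **size**
(voxel count) with the null maximum size. On spatially unsmoothed maps with
a high forming threshold, however, nearly every suprathreshold cluster is a
singleton; the max-size null is then tied at 1 and the achievable test
levels jump from well below to well above 0.05, making size-based inference
valid but very conservative (measured family-wise rate ≈ 0.003 at nominal
0.05 on white noise). Cluster **mass** (sum of |z| over the cluster) is
continuous, breaks those ties, and stays calibrated at the nominal level
(measured ≈ 0.045); it is the statistic used for exact-calibration checks
and recommended whenever maps are unsmoothed.

## Signature expression and LASSO-PCR

Signature expression is the dot product of a subject's beta vector with a
fixed voxel-weight pattern, restricted to the voxels in the signature's own
definition. The packaged signature builder is *synthetic* — unit weights on
the generator's planted blob — standing in for an empirically trained pain
signature so that expression scoring, the paired high-vs-low t (df = n − 1),
and the expression–rating correlation (df = n − 2) are fully testable.

LASSO-PCR predicts each subject's rating from their whole-brain map:
mean-center, project onto principal components (full rank,
`min(n_train − 1, n_voxels)` — the L1 penalty performs the selection),
and fit a LASSO on component scores. The penalty comes from an inner 5-fold
CV minimizing MSE over 50 log-spaced values from `λ_max` (all-zero
solution) down to `1e-3 · λ_max`, inside an outer 5-fold loop repeated 5
times; held-out data never influence penalty selection (audited by a
construction test). The cross-validation error is the per-repeat held-out
RMSE averaged over repeats, in VAS units, with MAE reported alongside
(RMSE is the declared primary since "cross-validation error" alone is
ambiguous).

The prediction–outcome correlation is computed on the *model-driven
component* of the held-out predictions (each prediction minus its fold's
fitted intercept). The intercept is a constant within its fold, and a
correlation is invariant to constant shifts — but fold-to-fold intercept
variation tracks the training-fold mean, which is anti-correlated with the
held-out outcomes; correlating raw CV predictions therefore carries a
negative artifact of about `−1/√(fold size)` (≈ −0.22 at n = 101 with 5
folds) whenever the penalty selects the null model. Removing the fold
intercepts eliminates the artifact (null mean r ≈ 0.00 in simulation)
without touching genuine signal; when every fold selects the null model the
prediction carries no information and r is defined as 0. RMSE and MAE are
always computed on the raw predictions. Voxel weights are back-projected
(`Vᵀ · coef`) from a final
full-data fit. Weight stability uses a subject bootstrap (default 5000
resamples, ≥ 100 enforced) refitting at the full-data penalty per sample —
re-estimating the penalty inside every bootstrap sample is prohibitively
expensive and not part of the procedure's definition — with
`z = mean/sd` per voxel.

## Shared statistics

Kruskal–Wallis H and Dunn z are computed from pooled average ranks with a
single shared tie-correction term `Σ(t³ − t)`; p-values use the χ²/normal
asymptotics (group sizes ~20–100). Fully tied data return H = 0, p = 1
rather than erroring, so pipelines survive pathological draws. Paired t on
identical vectors returns t = 0, p = 1; constant nonzero differences return
t = ±∞, p = 0 (flagged by the infinite statistic).

## Pipeline

`run_pipeline` chains simulate → classify → power fits → thresholds →
per-modality brain analyses and writes a findings file stating, per
modality, whether a rating–activation relationship was detected. Default
regimes are heat/cold dissociated and auditory coupled, and per-modality
missing-data counts (cold 28, auditory 4 of 101) reproduce differing
analysis ns; subjects are dropped per analysis, not listwise. A fixed seed
makes the full run byte-identical. The bootstrap stage is off by default in
`run-all` (`n_boot = 0`) to keep the end-to-end run desk-scale; it is a
first-class operation with its own default when called directly.

## Problem sizes in the test suite

The acceptance-style tests run at deliberately desk-scale sizes chosen as
the package's own verification budget: 50 simulated cohorts (n = 101) for
class recovery; 50 map simulations per regime with 300 permutations and
5 × 2 cross-validation for the dissociation reproduction; 400 null
simulations (n = 20 subjects, 12³ grid) for cluster-FWE calibration; 1000
null simulations each for Kruskal–Wallis and Pearson calibration; 100
random logistic datasets for the threshold oracle. Calibration rates are
checked against bands that account for binomial simulation error.

## Known limitations

- Synthetic beta maps are spatially white; smoothness-dependent behavior of
  cluster statistics on real fMRI is out of scope.
- The mixture model's absolute BIC values are parameterization-dependent
  and not comparable across software.
- The logistic threshold model has no lapse rate; a participant who
  discriminates at chance far above threshold would bias the fit.
- Power-law fits assume the baseline is exactly neutral (rating 0 at 35 °C);
  a nonzero baseline sensation would bias `c`.
- The generator's class coefficients are fixed constants, not resampled, so
  cross-seed variability reflects trial noise and class mixing only.
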