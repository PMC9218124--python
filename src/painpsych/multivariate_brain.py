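"""Multivariate brain-rating analyses: signature expression and LASSO-PCR.

*Signature expression* is the dot product of a subject's vectorized beta map
with a fixed voxel-weight pattern (the Neurologic-Pain-Signature style of
scoring), restricted to the voxels included in the signature definition.  A
positive expression means the subject's activation projects onto the
signature; within-individual intensity effects are tested with a paired t on
high-vs-low expressions and between-individual coupling with the Pearson
correlation between expression and mean rating.

*LASSO-PCR* predicts each subject's rating from their whole-brain beta map:
maps are mean-centered, projected onto principal components (full rank,
min(n_train - 1, n_voxels) components), and an L1-penalized regression is fit
on the component scores.  The penalty is chosen per training set by an inner
5-fold cross-validation minimizing mean squared error, inside an outer
k-fold loop repeated several times, so held-out predictions never influence
the penalty.  Component coefficients are back-projected to voxel space for an
interpretable weight map, and weight stability is assessed with a subject
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from . import group_stats
from .synthetic import BetaMapSet, SyntheticTruth

__all__ = [
    "SignatureWeights",
    "LassoPcrModel",
    "BootstrapWeights",
    "signature_expression",
    "expression_tests",
    "lasso_pcr_fit",
    "bootstrap_weights",
    "signature_from_planted",
]


@dataclass
class SignatureWeights:
    """A fixed voxel-weight pattern on the analysis grid.

    ``weights`` is aligned to the in-mask voxel vector of the analysis mask;
    ``signature_mask`` marks the voxels included in the signature definition
    (a subset of the analysis mask) — only those contribute to expression.
    """

    weights: np.ndarray
    signature_mask: np.ndarray  # boolean over in-mask voxels

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.signature_mask = np.asarray(self.signature_mask, dtype=bool)
        if self.weights.shape != self.signature_mask.shape:
            raise ValueError("weights and signature mask must be aligned")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("signature weights must be finite")


def signature_from_planted(
    truth: SyntheticTruth, maps: BetaMapSet, modality: str = "heat"
) -> SignatureWeights:
    """Synthetic signature aligned with the planted effect blob.

    Stands in for an empirically trained pain signature: unit weights at the
    generator's effect voxels, zero elsewhere, with the signature mask equal
    to the planted blob.
    """
    planted = truth.planted[modality]
    weights = np.zeros(maps.n_voxels)
    sig_mask = np.zeros(maps.n_voxels, dtype=bool)
    weights[planted.effect_voxels] = 1.0
    sig_mask[planted.effect_voxels] = True
    return SignatureWeights(weights=weights, signature_mask=sig_mask)


def signature_expression(
    beta_map: np.ndarray | BetaMapSet, weights: SignatureWeights
) -> float | np.ndarray:
    """Dot-product expression of a signature in one map or a map set.

    Only voxels inside the signature mask contribute.  For a
    :class:`BetaMapSet` the per-subject expression vector is returned.
    """
    if isinstance(beta_map, BetaMapSet):
        data = beta_map.data
    else:
        data = np.asarray(beta_map, dtype=float)
    if data.shape[-1] != weights.weights.shape[0]:
        raise ValueError(
            f"grid mismatch: map has {data.shape[-1]} voxels, "
            f"signature has {weights.weights.shape[0]}"
        )
    w = np.where(weights.signature_mask, weights.weights, 0.0)
    out = data @ w
    return float(out) if np.ndim(out) == 0 else out


def expression_tests(
    expressions_high: np.ndarray,
    expressions_low: np.ndarray,
    ratings: np.ndarray,
) -> dict:
    """Within-individual paired t (high vs. low) and expression-rating r."""
    expressions_high = np.asarray(expressions_high, dtype=float)
    expressions_low = np.asarray(expressions_low, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if not (expressions_high.shape == expressions_low.shape == ratings.shape):
        raise ValueError("expression and rating vectors must have matching lengths")
    t, t_df, t_p = group_stats.paired_t(expressions_high, expressions_low)
    r, r_df, r_p = group_stats.pearson_r(expressions_high, ratings)
    return {
        "paired_t": {"t": t, "df": t_df, "p": t_p},
        "correlation": {"r": r, "df": r_df, "p": r_p},
        "all_positive_high": bool(np.all(expressions_high > 0)),
    }


# ---------------------------------------------------------------------------
# LASSO-PCR


@dataclass
class LassoPcrModel:
    subject_ids: list[str]
    predictions: np.ndarray  # n_repeats x n, held-out predictions
    cv_predictions: np.ndarray  # n, mean over repeats
    rmse: float  # mean over repeats of per-repeat held-out RMSE, VAS units
    mae: float
    pred_r: float
    pred_r_p: float
    fold_assignments: np.ndarray  # n_repeats x n fold index
    selected_alphas: list[float]  # one per outer fold fit, in fit order
    full_alpha: float  # penalty of the final full-data fit
    voxel_weights: np.ndarray  # back-projected weight map (in-mask vector)
    loadings: np.ndarray = field(repr=False, default=None)  # components x voxels
    coef: np.ndarray = field(repr=False, default=None)  # penalized component coefs
    intercept: float = 0.0
    k_folds: int = 5
    n_repeats: int = 5


def _alpha_grid(scores: np.ndarray, y_c: np.ndarray, n_alphas: int, min_ratio: float) -> np.ndarray:
    n = scores.shape[0]
    alpha_max = np.max(np.abs(scores.T @ y_c)) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * min_ratio), n_alphas)


def _fit_pcr_lasso(
    x: np.ndarray,
    y: np.ndarray,
    inner_folds: int,
    n_alphas: int,
    min_ratio: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, Lasso, float, np.ndarray]:
    """Center -> PCA -> inner-CV penalized regression on one training set.

    Returns (x_mean, loadings Vt, fitted Lasso on scores, selected alpha,
    voxel weights).
    """
    x_mean = x.mean(axis=0)
    xc = x - x_mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    r = max(1, min(x.shape[0] - 1, x.shape[1]))
    u, s, vt = u[:, :r], s[:r], vt[:r]
    scores = u * s  # columns are centered because xc has zero column means

    y = np.asarray(y, dtype=float)
    y_c = y - y.mean()
    alphas = _alpha_grid(scores, y_c, n_alphas, min_ratio)

    n_eff = min(inner_folds, scores.shape[0])
    kf = KFold(n_splits=n_eff, shuffle=True, random_state=seed)
    mse = np.zeros((n_eff, alphas.size))
    for i, (tr, va) in enumerate(kf.split(scores)):
        t_tr, t_va = scores[tr], scores[va]
        y_tr, y_va = y[tr], y[va]
        tm, ym = t_tr.mean(axis=0), y_tr.mean()
        _, coefs, _ = lasso_path(t_tr - tm, y_tr - ym, alphas=alphas)
        preds = (t_va - tm) @ coefs + ym  # (n_va, n_alphas)
        mse[i] = np.mean((preds - y_va[:, None]) ** 2, axis=0)
    best = int(np.argmin(mse.mean(axis=0)))  # ties -> largest alpha (sparser)
    alpha = float(alphas[best])

    lasso = Lasso(alpha=alpha, fit_intercept=True, max_iter=10000)
    lasso.fit(scores, y)
    voxel_weights = vt.T @ lasso.coef_
    return x_mean, vt, lasso, alpha, voxel_weights


def lasso_pcr_fit(
    maps: BetaMapSet,
    ratings: np.ndarray,
    k_folds: int = 5,
    n_repeats: int = 5,
    n_alphas: int = 50,
    alpha_min_ratio: float = 1e-3,
    seed: int = 0,
) -> LassoPcrModel:
    """Nested cross-validated LASSO-PCR prediction of ratings from beta maps.

    Outer loop: ``k_folds``-fold splits repeated ``n_repeats`` times (every
    subject held out exactly once per repeat).  Inner loop: 5-fold CV on the
    training subjects selects the penalty minimizing MSE.  The reported
    cross-validation error is the per-repeat held-out RMSE averaged over
    repeats, in VAS units (MAE reported alongside); the weight map comes from
    a final fit on all subjects.
    """
    ratings = np.asarray(ratings, dtype=float)
    n = maps.n_subjects
    if ratings.size != n:
        raise ValueError("ratings length must equal the number of subjects")
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} subjects, have {n}")
    if ratings.std() == 0:
        raise ValueError("zero-variance ratings")
    if np.allclose(maps.data.std(axis=0), 0):
        raise ValueError("constant beta maps (zero variance)")

    rng = np.random.default_rng(seed)
    predictions = np.zeros((n_repeats, n))
    model_component = np.zeros((n_repeats, n))  # predictions minus fold intercept
    fold_assignments = np.zeros((n_repeats, n), dtype=int)
    selected: list[float] = []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(kf.split(maps.data)):
            x_mean, vt, lasso, alpha, _ = _fit_pcr_lasso(
                maps.data[tr], ratings[tr], inner_folds=5,
                n_alphas=n_alphas, min_ratio=alpha_min_ratio,
                seed=int(rng.integers(2**31 - 1)),
            )
            scores_te = (maps.data[te] - x_mean) @ vt.T
            predictions[rep, te] = lasso.predict(scores_te)
            model_component[rep, te] = predictions[rep, te] - lasso.intercept_
            fold_assignments[rep, te] = fold
            selected.append(alpha)

    per_repeat_rmse = np.sqrt(np.mean((predictions - ratings) ** 2, axis=1))
    per_repeat_mae = np.mean(np.abs(predictions - ratings), axis=1)
    cv_pred = predictions.mean(axis=0)
    # prediction-outcome correlation uses the model-driven part of each
    # prediction: the fold intercept is a constant shift within its fold, and
    # fold-to-fold intercept variation injects a negative fold-mean artifact
    # (about -1/sqrt(fold size) when the model is null) into a plain
    # correlation of raw held-out predictions
    cv_model = model_component.mean(axis=0)
    if cv_model.std() > 1e-12:
        pred_r, _, pred_p = group_stats.pearson_r(cv_model, ratings)
    else:  # null model in every fold: no predictive signal by definition
        pred_r, pred_p = 0.0, 1.0

    _, vt_full, lasso_full, alpha_full, w_full = _fit_pcr_lasso(
        maps.data, ratings, inner_folds=5,
        n_alphas=n_alphas, min_ratio=alpha_min_ratio,
        seed=int(rng.integers(2**31 - 1)),
    )
    return LassoPcrModel(
        subject_ids=list(maps.subject_ids),
        predictions=predictions,
        cv_predictions=cv_pred,
        rmse=float(per_repeat_rmse.mean()),
        mae=float(per_repeat_mae.mean()),
        pred_r=float(pred_r),
        pred_r_p=float(pred_p),
        fold_assignments=fold_assignments,
        selected_alphas=selected,
        full_alpha=alpha_full,
        voxel_weights=w_full,
        loadings=vt_full,
        coef=lasso_full.coef_,
        intercept=float(lasso_full.intercept_),
        k_folds=k_folds,
        n_repeats=n_repeats,
    )


@dataclass
class BootstrapWeights:
    z: np.ndarray
    p: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_boot: int


def bootstrap_weights(
    maps: BetaMapSet,
    ratings: np.ndarray,
    model: LassoPcrModel,
    n_boot: int = 5000,
    seed: int = 0,
) -> BootstrapWeights:
    """Subject bootstrap of the back-projected voxel weight map.

    Subjects are resampled with replacement and the full-data PCA + penalized
    fit is repeated per sample at the model's selected penalty; z is the
    ratio of the bootstrap mean to the bootstrap sd per voxel (defined as 0
    for voxels whose weight is zero in every sample).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratings = np.asarray(ratings, dtype=float)
    rng = np.random.default_rng(seed)
    n = maps.n_subjects
    samples = np.zeros((n_boot, maps.n_voxels))
    from scipy import stats as _stats

    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        x, y = maps.data[idx], ratings[idx]
        if y.std() == 0:
            continue  # degenerate resample: weights stay zero
        x_mean = x.mean(axis=0)
        u, s, vt = np.linalg.svd(x - x_mean, full_matrices=False)
        r = max(1, min(n - 1, maps.n_voxels))
        scores = u[:, :r] * s[:r]
        lasso = Lasso(alpha=model.full_alpha, fit_intercept=True, max_iter=10000)
        lasso.fit(scores, y)
        w = vt[:r].T @ lasso.coef_
        # back-projection leaves numerical dust on voxels no component loads;
        # zero it so never-selected voxels are exactly zero in every sample
        scale = np.max(np.abs(w))
        if scale > 0:
            w[np.abs(w) < 1e-12 * scale] = 0.0
        samples[b] = w

    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    z = np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0)
    p = 2.0 * _stats.norm.sf(np.abs(z))
    return BootstrapWeights(z=z, p=p, mean=mean, sd=sd, n_boot=n_boot)
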