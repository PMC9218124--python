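"""Pain-sensitivity class assignment via Gaussian mixture models.

Participants are described by 14 features: their mean pain-intensity and mean
pain-unpleasantness rating at each noxious familiarization temperature
(43-49 degC; the 35 degC baseline is excluded).  Mixtures with 1-5 diagonal
Gaussian components are fitted by EM with multiple k-means++ restarts, and the
reported model is chosen by two rules applied in order:

1. *spurious-class rule*: any model in which some class holds <= 10% of the
   participants is eliminated (over-extraction);
2. among survivors, the model with the lowest BIC wins, where
   BIC = -2 log L + n_params ln(n) and n_params = (K-1) + 2 K d for K diagonal
   Gaussians in d dimensions.

Classes are named Low / Moderate / High pain sensitivity by their grand-mean
rating level, so labels are invariant to component order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "FeatureMatrix",
    "ClassModel",
    "build_feature_matrix",
    "fit_mixture",
    "select_model",
    "label_classes",
    "classify_cohort",
]

NOXIOUS_TEMPS = (43.0, 44.0, 45.0, 46.0, 47.0, 48.0, 49.0)
SPURIOUS_FRACTION = 0.10


@dataclass
class FeatureMatrix:
    participant_ids: list[str]
    values: np.ndarray  # participants x features
    feature_names: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class ClassModel:
    """A fitted K-component diagonal Gaussian mixture."""

    k: int
    means: np.ndarray  # K x d
    variances: np.ndarray  # K x d (diagonal covariances)
    weights: np.ndarray  # K
    log_likelihood: float
    n_params: int
    bic: float
    responsibilities: np.ndarray  # n x K
    assignments: np.ndarray  # n, hard labels by max responsibility
    smallest_class_fraction: float
    seed: int | None = None


def build_feature_matrix(dataset: pd.DataFrame) -> FeatureMatrix:
    """Participant x 14 matrix of mean ratings at the noxious temperatures.

    Each cell is the mean over the familiarization repetitions; a participant
    missing any noxious temperature is an error naming participant and level.
    """
    fam = dataset[
        (dataset["session"] == "QST")
        & (dataset["modality"] == "heat")
        & (dataset["stimulus_level"].isin(NOXIOUS_TEMPS))
    ]
    if fam.empty:
        raise ValueError("dataset contains no familiarization trials")
    pids = sorted(fam["participant_id"].unique())
    grouped = fam.groupby(["participant_id", "stimulus_level"])[
        ["intensity_rating", "unpleasantness_rating"]
    ].mean()
    columns: list[str] = [
        f"{measure}_{int(t)}" for measure in ("intensity", "unpleasantness") for t in NOXIOUS_TEMPS
    ]
    values = np.empty((len(pids), len(columns)))
    for i, pid in enumerate(pids):
        for j, temp in enumerate(NOXIOUS_TEMPS):
            if (pid, temp) not in grouped.index:
                raise ValueError(
                    f"participant {pid} is missing familiarization trials at {temp} degC"
                )
            row = grouped.loc[(pid, temp)]
            values[i, j] = row["intensity_rating"]
            values[i, j + len(NOXIOUS_TEMPS)] = row["unpleasantness_rating"]
    return FeatureMatrix(participant_ids=pids, values=values, feature_names=columns)


def fit_mixture(
    features: FeatureMatrix,
    k: int,
    n_restarts: int = 20,
    seed: int | None = None,
) -> ClassModel:
    """Fit a K-component diagonal GMM, keeping the best of ``n_restarts``."""
    x = features.values
    n, d = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"cannot fit {k} classes to {n} participants")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        n_init=n_restarts,
        init_params="k-means++",
        reg_covar=1e-6,
        tol=1e-8,
        max_iter=500,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)
    if not np.all(np.isfinite(gm.covariances_)) or np.any(gm.covariances_ <= 0):
        raise ValueError("singular covariance after regularization")
    loglik = float(gm.score(x) * n)
    n_params = (k - 1) + 2 * k * d
    bic = -2.0 * loglik + n_params * np.log(n)
    resp = gm.predict_proba(x)
    assignments = np.argmax(resp, axis=1)  # argmax breaks ties at lowest index
    counts = np.bincount(assignments, minlength=k)
    return ClassModel(
        k=k,
        means=gm.means_,
        variances=gm.covariances_,
        weights=gm.weights_,
        log_likelihood=loglik,
        n_params=n_params,
        bic=float(bic),
        responsibilities=resp,
        assignments=assignments,
        smallest_class_fraction=float(counts.min() / n),
        seed=seed,
    )


def select_model(
    models: list[ClassModel], spurious_fraction: float = SPURIOUS_FRACTION
) -> ClassModel:
    """Spurious-class elimination followed by minimum-BIC selection."""
    if not models:
        raise ValueError("no models to select from")
    survivors = [m for m in models if m.smallest_class_fraction > spurious_fraction]
    if not survivors:
        raise ValueError(
            "every candidate model has a spurious class "
            f"(<= {spurious_fraction:.0%} of participants)"
        )
    return min(survivors, key=lambda m: m.bic)


def label_classes(model: ClassModel, features: FeatureMatrix | None = None) -> dict[int, str]:
    """Name components Low/Moderate/High sensitivity by ascending rating level.

    The ordering statistic is the grand mean of the component mean vector, so
    the labels are invariant to permutations of the fitted components.
    """
    grand = model.means.mean(axis=1)
    order = np.argsort(grand, kind="stable")
    if len(set(np.round(grand, 12))) < model.k:
        warnings.warn("tied class grand means; breaking ties by component index")
    if model.k == 1:
        names = ["Moderate"]
    elif model.k == 2:
        names = ["Low", "High"]
    elif model.k == 3:
        names = ["Low", "Moderate", "High"]
    else:
        names = [f"Class{i + 1}" for i in range(model.k)]
    return {int(comp): names[rank] for rank, comp in enumerate(order)}


def classify_cohort(
    dataset: pd.DataFrame,
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_restarts: int = 20,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ClassModel, list[ClassModel]]:
    """End-to-end class assignment for a rating dataset.

    Fits every K in ``k_range``, applies the spurious + BIC selection, labels
    the chosen components, and returns (assignment table, selected model, all
    candidate models).
    """
    features = build_feature_matrix(dataset)
    models = [fit_mixture(features, k, n_restarts=n_restarts, seed=seed) for k in k_range]
    best = select_model(models)
    labels = label_classes(best, features)
    table = pd.DataFrame(
        {
            "participant_id": features.participant_ids,
            "class_label": [labels[int(a)] for a in best.assignments],
            "max_responsibility": best.responsibilities.max(axis=1),
        }
    )
    return table, best, models
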