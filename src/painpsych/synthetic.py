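"""Synthetic psychophysics cohorts and voxelwise beta maps with known ground truth.

The generator emulates a quantitative-sensory-testing (QST) study design:
a familiarization block of graded 5-s contact-heat stimuli (35-49 degC, four
repetitions each) rated on 0-10 visual analog scales (VAS) for both pain
intensity and pain unpleasantness, followed by MRI-session tasks with a high
and a low stimulus level per modality (heat 48/47 degC, cold 0.5/3 degC,
auditory 90/80 dB).

Ratings follow a Stevens power law: the mean rating at a stimulus increment
``dT`` above baseline is ``exp(b * ln(dT) + c)`` with a class-specific
exponent ``b`` and log-space proportionality constant ``c`` (natural log
throughout).  Trial noise is multiplicative (log-normal on ``rating + eps``)
so the double-log regression used downstream remains the natural estimator.

Brain "beta" maps (per-subject contrast amplitudes on a small 3-D grid) carry
a planted effect blob whose amplitude is either proportional to each
participant's rating (*coupled* regime) or identical across participants
(*dissociated* regime); high-intensity maps always receive a strictly larger
planted amplitude than low-intensity maps, so within-individual stimulus
effects exist in both regimes while between-individual rating coupling exists
only in the coupled one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassParams",
    "CohortConfig",
    "SyntheticTruth",
    "PlantedEffect",
    "BetaMapSet",
    "rating_model",
    "generate_cohort",
    "generate_beta_maps",
    "ellipsoid_mask",
    "DEFAULT_CLASS_PARAMS",
    "FAMILIARIZATION_TEMPS",
    "MRI_TRIAL_DESIGN",
    "HEAT_BASELINE_C",
]

HEAT_BASELINE_C = 35.0
COLD_BASELINE_C = 35.0
AUDITORY_BASELINE_DB = 60.0
#: offset used when noise is applied on log(rating + eps)
LOG_NOISE_EPS = 0.01
VAS_MAX = 10.0

FAMILIARIZATION_TEMPS: tuple[float, ...] = (35.0, 43.0, 44.0, 45.0, 46.0, 47.0, 48.0, 49.0)
FAMILIARIZATION_REPS = 4

#: MRI-task trial design: modality -> condition -> (stimulus level, repetitions)
MRI_TRIAL_DESIGN: dict[str, dict[str, tuple[float, int]]] = {
    "heat": {"high": (48.0, 17), "low": (47.0, 4)},
    "cold": {"high": (0.5, 4), "low": (3.0, 1)},
    "auditory": {"high": (90.0, 5), "low": (80.0, 2)},
}

RATING_COLUMNS = [
    "participant_id",
    "session",
    "modality",
    "stimulus_level",
    "repetition_index",
    "intensity_rating",
    "unpleasantness_rating",
]


@dataclass(frozen=True)
class ClassParams:
    """Power-function coefficients of one latent pain-sensitivity class.

    ``intensity`` and ``unpleasantness`` each hold ``(exponent b, constant c)``
    of the heat stimulus-response curve in double-natural-log space.
    """

    name: str
    intensity: tuple[float, float]
    unpleasantness: tuple[float, float]


#: Default three-class cohort: coefficient pairs of the High / Moderate / Low
#: pain-sensitivity stimulus-response curves.
DEFAULT_CLASS_PARAMS: tuple[ClassParams, ...] = (
    ClassParams("High", intensity=(2.93, -5.49), unpleasantness=(3.45, -6.88)),
    ClassParams("Moderate", intensity=(4.46, -10.02), unpleasantness=(5.12, -11.84)),
    ClassParams("Low", intensity=(3.88, -9.79), unpleasantness=(4.74, -12.10)),
)

#: Default class mixing proportions (High, Moderate, Low) for n = 101.
DEFAULT_PROPORTIONS: tuple[float, ...] = (23 / 101, 41 / 101, 37 / 101)

#: Class-independent cold stimulus-response defaults (dT = 35 - level).
COLD_PARAMS = {"intensity": (2.5, -7.93), "unpleasantness": (2.5, -8.40)}
#: Class-independent auditory defaults (dL = level - 60 dB).
AUDITORY_PARAMS = {"intensity": (2.0, -6.80), "unpleasantness": (2.0, -7.30)}


class ConfigurationError(ValueError):
    """Raised when a cohort or pipeline configuration violates an invariant."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design configuration of a synthetic cohort.

    Parameters
    ----------
    n_participants
        Cohort size (default 101).
    class_proportions
        Mixing weights over the sensitivity classes; must sum to one.
    class_params
        One :class:`ClassParams` per class, same order as the proportions.
    rating_noise_sd
        Trial-to-trial noise sd on the log-response scale (log VAS units).
    between_subject_sd
        Sd of the per-participant shift of the log-space constant ``c``
        (a participant-level sensitivity scaling shared across measures).
        The default is deliberately small relative to the trial noise: the
        shift scales every feature of a participant together, which a
        diagonal-covariance mixture cannot represent, so a large value makes
        the latent classes unidentifiable to the downstream class analysis.
    modality_between_sd
        Sd of the independent per-participant log-scale sensitivity shift for
        the non-heat modalities (cold, auditory).  Heat between-individual
        variance comes mostly from the class structure; cold and loudness
        sensitivity are not class-determined, so they get their own wide
        individual spread (ratings varying by roughly a factor of two around
        the modality median, matching the wide ranges such tasks elicit).
    seed
        Seed for all randomness; identical seeds give byte-identical output.
    familiarization_temps, familiarization_reps, trial_design
        The stimulus grids; defaults reproduce the study design above.
    """

    n_participants: int = 101
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    class_params: tuple[ClassParams, ...] = DEFAULT_CLASS_PARAMS
    rating_noise_sd: float = 0.25
    between_subject_sd: float = 0.05
    modality_between_sd: float = 0.7
    seed: int = 0
    familiarization_temps: tuple[float, ...] = FAMILIARIZATION_TEMPS
    familiarization_reps: int = FAMILIARIZATION_REPS
    trial_design: Mapping[str, Mapping[str, tuple[float, int]]] = field(
        default_factory=lambda: {m: dict(d) for m, d in MRI_TRIAL_DESIGN.items()}
    )

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if len(self.class_proportions) != len(self.class_params):
            raise ConfigurationError("class_proportions and class_params length mismatch")
        total = float(np.sum(self.class_proportions))
        if abs(total - 1.0) > 1e-12 or np.any(np.asarray(self.class_proportions) < 0):
            raise ConfigurationError(
                f"class_proportions must be a simplex (sum 1), got sum {total!r}"
            )
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd must be >= 0")
        if self.familiarization_reps < 1:
            raise ConfigurationError("familiarization repetition count must be >= 1")
        for modality, design in self.trial_design.items():
            for cond, (_, reps) in design.items():
                if reps < 1:
                    raise ConfigurationError(
                        f"repetition count must be >= 1 ({modality}/{cond})"
                    )

    def class_counts(self) -> np.ndarray:
        """Deterministic per-class counts via largest-remainder rounding."""
        raw = np.asarray(self.class_proportions) * self.n_participants
        counts = np.floor(raw).astype(int)
        remainder = self.n_participants - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
        return counts


@dataclass
class PlantedEffect:
    """Ground truth of a planted brain effect for one modality."""

    regime: str
    modality: str
    effect_voxels: np.ndarray  # indices into the in-mask voxel vector
    amplitude_high: np.ndarray  # per participant
    amplitude_low: np.ndarray


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    participant_ids: list[str]
    class_labels: list[str]
    params: dict[str, dict[str, tuple[float, float]]]  # pid -> measure -> (b, c)
    clean_ratings: dict[str, dict[str, dict[str, float]]]  # pid -> modality -> cond -> VAS
    seed: int
    planted: dict[str, PlantedEffect] = field(default_factory=dict)

    def clean_rating_vector(self, modality: str, condition: str) -> np.ndarray:
        return np.array(
            [self.clean_ratings[pid][modality][condition] for pid in self.participant_ids]
        )

    def to_jsonable(self) -> dict:
        out = {
            "participant_ids": self.participant_ids,
            "class_labels": self.class_labels,
            "params": self.params,
            "clean_ratings": self.clean_ratings,
            "seed": self.seed,
            "planted": {
                m: {
                    "regime": p.regime,
                    "modality": p.modality,
                    "effect_voxels": p.effect_voxels.tolist(),
                    "amplitude_high": p.amplitude_high.tolist(),
                    "amplitude_low": p.amplitude_low.tolist(),
                }
                for m, p in self.planted.items()
            },
        }
        return out

    @classmethod
    def from_jsonable(cls, obj: Mapping) -> "SyntheticTruth":
        truth = cls(
            participant_ids=list(obj["participant_ids"]),
            class_labels=list(obj["class_labels"]),
            params={
                pid: {m: tuple(v) for m, v in d.items()} for pid, d in obj["params"].items()
            },
            clean_ratings={
                pid: {m: dict(c) for m, c in d.items()}
                for pid, d in obj["clean_ratings"].items()
            },
            seed=int(obj["seed"]),
        )
        for m, p in obj.get("planted", {}).items():
            truth.planted[m] = PlantedEffect(
                regime=p["regime"],
                modality=p["modality"],
                effect_voxels=np.asarray(p["effect_voxels"], dtype=int),
                amplitude_high=np.asarray(p["amplitude_high"], dtype=float),
                amplitude_low=np.asarray(p["amplitude_low"], dtype=float),
            )
        return truth


def rating_model(
    stimulus_level: float,
    baseline: float = HEAT_BASELINE_C,
    exponent: float = 1.0,
    constant: float = 0.0,
) -> float:
    """Noiseless power-law VAS rating for a stimulus increment above baseline.

    ``rating = exp(b * ln(level - baseline) + c)``, clipped to [0, 10].
    The baseline itself (and anything below it) is rated 0 by convention.
    """
    delta = stimulus_level - baseline
    if delta <= 0:
        return 0.0
    return float(min(np.exp(exponent * np.log(delta) + constant), VAS_MAX))


def _noisy_rating(clean: float, sd: float, rng: np.random.Generator) -> float:
    """Apply multiplicative (log-scale) noise and clip to the VAS range."""
    if sd == 0:
        return float(np.clip(clean, 0.0, VAS_MAX))
    value = np.exp(np.log(clean + LOG_NOISE_EPS) + rng.normal(0.0, sd)) - LOG_NOISE_EPS
    return float(np.clip(value, 0.0, VAS_MAX))


def _stimulus_delta(modality: str, level: float) -> float:
    if modality == "heat":
        return level - HEAT_BASELINE_C
    if modality == "cold":
        return COLD_BASELINE_C - level
    if modality == "auditory":
        return level - AUDITORY_BASELINE_DB
    raise ValueError(f"unknown modality {modality!r}")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the full rating dataset of a cohort.

    Returns the long-format trial table (one row per stimulus, both VAS
    measures as columns) and the :class:`SyntheticTruth` needed for recovery
    tests.  The table holds the complete familiarization grid plus the
    MRI-session trials of every modality in ``config.trial_design``.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    class_idx = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(class_idx)

    n = config.n_participants
    width = max(3, len(str(n)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]

    params: dict[str, dict[str, tuple[float, float]]] = {}
    clean: dict[str, dict[str, dict[str, float]]] = {}
    labels: list[str] = []
    rows: list[tuple] = []

    for pid, ci in zip(pids, class_idx):
        cls = config.class_params[ci]
        labels.append(cls.name)
        shift = rng.normal(0.0, config.between_subject_sd) if config.between_subject_sd else 0.0
        p_params = {
            "intensity": (cls.intensity[0], cls.intensity[1] + shift),
            "unpleasantness": (cls.unpleasantness[0], cls.unpleasantness[1] + shift),
        }
        params[pid] = p_params
        clean[pid] = {}

        # QST familiarization: heat only, both measures per trial
        for temp in config.familiarization_temps:
            for rep in range(1, config.familiarization_reps + 1):
                vals = {}
                for measure in ("intensity", "unpleasantness"):
                    b, c = p_params[measure]
                    vals[measure] = _noisy_rating(
                        rating_model(temp, HEAT_BASELINE_C, b, c),
                        config.rating_noise_sd,
                        rng,
                    )
                rows.append(
                    (pid, "QST", "heat", temp, rep, vals["intensity"], vals["unpleasantness"])
                )

        # MRI-session tasks
        modality_shift = {
            m: (rng.normal(0.0, config.modality_between_sd)
                if (m != "heat" and config.modality_between_sd) else 0.0)
            for m in config.trial_design
        }
        for modality, design in config.trial_design.items():
            clean[pid][modality] = {}
            for cond in ("high", "low"):
                level, reps = design[cond]
                delta = _stimulus_delta(modality, level)
                cond_clean = {}
                for measure in ("intensity", "unpleasantness"):
                    if modality == "heat":
                        b, c = p_params[measure]
                    else:
                        base = COLD_PARAMS if modality == "cold" else AUDITORY_PARAMS
                        b, c0 = base[measure]
                        c = c0 + modality_shift[modality]
                    if delta <= 0:
                        cond_clean[measure] = 0.0
                    else:
                        cond_clean[measure] = float(
                            min(np.exp(b * np.log(delta) + c), VAS_MAX)
                        )
                clean[pid][modality][cond] = cond_clean["intensity"]
                for rep in range(1, reps + 1):
                    ri = _noisy_rating(cond_clean["intensity"], config.rating_noise_sd, rng)
                    ru = _noisy_rating(
                        cond_clean["unpleasantness"], config.rating_noise_sd, rng
                    )
                    rows.append((pid, "MRI", modality, level, rep, ri, ru))

    dataset = pd.DataFrame(rows, columns=RATING_COLUMNS)
    truth = SyntheticTruth(
        participant_ids=pids,
        class_labels=labels,
        params=params,
        clean_ratings=clean,
        seed=config.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Beta maps


@dataclass
class BetaMapSet:
    """Per-subject voxelwise contrast amplitudes for one condition.

    ``data`` is subjects x in-mask voxels; ``mask`` is the 3-D boolean grid
    that defines the column order (C-order scan of True voxels).
    """

    data: np.ndarray
    mask: np.ndarray
    subject_ids: list[str]
    condition: str = ""
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (subjects x voxels)")
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("row count != number of subject ids")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta maps contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask voxel vector back onto the 3-D grid."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol


def ellipsoid_mask(
    shape: tuple[int, int, int] = (16, 16, 16),
    radii: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Boolean ellipsoidal analysis mask centered on the grid."""
    if radii is None:
        radii = tuple(s / 2.0 - 1.0 for s in shape)
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist <= 1.0


def _effect_blob_indices(mask: np.ndarray, side: int = 4) -> np.ndarray:
    """In-mask flat indices of a contiguous side**3 cube at the mask center."""
    shape = mask.shape
    start = [max(0, s // 2 - side // 2) for s in shape]
    blob = np.zeros(shape, dtype=bool)
    blob[
        start[0] : start[0] + side,
        start[1] : start[1] + side,
        start[2] : start[2] + side,
    ] = True
    blob &= mask
    if not blob.any():
        raise ValueError("effect blob does not intersect the mask")
    flat_positions = np.flatnonzero(blob[mask])
    return flat_positions


def generate_beta_maps(
    truth: SyntheticTruth,
    regime: str,
    modality: str = "heat",
    noise_sd: float = 1.0,
    coupling_gain: float = 2.0,
    intensity_gap: float = 1.0,
    shape: tuple[int, int, int] = (16, 16, 16),
    mask: np.ndarray | None = None,
    effect_side: int = 4,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> dict[str, BetaMapSet]:
    """Simulate high- and low-condition beta maps under a coupling regime.

    In the *coupled* regime the planted effect amplitude is
    ``coupling_gain * clean_high_rating`` per participant (so the voxel slope
    on ratings equals ``coupling_gain``); in the *dissociated* regime it is a
    constant ``coupling_gain * mean(clean_high_rating)`` for everyone.  High
    maps receive an extra ``intensity_gap`` at the effect voxels so paired
    high-vs-low contrasts are positive in both regimes.  IID Gaussian voxel
    noise with sd ``noise_sd`` is added everywhere.
    """
    if regime not in {"coupled", "dissociated"}:
        raise ValueError(f"regime must be 'coupled' or 'dissociated', got {regime!r}")
    if mask is None:
        mask = ellipsoid_mask(shape)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if subject_ids is None:
        subject_ids = truth.participant_ids
    subject_ids = list(subject_ids)

    ratings = np.array(
        [truth.clean_ratings[pid][modality]["high"] for pid in subject_ids]
    )
    n, n_vox = len(subject_ids), int(mask.sum())
    effect_idx = _effect_blob_indices(mask, side=effect_side)

    if regime == "coupled":
        base = coupling_gain * ratings
    else:
        base = np.full(n, coupling_gain * float(ratings.mean()))
    amp_high = base + intensity_gap
    amp_low = base.copy()

    rng = np.random.default_rng(seed)
    out: dict[str, BetaMapSet] = {}
    for cond, amp in (("high", amp_high), ("low", amp_low)):
        data = rng.normal(0.0, noise_sd, size=(n, n_vox)) if noise_sd > 0 else np.zeros((n, n_vox))
        data[:, effect_idx] += amp[:, None]
        out[cond] = BetaMapSet(
            data=data, mask=mask, subject_ids=subject_ids, condition=cond
        )
    truth.planted[modality] = PlantedEffect(
        regime=regime,
        modality=modality,
        effect_voxels=effect_idx,
        amplitude_high=amp_high,
        amplitude_low=amp_low,
    )
    return out
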