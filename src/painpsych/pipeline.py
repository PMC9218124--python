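"""End-to-end orchestration: simulate -> classify -> fit -> thresholds -> brain.

``run_pipeline`` executes the whole analysis on a synthetic cohort and writes
every stage's output to disk, ending with a ``findings.json`` that states,
per modality, whether a between-individual rating-activation relationship was
detected.  Under the default regimes (heat and cold dissociated, auditory
coupled) the expected pattern is: no covariate clusters for heat or cold,
at least one for auditory — within-individual intensity effects present in
all three.

Every stage is also runnable standalone from files on disk via the functions
in this module (and the thin CLI in :mod:`painpsych.cli`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import group_stats
from .discrimination import compare_thresholds, discrimination_table
from .mass_univariate import class_contrasts, fit_covariate_glm, paired_contrast
from .multivariate_brain import (
    bootstrap_weights,
    expression_tests,
    lasso_pcr_fit,
    signature_expression,
    signature_from_planted,
)
from .power_fit import class_power_table, compare_exponents
from .sensitivity_classes import classify_cohort
from .synthetic import (
    BetaMapSet,
    CohortConfig,
    ConfigurationError,
    SyntheticTruth,
    generate_beta_maps,
    generate_cohort,
)

logger = logging.getLogger("painpsych")

__all__ = ["PipelineConfig", "run_pipeline"]

#: modality -> coupling regime reproducing the study's empirical pattern
DEFAULT_REGIMES = {"heat": "dissociated", "cold": "dissociated", "auditory": "coupled"}
#: per-modality counts of participants with missing MRI data
DEFAULT_MISSING = {"heat": 0, "cold": 28, "auditory": 4}


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    regimes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGIMES))
    missing: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MISSING))
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    brain_noise_sd: float = 1.0
    coupling_gain: float = 2.0
    intensity_gap: float = 1.0
    z_thresh: float = 3.1
    alpha: float = 0.05
    k_folds: int = 5
    n_repeats: int = 5
    n_perm: int = 1000
    n_boot: int = 0  # 0 disables the bootstrap stage in run-all
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds > self.cohort.n_participants:
            raise ConfigurationError(
                f"k_folds={self.k_folds} exceeds n_participants={self.cohort.n_participants}"
            )
        for m, r in self.regimes.items():
            if r not in {"coupled", "dissociated"}:
                raise ConfigurationError(f"unknown regime {r!r} for modality {m!r}")
        for m, k in self.missing.items():
            if k < 0 or k >= self.cohort.n_participants:
                raise ConfigurationError(f"invalid missing count {k} for modality {m!r}")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["class_params"] = [dataclasses.asdict(c) for c in self.cohort.class_params]
        return d

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj or {})
        cohort_d = dict(obj.pop("cohort", {}))
        if "class_params" in cohort_d:
            from .synthetic import ClassParams

            cohort_d["class_params"] = tuple(
                ClassParams(
                    name=c["name"],
                    intensity=tuple(c["intensity"]),
                    unpleasantness=tuple(c["unpleasantness"]),
                )
                for c in cohort_d["class_params"]
            )
        for key in ("class_proportions", "familiarization_temps"):
            if key in cohort_d:
                cohort_d[key] = tuple(cohort_d[key])
        cohort = CohortConfig(**cohort_d)
        if "grid_shape" in obj:
            obj["grid_shape"] = tuple(obj["grid_shape"])
        return cls(cohort=cohort, **obj)


def _modality_subjects(
    truth: SyntheticTruth, modality: str, missing: int, seed: int
) -> list[str]:
    """Subjects retained for one modality after seeded missing-data dropping."""
    pids = list(truth.participant_ids)
    if missing <= 0:
        return pids
    rng = np.random.default_rng(seed + sum(ord(c) for c in modality))
    drop = set(rng.choice(len(pids), size=missing, replace=False).tolist())
    kept = [p for i, p in enumerate(pids) if i not in drop]
    logger.info("%s: dropping %d subjects with missing data, %d remain",
                modality, missing, len(kept))
    return kept


def _mean_high_ratings(dataset: pd.DataFrame, modality: str, subjects: list[str],
                       level: float) -> np.ndarray:
    sub = dataset[
        (dataset["session"] == "MRI")
        & (dataset["modality"] == modality)
        & (dataset["stimulus_level"] == level)
    ]
    means = sub.groupby("participant_id")["intensity_rating"].mean()
    return means.reindex(subjects).to_numpy()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_yaml(config.to_jsonable(), out / "config_snapshot.yaml")

    # --- simulate -----------------------------------------------------------
    logger.info("simulating cohort of %d participants (seed %d)",
                config.cohort.n_participants, config.cohort.seed)
    dataset, truth = generate_cohort(config.cohort)
    pio.write_ratings_csv(dataset, out / "ratings.csv")

    maps: dict[str, dict[str, BetaMapSet]] = {}
    for i, (modality, regime) in enumerate(sorted(config.regimes.items())):
        subjects = _modality_subjects(truth, modality, config.missing.get(modality, 0),
                                      config.seed)
        maps[modality] = generate_beta_maps(
            truth,
            regime=regime,
            modality=modality,
            noise_sd=config.brain_noise_sd,
            coupling_gain=config.coupling_gain,
            intensity_gap=config.intensity_gap,
            shape=config.grid_shape,
            seed=config.seed + 101 + i,
            subject_ids=subjects,
        )
        for cond, ms in maps[modality].items():
            pio.write_beta_maps(ms, out / f"beta_{modality}_{cond}")
    pio.write_truth_json(truth, out / "truth.json")

    # --- sensitivity classes ------------------------------------------------
    logger.info("fitting mixture models (K=1..5)")
    assignments, best, models = classify_cohort(dataset, seed=config.seed)
    assignments.to_csv(out / "class_assignments.csv", index=False)
    pio.write_json(
        {
            "selected_k": best.k,
            "bic_table": {str(m.k): m.bic for m in models},
            "smallest_class_fraction": {str(m.k): m.smallest_class_fraction for m in models},
        },
        out / "class_model_summary.json",
    )
    class_labels = dict(zip(assignments["participant_id"], assignments["class_label"]))

    # --- power functions ----------------------------------------------------
    power_table, fits = class_power_table(dataset, class_labels)
    power_table.to_csv(out / "power_fits.csv", index=False)
    compare_exponents(fits).to_csv(out / "power_exponent_comparison.csv", index=False)

    # --- discrimination thresholds -----------------------------------------
    logger.info("estimating discrimination thresholds")
    thresholds = discrimination_table(dataset)
    thresholds.to_csv(out / "thresholds.csv", index=False)
    pio.write_json(compare_thresholds(thresholds, class_labels),
                   out / "threshold_comparisons.json")

    # --- brain analyses -----------------------------------------------------
    findings: dict[str, dict] = {}
    for modality in sorted(config.regimes):
        high, low = maps[modality]["high"], maps[modality]["low"]
        level_high = config.cohort.trial_design[modality]["high"][0]
        ratings = _mean_high_ratings(dataset, modality, high.subject_ids, level_high)
        logger.info("%s: covariate GLM on %d subjects, %d voxels",
                    modality, high.n_subjects, high.n_voxels)
        glm = fit_covariate_glm(
            high, ratings, z_thresh=config.z_thresh, alpha=config.alpha,
            n_perm=config.n_perm, seed=config.seed + 7,
        )
        glm.cluster_table.to_csv(out / f"glm_covariate_clusters_{modality}.csv", index=False)
        paired = paired_contrast(
            high, low, z_thresh=config.z_thresh, alpha=config.alpha,
            n_perm=config.n_perm, seed=config.seed + 11,
        )
        paired.cluster_table.to_csv(out / f"paired_contrast_clusters_{modality}.csv", index=False)
        findings[modality] = {
            "regime": config.regimes[modality],
            "n_subjects": high.n_subjects,
            "covariate_clusters": glm.n_significant_clusters,
            "rating_activation_relationship": glm.n_significant_clusters > 0,
            "paired_clusters": paired.n_significant_clusters,
            "within_individual_intensity_effect": paired.n_significant_clusters > 0,
        }

    # heat-specific confirmatory analyses
    heat_high, heat_low = maps["heat"]["high"], maps["heat"]["low"]
    heat_ratings = _mean_high_ratings(
        dataset, "heat", heat_high.subject_ids, config.cohort.trial_design["heat"]["high"][0]
    )
    sig = signature_from_planted(truth, heat_high, modality="heat")
    expr_high = signature_expression(heat_high, sig)
    expr_low = signature_expression(heat_low, sig)
    nps = expression_tests(expr_high, expr_low, heat_ratings)
    pio.write_json(nps, out / "signature_expression_heat.json")

    logger.info("heat: LASSO-PCR (%d folds x %d repeats)", config.k_folds, config.n_repeats)
    lasso = lasso_pcr_fit(
        heat_high, heat_ratings, k_folds=config.k_folds,
        n_repeats=config.n_repeats, seed=config.seed + 13,
    )
    pd.DataFrame(
        {
            "participant_id": lasso.subject_ids,
            "rating": heat_ratings,
            "cv_prediction": lasso.cv_predictions,
        }
    ).to_csv(out / "lasso_pcr_predictions.csv", index=False)
    pio.write_json(
        {
            "rmse_vas": lasso.rmse,
            "mae_vas": lasso.mae,
            "pred_r": lasso.pred_r,
            "pred_r_p": lasso.pred_r_p,
            "selected_alphas": lasso.selected_alphas,
        },
        out / "lasso_pcr_summary.json",
    )
    if config.n_boot >= 100:
        boot = bootstrap_weights(heat_high, heat_ratings, lasso,
                                 n_boot=config.n_boot, seed=config.seed + 17)
        np.savetxt(out / "bootstrap_weight_z.csv", boot.z, delimiter=",")

    # between-class brain contrasts on heat
    heat_labels = {pid: class_labels[pid] for pid in heat_high.subject_ids}
    logger.info("heat: between-class contrasts")
    cc = class_contrasts(
        heat_high, heat_labels, z_thresh=config.z_thresh, alpha=config.alpha,
        n_perm=config.n_perm, seed=config.seed + 19,
    )
    cc.f_cluster_table.to_csv(out / "class_F_clusters_heat.csv", index=False)
    class_cluster_counts = {
        key: int(tab["significant"].sum()) if not tab.empty else 0
        for key, tab in cc.pairwise.items()
    }

    findings["heat"].update(
        {
            "nps_paired_t": nps["paired_t"],
            "nps_correlation": nps["correlation"],
            "lasso_pcr": {"rmse_vas": lasso.rmse, "pred_r": lasso.pred_r},
            "class_F_clusters": int(cc.f_cluster_table["significant"].sum())
            if not cc.f_cluster_table.empty else 0,
            "class_pairwise_clusters": class_cluster_counts,
        }
    )
    findings["selected_k"] = best.k
    pio.write_json(findings, out / "findings.json")
    logger.info("pipeline complete; findings written to %s", out / "findings.json")
    return findings
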