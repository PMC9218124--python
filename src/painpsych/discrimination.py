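"""Rating-based discrimination thresholds and their comparison across classes.

A participant's ability to report small temperature differences is estimated
from the familiarization ratings.  Relative to a reference temperature
(43 degC when stepping up, 49 degC when stepping down), each trial at every
other noxious temperature is binarized: 1 if it was rated strictly more
intense/unpleasant than the participant's mean rating at the reference
(ascending) or strictly less (descending).  A per-participant logistic
regression of the indicator on temperature then gives the threshold as the
temperature at which the fitted probability of reporting a change is 0.5,
i.e. -intercept/slope.

A participant who discriminates *every* trial is credited with a step smaller
than the 1 degC grid: the threshold is set half a degree from the reference
(43.5 degC ascending, 48.5 degC descending) without fitting.  Complete
separation short of that pattern makes the logistic MLE undefined; those
participants get the midpoint between the warmest all-0 and coolest all-1
temperature (and the symmetric rule when descending), flagged as separated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import group_stats
from .synthetic import HEAT_BASELINE_C

__all__ = [
    "BinarizedSeries",
    "DiscriminationThreshold",
    "binarize_trials",
    "fit_threshold",
    "discrimination_table",
    "compare_thresholds",
]

ASCENDING_REFERENCE_C = 43.0
DESCENDING_REFERENCE_C = 49.0
EDGE_STEP_C = 0.5


@dataclass
class BinarizedSeries:
    participant_id: str
    reference_temp: float
    direction: str  # "ascending" | "descending"
    measure: str  # "intensity" | "unpleasantness"
    temps: np.ndarray  # per-trial comparison temperature
    indicators: np.ndarray  # per-trial 0/1
    reference_rating: float


@dataclass
class DiscriminationThreshold:
    participant_id: str
    direction: str
    measure: str
    threshold: float
    edge_case: bool = False
    separated: bool = False
    no_discrimination: bool = False
    intercept: float | None = None
    slope: float | None = None


def _default_reference(direction: str) -> float:
    if direction == "ascending":
        return ASCENDING_REFERENCE_C
    if direction == "descending":
        return DESCENDING_REFERENCE_C
    raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")


def binarize_trials(
    dataset: pd.DataFrame,
    reference_temp: float | None = None,
    direction: str = "ascending",
    measure: str = "intensity",
) -> dict[str, BinarizedSeries]:
    """Binarize familiarization trials against each participant's reference.

    The reference rating is the participant's mean rating at the reference
    temperature.  Ascending uses comparison temperatures above the reference;
    descending uses noxious temperatures below it (the 35 degC baseline is
    never a comparison stimulus).  Ties with the reference count as 0.
    """
    if reference_temp is None:
        reference_temp = _default_reference(direction)
    else:
        _default_reference(direction)  # validate direction
    col = f"{measure}_rating"
    if col not in dataset.columns:
        raise ValueError(f"unknown measure {measure!r}")
    fam = dataset[(dataset["session"] == "QST") & (dataset["modality"] == "heat")]
    out: dict[str, BinarizedSeries] = {}
    for pid, sub in fam.groupby("participant_id"):
        ref_rows = sub[sub["stimulus_level"] == reference_temp]
        if ref_rows.empty:
            raise ValueError(
                f"participant {pid} has no trials at the {reference_temp} degC reference"
            )
        ref = float(ref_rows[col].mean())
        if direction == "ascending":
            comp = sub[sub["stimulus_level"] > reference_temp]
            ind = (comp[col].to_numpy() > ref).astype(int)
        else:
            comp = sub[
                (sub["stimulus_level"] < reference_temp)
                & (sub["stimulus_level"] > HEAT_BASELINE_C)
            ]
            ind = (comp[col].to_numpy() < ref).astype(int)
        if comp.empty:
            raise ValueError(f"participant {pid} has no comparison trials")
        out[pid] = BinarizedSeries(
            participant_id=pid,
            reference_temp=reference_temp,
            direction=direction,
            measure=measure,
            temps=comp["stimulus_level"].to_numpy(dtype=float),
            indicators=ind,
            reference_rating=ref,
        )
    return out


def _separation_midpoint(temps: np.ndarray, ind: np.ndarray) -> float | None:
    """Midpoint rule if the 0- and 1-trials are cleanly split by temperature."""
    t0, t1 = temps[ind == 0], temps[ind == 1]
    if t0.size == 0 or t1.size == 0:
        return None
    if t0.max() < t1.min():
        return float((t0.max() + t1.min()) / 2.0)
    if t1.max() < t0.min():
        return float((t1.max() + t0.min()) / 2.0)
    return None


def fit_threshold(series: BinarizedSeries) -> DiscriminationThreshold:
    """Estimate the probability-0.5 discrimination threshold for one series."""
    temps, ind = series.temps, series.indicators
    if np.unique(temps).size < 2:
        raise ValueError("need at least two distinct comparison temperatures")
    base = dict(
        participant_id=series.participant_id,
        direction=series.direction,
        measure=series.measure,
    )
    sign = 1.0 if series.direction == "ascending" else -1.0

    if np.all(ind == 1):
        # discriminates every trial: credited with a sub-grid step
        return DiscriminationThreshold(
            threshold=series.reference_temp + sign * EDGE_STEP_C, edge_case=True, **base
        )
    if np.all(ind == 0):
        # never discriminates: censored just beyond the comparison range
        extreme = temps.max() if series.direction == "ascending" else temps.min()
        return DiscriminationThreshold(
            threshold=float(extreme + sign * EDGE_STEP_C),
            no_discrimination=True,
            **base,
        )

    midpoint = _separation_midpoint(temps, ind)
    if midpoint is not None:
        return DiscriminationThreshold(threshold=midpoint, separated=True, **base)

    params = _fit_logit(temps, ind)
    if params is None:
        # quasi-separation: MLE undefined; empirical 0.5-crossing of the
        # per-temperature discrimination proportions, flagged
        return DiscriminationThreshold(
            threshold=_proportion_crossing(temps, ind, series.direction),
            separated=True,
            **base,
        )
    intercept, slope = params
    if slope == 0:
        raise ValueError("degenerate logistic fit with zero slope")
    return DiscriminationThreshold(
        threshold=-intercept / slope, intercept=intercept, slope=slope, **base
    )


def _fit_logit(temps: np.ndarray, ind: np.ndarray) -> tuple[float, float] | None:
    """Logistic MLE of indicator on temperature; None if it does not exist."""
    design = sm.add_constant(temps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs"):
            try:
                model = sm.Logit(ind, design).fit(disp=0, maxiter=500, method=method)
            except Exception:
                continue
            params = np.asarray(model.params, dtype=float)
            if np.all(np.isfinite(params)) and np.all(np.abs(params) < 1e4):
                return float(params[0]), float(params[1])
    return None


def _proportion_crossing(temps: np.ndarray, ind: np.ndarray, direction: str) -> float:
    """Temperature where the per-level discrimination proportion crosses 0.5."""
    levels = np.unique(temps)
    props = np.array([ind[temps == t].mean() for t in levels])
    if direction == "descending":
        levels, props = levels[::-1], props[::-1]
    crossing = np.flatnonzero(props >= 0.5)
    if crossing.size == 0:
        return float(levels[-1])
    j = int(crossing[0])
    if j == 0 or props[j] == props[j - 1]:
        return float(levels[j])
    frac = (0.5 - props[j - 1]) / (props[j] - props[j - 1])
    return float(levels[j - 1] + frac * (levels[j] - levels[j - 1]))


def discrimination_table(
    dataset: pd.DataFrame,
    directions: tuple[str, ...] = ("ascending", "descending"),
    measures: tuple[str, ...] = ("intensity", "unpleasantness"),
) -> pd.DataFrame:
    """Per-participant thresholds for every (direction, measure) combination."""
    rows = []
    for direction in directions:
        for measure in measures:
            series = binarize_trials(dataset, direction=direction, measure=measure)
            for pid, s in series.items():
                th = fit_threshold(s)
                rows.append(
                    {
                        "participant_id": pid,
                        "direction": direction,
                        "measure": measure,
                        "threshold": th.threshold,
                        "edge_case": th.edge_case,
                        "separated": th.separated,
                        "no_discrimination": th.no_discrimination,
                    }
                )
    return pd.DataFrame(rows)


def compare_thresholds(
    thresholds: pd.DataFrame, class_labels: dict[str, str]
) -> dict[str, dict]:
    """Kruskal-Wallis + Dunn comparison of thresholds across classes.

    Keyed by ``"<direction>/<measure>"``; every participant must carry a class
    label and every class needs at least two members.
    """
    df = thresholds.copy()
    df["class_label"] = df["participant_id"].map(class_labels)
    if df["class_label"].isna().any():
        missing = sorted(df.loc[df["class_label"].isna(), "participant_id"].unique())
        raise ValueError(f"participants without class label: {missing[:5]}")
    out: dict[str, dict] = {}
    for (direction, measure), sub in df.groupby(["direction", "measure"]):
        class_names = sorted(sub["class_label"].unique())
        groups = [sub.loc[sub["class_label"] == c, "threshold"].to_numpy() for c in class_names]
        for name, g in zip(class_names, groups):
            if g.size < 2:
                raise ValueError(f"class {name!r} has fewer than two members")
        kw = group_stats.kruskal_wallis(groups)
        dunn = group_stats.dunn_posthoc(groups)
        out[f"{direction}/{measure}"] = {
            "classes": class_names,
            "kruskal_wallis": kw.to_jsonable(),
            "dunn": dunn.to_jsonable(),
        }
    return out
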