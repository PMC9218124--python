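"""Stevens power-function fits of VAS stimulus-response curves.

The perceived magnitude of experimental heat pain grows as a power of the
temperature increment above a 35 degC neutral baseline.  Fits are ordinary
least squares in double natural-log space: ln(mean rating) regressed on
ln(temperature - 35), giving the exponent b (slope) and log proportionality
constant c (intercept).  The baseline itself is never fitted, and any
temperature whose mean rating is <= 0 is dropped (the log is undefined; no
offset is added because offsets bias the exponent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import HEAT_BASELINE_C

__all__ = ["PowerFit", "fit_power", "compare_exponents", "class_power_table"]


@dataclass
class PowerFit:
    """OLS fit of ln(rating) on ln(dT): exponent = slope, constant = intercept."""

    exponent: float
    constant: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    measure: str = ""
    group: str = ""
    n_points: int = 0
    dropped_temps: tuple[float, ...] = ()


def fit_power(
    mean_ratings: Mapping[float, float] | pd.Series,
    baseline: float = HEAT_BASELINE_C,
    measure: str = "",
    group: str = "",
) -> PowerFit:
    """Fit a power function to per-temperature mean ratings.

    ``mean_ratings`` maps stimulus temperature (degC) to mean VAS rating.
    The slope F-test uses (1, n-2) degrees of freedom; a flat response is
    reported as slope 0 with F = 0 rather than an error.
    """
    if isinstance(mean_ratings, pd.Series):
        items = list(mean_ratings.items())
    else:
        items = list(mean_ratings.items())
    temps = np.array([t for t, _ in items], dtype=float)
    ratings = np.array([r for _, r in items], dtype=float)

    above = temps > baseline
    positive = ratings > 0
    dropped = tuple(sorted(temps[above & ~positive]))
    if dropped:
        warnings.warn(
            f"dropping temperatures with non-positive mean rating: {dropped}"
        )
    keep = above & positive
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 fittable temperatures above {baseline} degC, have {int(keep.sum())}"
        )
    x = np.log(temps[keep] - baseline)
    y = np.log(ratings[keep])
    n = int(keep.sum())

    if np.allclose(y, y[0]):
        return PowerFit(0.0, float(y[0]), 0.0, (1, n - 2), 1.0, 0.0,
                        measure=measure, group=group, n_points=n, dropped_temps=dropped)

    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 / (1.0 - r2) * (n - 2)
        p = float(stats.f.sf(f, 1, n - 2))
    return PowerFit(
        exponent=float(res.slope),
        constant=float(res.intercept),
        f_stat=float(f),
        df=(1, n - 2),
        p_value=p,
        r_squared=float(r2),
        measure=measure,
        group=group,
        n_points=n,
        dropped_temps=dropped,
    )


def class_power_table(
    dataset: pd.DataFrame,
    class_labels: Mapping[str, str],
    baseline: float = HEAT_BASELINE_C,
) -> tuple[pd.DataFrame, dict[str, dict[str, PowerFit]]]:
    """Per-class power fits of both VAS measures on familiarization data.

    The class curve is the mean over participants of per-participant mean
    ratings per temperature (averaged, then logged).  Returns a tidy table
    and the underlying :class:`PowerFit` objects keyed [class][measure].
    """
    fam = dataset[(dataset["session"] == "QST") & (dataset["modality"] == "heat")].copy()
    fam["class_label"] = fam["participant_id"].map(class_labels)
    if fam["class_label"].isna().any():
        missing = sorted(fam.loc[fam["class_label"].isna(), "participant_id"].unique())
        raise ValueError(f"participants without class label: {missing[:5]}")

    per_participant = fam.groupby(
        ["class_label", "participant_id", "stimulus_level"]
    )[["intensity_rating", "unpleasantness_rating"]].mean()
    class_means = per_participant.groupby(["class_label", "stimulus_level"]).mean()

    fits: dict[str, dict[str, PowerFit]] = {}
    rows = []
    for cls in sorted(class_means.index.get_level_values(0).unique()):
        fits[cls] = {}
        for measure, col in (
            ("intensity", "intensity_rating"),
            ("unpleasantness", "unpleasantness_rating"),
        ):
            series = class_means.loc[cls][col]
            fit = fit_power(series, baseline=baseline, measure=measure, group=cls)
            fits[cls][measure] = fit
            rows.append(
                {
                    "class": cls,
                    "measure": measure,
                    "exponent": fit.exponent,
                    "constant": fit.constant,
                    "F": fit.f_stat,
                    "df1": fit.df[0],
                    "df2": fit.df[1],
                    "p": fit.p_value,
                    "R2": fit.r_squared,
                }
            )
    return pd.DataFrame(rows), fits


def compare_exponents(fits: Mapping[str, Mapping[str, PowerFit]]) -> pd.DataFrame:
    """Check, per class, whether unpleasantness curves are steeper and lower.

    Returns booleans for exponent(unpleasantness) > exponent(intensity) and
    constant(unpleasantness) < constant(intensity).
    """
    rows = []
    for cls, by_measure in fits.items():
        if "intensity" not in by_measure or "unpleasantness" not in by_measure:
            raise ValueError(f"class {cls!r} is missing a fitted measure")
        bi, bu = by_measure["intensity"], by_measure["unpleasantness"]
        rows.append(
            {
                "class": cls,
                "exponent_unpleasantness_greater": bool(bu.exponent > bi.exponent),
                "constant_unpleasantness_lower": bool(bu.constant < bi.constant),
            }
        )
    return pd.DataFrame(rows).sort_values("class").reset_index(drop=True)
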