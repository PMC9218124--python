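"""Shared group statistics: Kruskal-Wallis, Dunn post-hoc, paired t, Pearson r.

Kruskal-Wallis and Dunn are implemented from the rank-sum formulas with a
single shared tie-correction term, because the two tests must agree on how
ties are handled.  Average ranks are assigned to ties and p-values use the
chi-square / normal asymptotics (group sizes in the intended use are ~20-100).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["KWResult", "DunnResult", "kruskal_wallis", "dunn_posthoc", "paired_t", "pearson_r"]


@dataclass
class KWResult:
    h: float
    df: int
    p_value: float
    tie_correction: float
    n_total: int

    def to_jsonable(self) -> dict:
        return {
            "H": self.h,
            "df": self.df,
            "p": self.p_value,
            "tie_correction": self.tie_correction,
            "n": self.n_total,
        }


@dataclass
class DunnResult:
    pairs: list[tuple[int, int]]
    z: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    method: str

    def to_jsonable(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "z": self.z.tolist(),
            "p_raw": self.p_raw.tolist(),
            "p_adjusted": self.p_adjusted.tolist(),
            "method": self.method,
        }


def _pooled_ranks(groups: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    """Average ranks of the pooled sample, split back per group.

    Returns (per-group ranks, tie term sum(t^3 - t), N).
    """
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + g.size])
        start += g.size
    return out, tie_term, n_total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Rank-based one-way test that k samples share a distribution.

    H is tie-corrected; p comes from the chi-square(k-1) asymptotic.  If every
    pooled value is identical the statistic is defined as 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least one value")
    ranks, tie_term, n = _pooled_ranks(arrays)
    df = len(arrays) - 1
    correction = 1.0 - tie_term / (n**3 - n) if n > 1 else 0.0
    if correction <= 0:  # all pooled values identical
        return KWResult(h=0.0, df=df, p_value=1.0, tie_correction=0.0, n_total=n)
    h = 12.0 / (n * (n + 1)) * sum(
        r.size * (r.mean() - (n + 1) / 2.0) ** 2 for r in ranks
    )
    h /= correction
    p = float(stats.chi2.sf(h, df))
    return KWResult(h=float(h), df=df, p_value=p, tie_correction=correction, n_total=n)


def dunn_posthoc(
    groups: Sequence[Sequence[float]], adjust: str = "bonferroni"
) -> DunnResult:
    """Dunn's pairwise rank comparisons following a Kruskal-Wallis test.

    z_{ij} = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with the same tie term T = sum(t^3 - t) as the omnibus test.
    """
    if adjust not in {"bonferroni", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    ranks, tie_term, n = _pooled_ranks(arrays)
    var_term = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs = list(combinations(range(len(arrays)), 2))
    z = np.zeros(len(pairs))
    for k, (i, j) in enumerate(pairs):
        se = np.sqrt(var_term * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        diff = ranks[i].mean() - ranks[j].mean()
        z[k] = 0.0 if se == 0 else diff / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    if adjust == "bonferroni":
        p_adj = np.minimum(p_raw * len(pairs), 1.0)
    else:
        p_adj = p_raw.copy()
    return DunnResult(pairs=pairs, z=z, p_raw=p_raw, p_adjusted=p_adj, method=adjust)


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired-sample t-test; returns (t, df, p) with df = n - 1.

    Degenerate cases: identical vectors give t = 0, p = 1; constant nonzero
    differences give t = +/-inf, p = 0 (flagged by the infinite statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d[0] == 0:
            return 0.0, df, 1.0
        return float(np.sign(d[0]) * np.inf), df, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pearson correlation; returns (r, df, p) with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), n - 2, float(p)
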