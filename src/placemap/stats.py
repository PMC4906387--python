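"""Nonparametric statistical battery for score tables.

All tests are two-sided. Families of pairwise comparisons are corrected with
Holm's sequential Bonferroni procedure and tagged B1|m (most significant of m
comparisons) through Bm|m. The Wilcoxon signed-rank test is implemented here
because the pulse-response classifier needs the exact null distribution with
midrank tie handling for small samples (count data is tie-heavy); for large
samples it switches to the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError, RobustnessError

__all__ = [
    "holm_adjust",
    "sign_test",
    "SignTestResult",
    "wilcoxon_signed_rank",
    "ks_pairwise",
    "kw_with_posthoc",
    "leave_one_out",
]


def holm_adjust(p_values: Sequence[float]) -> tuple[np.ndarray, list[str]]:
    """Holm step-down adjusted p-values and their rank tags.

    Sorted ascending, adjusted_i = max_{j<=i} (m-j+1) * p_(j), capped at 1.
    Tags follow the B1|m .. Bm|m nomenclature in ascending raw-p order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, j in enumerate(order):
        running = max(running, (m - rank) * p[j])
        adj[j] = min(1.0, running)
    tags = [""] * m
    for rank, j in enumerate(order):
        tags[j] = f"B{rank + 1}|{m}"
    return adj, tags


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    p_value: float

    def __float__(self) -> float:
        return self.p_value


def sign_test(scores: Sequence[float]) -> SignTestResult:
    """Exact two-sided binomial (sign) test of median zero.

    Zeros are excluded; tests whether positive and negative scores are
    equally likely among the nonzero ones.
    """
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    n_pos = int((s > 0).sum())
    n_neg = int((s < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        return SignTestResult(0, 0, math.nan)
    p = sps.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    return SignTestResult(n_pos, n_neg, float(p))


def _wilcoxon_exact_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic under random signs.

    Enumerates the null distribution of W+ by dynamic programming over the
    doubled (integer) midranks; with n nonzero differences this is the
    distribution over all 2^n sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_pos))
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    *,
    exact_max_n: int = 25,
    min_nonzero: int = 6,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values (or differences).

    Zero differences are excluded; tied absolute differences receive
    midranks. Exact null distribution up to ``exact_max_n`` nonzero
    differences, normal approximation with tie and continuity corrections
    beyond. Returns (W+, p); p is NaN with fewer than ``min_nonzero`` nonzero
    differences.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    n = len(d)
    if n == 0:
        return math.nan, math.nan
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n < min_nonzero:
        return w_pos, math.nan
    if n <= exact_max_n:
        return w_pos, _wilcoxon_exact_p(ranks, w_pos)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_pos, math.nan
    diff = w_pos - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    return w_pos, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def ks_pairwise(groups: Mapping[str, Sequence[float]], min_n: int = 5) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov test for every pair of groups, with Holm
    correction across the pairs. Undersized groups are skipped."""
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    usable = {k: v[np.isfinite(v)] for k, v in usable.items()}
    names = [k for k, v in usable.items() if len(v) >= min_n]
    if len(names) < 2:
        raise InsufficientDataError("need at least two groups of size >= min_n")
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        res = sps.ks_2samp(usable[g1], usable[g2], alternative="two-sided")
        rows.append(
            {
                "test": "ks",
                "group1": g1,
                "group2": g2,
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "n1": len(usable[g1]),
                "n2": len(usable[g2]),
            }
        )
    df = pd.DataFrame(rows)
    adj, tags = holm_adjust(df["p_raw"].to_numpy())
    df["p_holm"] = adj
    df["holm_tag"] = tags
    return df


def kw_with_posthoc(
    groups: Mapping[str, Sequence[float]], min_n: int = 5, alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus test plus all pairwise two-sided Mann-Whitney U
    post hoc comparisons with Holm correction.

    Post hoc rows are always computed but carry ``omnibus_gated`` marking
    whether the omnibus test reached ``alpha``.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    usable = {k: v[np.isfinite(v)] for k, v in usable.items()}
    names = [k for k, v in usable.items() if len(v) >= min_n]
    if len(names) < 3:
        raise InsufficientDataError("need at least three groups of size >= min_n")
    samples = [usable[k] for k in names]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        raise InsufficientDataError("degenerate all-tied input")
    H, p_kw = sps.kruskal(*samples)
    rows = [
        {
            "test": "kruskal",
            "group1": "|".join(names),
            "group2": "",
            "statistic": float(H),
            "p_raw": float(p_kw),
            "p_holm": float(p_kw),
            "holm_tag": "",
            "omnibus_gated": True,
            "n1": int(sum(len(s) for s in samples)),
            "n2": 0,
        }
    ]
    ph = []
    for g1, g2 in itertools.combinations(names, 2):
        res = sps.mannwhitneyu(usable[g1], usable[g2], alternative="two-sided")
        ph.append(
            {
                "test": "mannwhitney",
                "group1": g1,
                "group2": g2,
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "omnibus_gated": bool(p_kw < alpha),
                "n1": len(usable[g1]),
                "n2": len(usable[g2]),
            }
        )
    adj, tags = holm_adjust([r["p_raw"] for r in ph])
    for r, a, t in zip(ph, adj, tags):
        r["p_holm"] = float(a)
        r["holm_tag"] = t
    return pd.DataFrame(rows + ph)


def leave_one_out(
    test: Callable[[Mapping[str, np.ndarray]], float],
    data_by_animal: Mapping[str, Mapping[str, Sequence[float]]],
) -> tuple[float, pd.DataFrame]:
    """Leave-one-animal-out robustness: rerun ``test`` (a callable returning a
    p-value on a groups mapping) with each animal excluded and report the
    least significant (maximum) p alongside the per-exclusion table."""
    animals = sorted(data_by_animal)
    if len(animals) < 3:
        raise RobustnessError("leave-one-out needs at least 3 animals")
    group_names = sorted({g for a in animals for g in data_by_animal[a]})
    rows = []
    for excluded in animals:
        pooled = {
            g: np.concatenate(
                [np.asarray(data_by_animal[a].get(g, []), dtype=float)
                 for a in animals if a != excluded]
            )
            for g in group_names
        }
        rows.append({"excluded": excluded, "p": float(test(pooled))})
    df = pd.DataFrame(rows)
    return float(df["p"].max()), df
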