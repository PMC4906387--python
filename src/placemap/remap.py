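"""Per-unit stability and rate-change scores between session pairs.

Place-field similarity (PFS) is the bin-by-bin Pearson correlation of two
rate maps over the bins visited in both sessions. The rate-remapping score
c = (r2 - r1) / (r2 + r1) is a symmetric normalised rate difference in
[-1, 1] whose extremes mean firing exclusively in one session; the fold
change is recovered as r2/r1 = (c + 1) / (1 - c). The firing-field bias
(field_in - field_out) / (field_in + field_out) compares field sizes inside
the light zone and in the matched control sector; negative = smaller field
inside the zone.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientOverlapError, InvalidArgumentError
from .ratemap import RateMap, firing_field

logger = logging.getLogger(__name__)

__all__ = [
    "place_field_similarity",
    "rate_change_score",
    "fold_change_from_score",
    "firing_field_bias",
    "score_battery",
]


def place_field_similarity(
    map1: RateMap,
    map2: RateMap,
    min_overlap: int = 10,
    method: str = "pearson",
) -> float:
    """Bin-by-bin correlation over bins visited in both sessions.

    NaN when either series has zero variance; raises
    :class:`InsufficientOverlapError` below ``min_overlap`` common bins.
    """
    if map1.shape != map2.shape:
        raise InvalidArgumentError("rate maps have mismatched grids")
    both = map1.mask & map2.mask & np.isfinite(map1.rate) & np.isfinite(map2.rate)
    n = int(both.sum())
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"only {n} commonly visited bins (need {min_overlap})"
        )
    a = map1.rate[both]
    b = map2.rate[both]
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    if method == "pearson":
        return float(sps.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(sps.spearmanr(a, b).statistic)
    raise InvalidArgumentError(f"unknown correlation method {method!r}")


def rate_change_score(r1: float, r2: float) -> float:
    """c = (r2 - r1) / (r2 + r1); NaN when both rates are zero."""
    if r1 < 0 or r2 < 0:
        raise InvalidArgumentError("rates must be non-negative")
    if r1 == 0 and r2 == 0:
        return math.nan
    return (r2 - r1) / (r2 + r1)


def fold_change_from_score(c: float) -> float:
    """r2/r1 = (c + 1) / (1 - c); signed sentinel (inf / 0) at |c| = 1."""
    if not -1.0 <= c <= 1.0:
        raise InvalidArgumentError("score must lie in [-1, 1]")
    if c == 1.0:
        return math.inf
    if c == -1.0:
        return 0.0
    return (c + 1.0) / (1.0 - c)


def firing_field_bias(field_in: float, field_out: float) -> float:
    """(field_in - field_out) / (field_in + field_out); NaN when both zero.

    Fields are proportions computed within each zone's own bin set, so
    unequal zone areas cannot bias the score."""
    if field_in < 0 or field_out < 0:
        raise InvalidArgumentError("field proportions must be non-negative")
    if field_in == 0 and field_out == 0:
        return math.nan
    return (field_in - field_out) / (field_in + field_out)


def score_battery(
    unit_maps: Mapping[int, Mapping[str, Mapping[str, RateMap]]],
    session_pairs: Sequence[tuple[str, str]],
    *,
    min_overlap: int = 10,
    field_threshold_hz: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All per-unit scores for the requested session pairs.

    ``unit_maps[unit][session]`` maps "whole"/"in"/"out" to rate maps (the
    zone-restricted maps are built with zone-limited smoothing). Returns a
    pair table (PFS whole/in/out and rate-change scores in/out per session
    pair) and a per-session firing-field bias table. Unavailable scores are
    NaN with a logged reason.
    """
    pair_rows = []
    bias_rows = []
    sessions = sorted({s for pair in session_pairs for s in pair})

    def safe_pfs(m1, m2):
        try:
            return place_field_similarity(m1, m2, min_overlap=min_overlap)
        except InsufficientOverlapError as exc:
            logger.info("PFS unavailable: %s", exc)
            return math.nan

    for uid, per_session in unit_maps.items():
        for s1, s2 in session_pairs:
            if s1 not in per_session or s2 not in per_session:
                continue
            m1, m2 = per_session[s1], per_session[s2]
            r_in_1, r_in_2 = m1["in"].mean_rate_hz, m2["in"].mean_rate_hz
            r_out_1, r_out_2 = m1["out"].mean_rate_hz, m2["out"].mean_rate_hz
            pair_rows.append(
                {
                    "unit_id": uid,
                    "pair": f"{s1}/{s2}",
                    "pfs_whole": safe_pfs(m1["whole"], m2["whole"]),
                    "pfs_in": safe_pfs(m1["in"], m2["in"]),
                    "pfs_out": safe_pfs(m1["out"], m2["out"]),
                    "c_in": rate_change_score(r_in_1, r_in_2)
                    if not (r_in_1 == 0 and r_in_2 == 0) else math.nan,
                    "c_out": rate_change_score(r_out_1, r_out_2)
                    if not (r_out_1 == 0 and r_out_2 == 0) else math.nan,
                }
            )
        for s in sessions:
            if s not in per_session:
                continue
            fin = firing_field(per_session[s]["in"], field_threshold_hz)
            fout = firing_field(per_session[s]["out"], field_threshold_hz)
            bias_rows.append(
                {
                    "unit_id": uid,
                    "session": s,
                    "field_in": fin,
                    "field_out": fout,
                    "bias": firing_field_bias(fin, fout),
                }
            )
    return pd.DataFrame(pair_rows), pd.DataFrame(bias_rows)
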