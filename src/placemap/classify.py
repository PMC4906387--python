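"""Light-response classification of units and place-cell gating.

Units are first classified from the rest-box pulse-test session (the
"sleep" label): a unit is *suppressed* when its rate during the 400-ms
pulses drops by more than 33% relative to the immediately preceding 400-ms
baseline windows and the per-pulse paired rate change is significant
(two-sided Wilcoxon signed-rank, P < 0.05); *disinhibited* when it increases
by more than 33% with significance; otherwise *remaining*.

In the familiar paradigm the paradigm label additionally requires a
consistent in-zone rate change during the illuminated exploration session
(>50% drop or rise in the light zone in a2 relative to a1), with the sleep
response required to agree in sign. In the novel paradigm only the sleep
response is available, gated by place-cell criteria in the later light-off
sessions. Place cells are gated by sparsity < 0.3, coherence > 0.55 and a
mean rate above 0.25 Hz in the qualifying sessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, ProtocolError
from .ratemap import RateMap, coherence, sparsity
from .stats import wilcoxon_signed_rank

logger = logging.getLogger(__name__)

__all__ = [
    "PulseResponse",
    "pulse_response",
    "classify_by_pulses",
    "is_place_cell",
    "classify_familiar",
    "classify_novel",
    "proportions",
]

SLEEP_CHANGE_THRESHOLD = 0.33
EXPLORATION_CHANGE_THRESHOLD = 0.5
ALPHA = 0.05


@dataclass(frozen=True)
class PulseResponse:
    """Paired pulse/baseline firing summary for one unit."""

    unit_id: int
    baseline_rate_hz: float
    pulse_rate_hz: float
    relative_change: float
    p_value: float
    n_pulses: int


def pulse_response(
    spike_times: Sequence[float],
    pulse_onsets: Sequence[float],
    pulse_duration_s: float = 0.4,
    *,
    unit_id: int = -1,
    min_pulses: int = 20,
) -> PulseResponse:
    """Per-pulse paired rates: [onset, onset+d) versus the immediately
    preceding baseline window [onset-d, onset).

    Rates are pooled over pulses; the p-value is a two-sided Wilcoxon
    signed-rank test on the per-pulse count pairs (zero differences dropped).
    With zero baseline spikes the relative change is +inf if any pulse spikes
    occurred, NaN otherwise.
    """
    onsets = np.sort(np.asarray(pulse_onsets, dtype=float))
    if len(onsets) < min_pulses:
        raise InsufficientDataError(
            f"need at least {min_pulses} pulses, got {len(onsets)}"
        )
    if np.any(np.diff(onsets) < 2 * pulse_duration_s):
        raise ProtocolError("baseline window overlaps the previous pulse")
    ts = np.sort(np.asarray(spike_times, dtype=float))
    pulse_counts = (
        np.searchsorted(ts, onsets + pulse_duration_s) - np.searchsorted(ts, onsets)
    ).astype(float)
    base_counts = (
        np.searchsorted(ts, onsets) - np.searchsorted(ts, onsets - pulse_duration_s)
    ).astype(float)
    n = len(onsets)
    total_t = n * pulse_duration_s
    base_rate = base_counts.sum() / total_t
    pulse_rate = pulse_counts.sum() / total_t
    if base_rate > 0:
        change = (pulse_rate - base_rate) / base_rate
    else:
        change = math.inf if pulse_rate > 0 else math.nan
    _, p = wilcoxon_signed_rank(pulse_counts, base_counts)
    return PulseResponse(
        unit_id=unit_id,
        baseline_rate_hz=float(base_rate),
        pulse_rate_hz=float(pulse_rate),
        relative_change=float(change),
        p_value=float(p),
        n_pulses=n,
    )


def classify_by_pulses(
    resp: PulseResponse,
    threshold: float = SLEEP_CHANGE_THRESHOLD,
    alpha: float = ALPHA,
) -> str:
    """Sleep label from the pulse response: a magnitude criterion (>33% rate
    change) and a significance criterion (P < 0.05) must both hold."""
    change = resp.relative_change
    if math.isnan(change):
        logger.warning("unit %s: undefined pulse response, labelled remaining", resp.unit_id)
        return "remaining"
    significant = (not math.isnan(resp.p_value)) and resp.p_value < alpha
    if change <= -threshold and significant:
        return "suppressed"
    if change >= threshold and significant:
        return "disinhibited"
    return "remaining"


def is_place_cell(
    maps: Mapping[str, RateMap],
    sparsity_max: float = 0.3,
    coherence_min: float = 0.55,
    rate_min_hz: float = 0.25,
    combine: str = "any",
) -> tuple[bool, dict[str, bool]]:
    """Place-cell gate over the qualifying sessions' maps.

    A session passes when sparsity < 0.3, coherence > 0.55 and the session
    mean rate exceeds 0.25 Hz; the flag combines sessions with OR ("any",
    the default: criteria met in a1 and/or a3, b2 and/or b3) or AND ("all").
    Sessions whose tuning measures are unavailable fail, with a log entry.
    """
    if len(maps) == 0:
        raise InsufficientDataError("no session maps supplied")
    per_session: dict[str, bool] = {}
    for name, rm in maps.items():
        try:
            s = sparsity(rm)
            c = coherence(rm)
            r = rm.mean_rate_hz
        except (InsufficientDataError, Exception) as exc:  # noqa: BLE001
            logger.info("session %s fails place-cell gate: %s", name, exc)
            per_session[name] = False
            continue
        if any(math.isnan(v) for v in (s, c, r)):
            logger.info("session %s fails place-cell gate: undefined measure", name)
            per_session[name] = False
            continue
        per_session[name] = (s < sparsity_max) and (c > coherence_min) and (r > rate_min_hz)
    flags = list(per_session.values())
    flag = any(flags) if combine == "any" else all(flags)
    return flag, per_session


def classify_familiar(
    zone_rate_a1: float,
    zone_rate_a2_lighton: float,
    sleep_label: str,
    sleep_change: float,
    threshold: float = EXPLORATION_CHANGE_THRESHOLD,
) -> str:
    """Paradigm label from in-zone rates (a2 restricted to light-on periods).

    Precedence: suppressed -> disinhibited -> unaffected -> remaining.
    A consistent sleep response is required: suppression needs a sleep drop,
    disinhibition a positive sleep change, and "unaffected" a sleep change
    within the +/-50% band.
    """
    if zone_rate_a1 <= 0:
        logger.info("zero in-zone rate in a1; labelled remaining")
        return "remaining"
    ratio = zone_rate_a2_lighton / zone_rate_a1
    if ratio < 1.0 - threshold and sleep_label == "suppressed":
        return "suppressed"
    if ratio > 1.0 + threshold and not math.isnan(sleep_change) and sleep_change > 0:
        return "disinhibited"
    if (
        1.0 - threshold <= ratio <= 1.0 + threshold
        and not math.isnan(sleep_change)
        and abs(sleep_change) <= threshold
    ):
        return "unaffected"
    return "remaining"


def classify_novel(
    sleep_label: str,
    sleep_change: float,
    place_flag: bool,
    band: float = SLEEP_CHANGE_THRESHOLD,
) -> str:
    """Paradigm label for the novel paradigm: the sleep label, gated by the
    place-cell flag in sessions b2 and/or b3. Sleep-remaining units whose
    pulse change lies within the +/-33% band count as unaffected; non-place
    cells are remaining."""
    if not place_flag:
        return "remaining"
    if sleep_label in ("suppressed", "disinhibited"):
        return sleep_label
    if not math.isnan(sleep_change) and abs(sleep_change) <= band:
        return "unaffected"
    return "remaining"


def proportions(labels: Sequence[str]) -> dict[str, float]:
    """Percentage of units per label (classification bookkeeping)."""
    labels = list(labels)
    n = len(labels)
    if n == 0:
        raise InsufficientDataError("no labels")
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return {k: 100.0 * v / n for k, v in sorted(out.items())}
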