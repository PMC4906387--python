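"""Occupancy-normalised spatial firing maps and spatial-tuning measures.

Rate maps are built on the arena's 4x4-cm bin grid: spikes are counted per
bin, occupancy is accumulated per bin (each position sample contributes one
sampling interval), and the rate is the Gaussian-smoothed count divided by
the Gaussian-smoothed occupancy. Smoothing is mask-aware: when a map is
restricted to a zone, the kernel is renormalised over the bins inside the
zone so that rates never bleed across the zone boundary.

Tuning measures: occupancy-weighted sparsity (lower = more selective),
coherence (correlation between each bin's unsmoothed rate and the mean
unsmoothed rate of its valid 8-neighbours), and the firing field (the
proportion of valid bins with a rate above 1 Hz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .arena import ArenaSpec, LightZone
from .errors import (
    EmptyMapError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .synth import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "RateMap",
    "compute_occupancy",
    "compute_rate_map",
    "zone_masks",
    "sparsity",
    "coherence",
    "firing_field",
    "cumulate_maps",
    "mobility_mask",
    "epochs_to_mask",
]


@dataclass
class RateMap:
    """Binned spatial firing map.

    ``rate`` is the smoothed rate in Hz with NaN outside ``mask`` (the valid
    analysed bins: inside the arena, visited, and inside any requested zone);
    ``raw_rate`` is the unsmoothed count/occupancy quotient on the same bins.
    """

    bin_size_cm: float
    occupancy: np.ndarray
    counts: np.ndarray
    rate: np.ndarray
    raw_rate: np.ndarray
    mask: np.ndarray
    sigma_bins: float
    n_spikes_dropped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def mean_rate_hz(self) -> float:
        """Overall mean rate over the analysed bins: spikes / time."""
        occ = self.occupancy[self.mask].sum()
        return float(self.counts[self.mask].sum() / occ) if occ > 0 else math.nan


def epochs_to_mask(traj: Trajectory, epochs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Sample mask for a list of half-open [start, end) time intervals."""
    if len(epochs) == 0:
        raise InvalidArgumentError("empty epoch list")
    m = np.zeros(len(traj.t), dtype=bool)
    for start, end in epochs:
        if end < start:
            raise InvalidArgumentError("epoch end before start")
        m |= (traj.t >= start) & (traj.t < end)
    return m


def mobility_mask(traj: Trajectory, speed_min_cm_s: float = 3.0) -> np.ndarray:
    """Exploration-epoch mask: samples with speed above the threshold."""
    return traj.speed() > speed_min_cm_s


def compute_occupancy(
    traj: Trajectory,
    arena: ArenaSpec,
    sample_mask: Optional[np.ndarray] = None,
    epochs: Optional[Sequence[tuple[float, float]]] = None,
) -> np.ndarray:
    """Occupancy grid in seconds. Each included position sample contributes
    one sampling interval to its bin, so the grid total equals the analysed
    duration exactly."""
    if epochs is not None:
        em = epochs_to_mask(traj, epochs)
        sample_mask = em if sample_mask is None else (sample_mask & em)
    if sample_mask is None:
        sample_mask = np.ones(len(traj.t), dtype=bool)
    if sample_mask.sum() == 0:
        raise EmptyMapError("no position samples in the requested epochs")
    n = arena.n_bins
    occ = np.zeros((n, n))
    row, col = arena.bin_index(traj.x[sample_mask], traj.y[sample_mask])
    np.add.at(occ, (row, col), traj.dt)
    return occ


def _assign_spikes(
    spike_times: np.ndarray, traj: Trajectory, sample_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Nearest-in-time position sample per spike (within one sampling
    interval); spikes farther than that, or landing on excluded samples, are
    dropped and counted."""
    ts = np.asarray(spike_times, dtype=float)
    if len(ts) == 0:
        return np.empty(0, dtype=int), 0
    idx = np.searchsorted(traj.t, ts)
    lo = np.clip(idx - 1, 0, len(traj.t) - 1)
    hi = np.clip(idx, 0, len(traj.t) - 1)
    pick = np.where(np.abs(traj.t[hi] - ts) < np.abs(traj.t[lo] - ts), hi, lo)
    ok = np.abs(traj.t[pick] - ts) <= traj.dt + 1e-12
    ok &= sample_mask[pick]
    dropped = int((~ok).sum())
    return pick[ok], dropped


def _smoothing_kernel(sigma_bins: float) -> np.ndarray:
    """Gaussian kernel truncated at 2 sigma (circular support)."""
    r = int(math.ceil(2.0 * sigma_bins))
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    k = np.exp(-d2 / (2.0 * sigma_bins**2))
    k[np.sqrt(d2) > 2.0 * sigma_bins] = 0.0
    return k


def compute_rate_map(
    spike_times: np.ndarray,
    traj: Trajectory,
    arena: ArenaSpec,
    *,
    sigma_bins: float = 1.0,
    sample_mask: Optional[np.ndarray] = None,
    epochs: Optional[Sequence[tuple[float, float]]] = None,
    mask: Optional[np.ndarray] = None,
) -> RateMap:
    """Smoothed occupancy-normalised rate map.

    ``mask`` restricts the map (and the smoothing support) to a zone; bins
    outside it are missing. Raises :class:`EmptyMapError` when no valid bin
    has occupancy under the mask.
    """
    if epochs is not None:
        em = epochs_to_mask(traj, epochs)
        sample_mask = em if sample_mask is None else (sample_mask & em)
    if sample_mask is None:
        sample_mask = np.ones(len(traj.t), dtype=bool)
    occ = compute_occupancy(traj, arena, sample_mask)
    pick, dropped = _assign_spikes(spike_times, traj, sample_mask)
    if dropped:
        logger.info("dropped %d spikes with no position sample within one interval", dropped)
    n = arena.n_bins
    counts = np.zeros((n, n))
    if len(pick):
        row, col = arena.bin_index(traj.x[pick], traj.y[pick])
        np.add.at(counts, (row, col), 1.0)

    m = arena.valid_mask & (occ > 0)
    if mask is not None:
        m = m & mask
    if not m.any():
        raise EmptyMapError("no valid occupied bins under the requested mask")

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(m, counts / np.where(occ > 0, occ, np.nan), np.nan)
    if sigma_bins > 0:
        k = _smoothing_kernel(sigma_bins)
        num = ndimage.convolve(np.where(m, counts, 0.0), k, mode="constant")
        den = ndimage.convolve(np.where(m, occ, 0.0), k, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(m & (den > 0), num / den, np.nan)
    else:
        rate = raw.copy()
    return RateMap(
        bin_size_cm=arena.bin_size_cm,
        occupancy=occ,
        counts=counts,
        rate=rate,
        raw_rate=raw,
        mask=m,
        sigma_bins=sigma_bins,
        n_spikes_dropped=dropped,
    )


def zone_masks(arena: ArenaSpec, zone: LightZone) -> tuple[np.ndarray, np.ndarray]:
    """(in_mask, out_mask): bins of the light zone and of the matched control
    sector (same angular width, centred opposite). For a 180-degree zone the
    two masks partition the valid bins."""
    cx, cy = arena.bin_centers()
    valid = arena.valid_mask
    in_mask = valid & zone.contains(cx, cy)
    out_mask = valid & zone.control_zone().contains(cx, cy)
    return in_mask, out_mask


def sparsity(rate_map: RateMap) -> float:
    """Occupancy-weighted sparsity S = (sum p*r)^2 / sum p*r^2, in [0, 1].

    Lower values indicate more spatially selective firing; the place-cell
    criterion is S < 0.3. NaN when the map is everywhere zero.
    """
    m = rate_map.mask & np.isfinite(rate_map.rate)
    if not m.any():
        raise EmptyMapError("sparsity of an all-invalid map")
    occ = rate_map.occupancy[m]
    p = occ / occ.sum()
    lam = rate_map.rate[m]
    denom = np.sum(p * lam**2)
    if denom == 0:
        return math.nan
    return float(np.sum(p * lam) ** 2 / denom)


def coherence(rate_map: RateMap) -> float:
    """Correlation between each bin's unsmoothed rate and the mean unsmoothed
    rate of its valid 8-neighbours (Pearson, over valid bins). NaN when either
    series is constant; requires at least 9 valid bins."""
    m = rate_map.mask & np.isfinite(rate_map.raw_rate)
    if m.sum() < 9:
        raise InsufficientDataError("coherence needs at least 9 valid bins")
    k = np.ones((3, 3))
    k[1, 1] = 0.0
    r = np.where(m, rate_map.raw_rate, 0.0)
    nb_sum = ndimage.convolve(r, k, mode="constant")
    nb_cnt = ndimage.convolve(m.astype(float), k, mode="constant")
    sel = m & (nb_cnt > 0)
    a = rate_map.raw_rate[sel]
    b = nb_sum[sel] / nb_cnt[sel]
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def firing_field(
    rate_map: RateMap, threshold_hz: float = 1.0, mask: Optional[np.ndarray] = None
) -> float:
    """Proportion of valid bins with a firing rate above the threshold."""
    m = rate_map.mask & np.isfinite(rate_map.rate)
    if mask is not None:
        m = m & mask
    if not m.any():
        raise EmptyMapError("firing field over an empty mask")
    return float((rate_map.rate[m] > threshold_hz).mean())


def cumulate_maps(maps: Sequence[RateMap]) -> RateMap:
    """Bin-wise sum of rates over bins valid in all maps (population map)."""
    if len(maps) == 0:
        raise InvalidArgumentError("no maps to cumulate")
    shape = maps[0].shape
    bs = maps[0].bin_size_cm
    for mp in maps:
        if mp.shape != shape or mp.bin_size_cm != bs:
            raise InvalidArgumentError("rate maps have mismatched grids")
    common = np.logical_and.reduce([mp.mask for mp in maps])
    rate = np.where(common, sum(np.where(common, mp.rate, 0.0) for mp in maps), np.nan)
    raw = np.where(common, sum(np.where(common, mp.raw_rate, 0.0) for mp in maps), np.nan)
    return RateMap(
        bin_size_cm=bs,
        occupancy=maps[0].occupancy.copy(),
        counts=sum(mp.counts for mp in maps),
        rate=rate,
        raw_rate=raw,
        mask=common,
        sigma_bins=maps[0].sigma_bins,
    )
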