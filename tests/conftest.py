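import numpy as np
import pytest

from placemap import ArenaSpec, LightZone
from placemap.ratemap import RateMap
from placemap.synth import Trajectory


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture(scope="session")
def zone180() -> LightZone:
    # boundary along the x axis (a bin-edge-aligned diameter)
    return LightZone(center_angle_deg=90.0, width_deg=180.0)


def make_ratemap(rate, occ=None, mask=None, raw=None, bin_size=4.0) -> RateMap:
    """Assemble a RateMap directly from arrays (for measure-level tests)."""
    rate = np.asarray(rate, dtype=float)
    occ = np.ones_like(rate) if occ is None else np.asarray(occ, dtype=float)
    mask = np.ones_like(rate, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    raw = rate if raw is None else np.asarray(raw, dtype=float)
    rate = np.where(mask, rate, np.nan)
    raw = np.where(mask, raw, np.nan)
    return RateMap(
        bin_size_cm=bin_size,
        occupancy=occ,
        counts=raw * occ,
        rate=rate,
        raw_rate=raw,
        mask=mask,
        sigma_bins=0.0,
    )


def parked_trajectory(x=10.0, y=10.0, duration_s=10.0, fs=50.0) -> Trajectory:
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return Trajectory(t=t, x=np.full(n, x), y=np.full(n, y), fs=fs)
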