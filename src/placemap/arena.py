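"""Arena geometry: the circular enclosure, its spatial binning, and the light zone.

The recording enclosure is a circular open field (120 cm diameter by default)
discretised into square bins (4 cm by default). The light zone is an angular
sector of the arena, defined by a centre angle and a width between 120 and
180 degrees; illumination is gated on whenever the animal is inside it. For
in-zone / out-zone comparisons a control sector of identical angular width,
centred opposite the light zone, is used so that unequal areas never bias a
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ArenaSpec", "LightZone"]


@dataclass(frozen=True)
class ArenaSpec:
    """Circular arena with a square-bin grid over its bounding box.

    Bins are indexed (row, col) from the lower-left corner of the bounding
    box; bin centres are used for all membership tests. Bins whose centre
    falls outside the circle are excluded from the valid mask.
    """

    shape: str = "circle"
    diameter_cm: float = 120.0
    bin_size_cm: float = 4.0

    def __post_init__(self) -> None:
        if self.shape != "circle":
            raise InvalidArgumentError(f"unsupported arena shape: {self.shape!r}")
        if self.diameter_cm <= 0:
            raise InvalidArgumentError("diameter_cm must be positive")
        if self.bin_size_cm <= 0:
            raise InvalidArgumentError("bin_size_cm must be positive")

    @property
    def radius_cm(self) -> float:
        return self.diameter_cm / 2.0

    @property
    def n_bins(self) -> int:
        """Bins per side of the bounding-box grid (partial last bin included;
        its centre lies outside the circle, so it never enters the valid mask)."""
        return int(math.ceil(self.diameter_cm / self.bin_size_cm))

    @property
    def bin_edges(self) -> np.ndarray:
        r = self.radius_cm
        return -r + self.bin_size_cm * np.arange(self.n_bins + 1)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(cx, cy) grids of bin-centre coordinates, shape (n_bins, n_bins).

        Row index corresponds to y, column index to x.
        """
        c = self.bin_edges[:-1] + self.bin_size_cm / 2.0
        cx, cy = np.meshgrid(c, c)
        return cx, cy

    @property
    def valid_mask(self) -> np.ndarray:
        cx, cy = self.bin_centers()
        return np.hypot(cx, cy) <= self.radius_cm

    def contains(self, x, y) -> np.ndarray:
        return np.hypot(np.asarray(x), np.asarray(y)) <= self.radius_cm

    def bin_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices for positions; positions are clipped into the grid."""
        r = self.radius_cm
        col = np.floor((np.asarray(x) + r) / self.bin_size_cm).astype(int)
        row = np.floor((np.asarray(y) + r) / self.bin_size_cm).astype(int)
        n = self.n_bins
        return np.clip(row, 0, n - 1), np.clip(col, 0, n - 1)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "diameter_cm": self.diameter_cm,
            "bin_size_cm": self.bin_size_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        return cls(**d)


@dataclass(frozen=True)
class LightZone:
    """Angular sector of the arena in which illumination is gated on.

    Membership is a half-open angular test [center - width/2, center + width/2)
    on the position's polar angle, so that for a 180-degree zone the zone and
    its matched control sector partition the arena exactly.
    """

    center_angle_deg: float
    width_deg: float = 180.0
    arena_center: tuple[float, float] = (0.0, 0.0)
    radius_cm: float = 60.0

    def __post_init__(self) -> None:
        if not (120.0 <= self.width_deg <= 180.0):
            raise InvalidArgumentError(
                f"zone width must lie in [120, 180] degrees, got {self.width_deg}"
            )

    def contains(self, x, y) -> np.ndarray:
        cx, cy = self.arena_center
        theta = np.degrees(np.arctan2(np.asarray(y) - cy, np.asarray(x) - cx))
        start = self.center_angle_deg - self.width_deg / 2.0
        return np.mod(theta - start, 360.0) < self.width_deg

    def control_zone(self) -> "LightZone":
        """Matched sector of identical width centred opposite the light zone."""
        return LightZone(
            center_angle_deg=(self.center_angle_deg + 180.0) % 360.0,
            width_deg=self.width_deg,
            arena_center=self.arena_center,
            radius_cm=self.radius_cm,
        )

    def to_dict(self) -> dict:
        return {
            "center_angle_deg": self.center_angle_deg,
            "width_deg": self.width_deg,
            "arena_center": list(self.arena_center),
            "radius_cm": self.radius_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightZone":
        d = dict(d)
        d["arena_center"] = tuple(d.get("arena_center", (0.0, 0.0)))
        return cls(**d)
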