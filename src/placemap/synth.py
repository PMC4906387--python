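"""Synthetic virtual experiments: foraging trajectories, tuned spike trains,
light protocols and ground-truth labels.

The generator emulates a spatially gated optogenetic experiment in a circular
open field: a rat forages for randomly dropped food pellets while units with
Gaussian place fields fire as inhomogeneous Poisson processes. A laser is
gated on whenever the animal is inside an angular "light zone" (and moving),
multiplying each unit's instantaneous rate by a phenotype-specific gain:
~0.22 for directly suppressed cells (a 78% rate reduction), ~2.34 for cells
disinhibited through interneuron silencing (a 134% increase), and 1 for
unaffected cells. A separate pulse-test session (400-ms pulses at 0.5 Hz for
18 min while the animal rests) provides a place-independent readout of each
unit's light response.

Two behavioural paradigms are generated:

* familiar — three exploration sessions a1-a3 of the same arena, light gated
  in a2 only, with a configurable across-session transition (remapping of
  suppressed cells' fields, persistent rate increase of disinhibited cells)
  applied between a2 and a3;
* novel — three exposures b1-b3 to a new arena with light gated in b1, the
  transition applied between b1 and b2, and b2 -> b3 unchanged.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .arena import ArenaSpec, LightZone
from .errors import InvalidArgumentError, InvalidModelError

__all__ = [
    "Trajectory",
    "GaussianField",
    "PlaceCellModel",
    "LightProtocol",
    "GroundTruth",
    "SpeedParams",
    "ParadigmConfig",
    "Dataset",
    "simulate_trajectory",
    "build_ensemble",
    "simulate_session",
    "simulate_pulse_session",
    "apply_session_transition",
    "generate_paradigm",
    "light_on_mask",
    "mask_to_intervals",
]

#: default phenotype proportions (suppressed, disinhibited, remaining) for
#: pyramidal cells, matching the recorded population tallies 386/1,154 and
#: 244/1,154.
DEFAULT_PHENOTYPE_PROPS = (0.334, 0.211, 0.455)

#: default multiplicative light gains: a 78% rate reduction for suppressed
#: units and a 134% increase for disinhibited units.
DEFAULT_GAINS = {"suppressed": 0.22, "disinhibited": 2.34, "remaining": 1.0}

#: fraction of interneurons directly suppressed by the light (46/60).
DEFAULT_INTERNEURON_SUPPRESSED_PROB = 0.767


@dataclass
class Trajectory:
    """Animal path sampled at a fixed rate: times (s), x/y positions (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float = 50.0

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration_s(self) -> float:
        return len(self.t) * self.dt

    def speed(self) -> np.ndarray:
        """Instantaneous speed (cm/s) per sample (forward difference, last
        value repeated)."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        v = np.hypot(dx, dy) * self.fs
        return np.append(v, v[-1] if len(v) else 0.0)


@dataclass(frozen=True)
class GaussianField:
    center_xy: tuple[float, float]
    sigma_cm: float = 8.0
    peak_hz: float = 10.0


@dataclass(frozen=True)
class PlaceCellModel:
    """Rate model for one unit.

    ``baseline_hz`` is the out-of-field rate during exploration; ``rest_hz``
    is the rate in the rest box, which is what the pulse-test session probes.
    ``light_gain`` multiplies the instantaneous rate while the light is on.
    """

    unit_id: int
    cell_type: str = "pyramidal"  # or "interneuron"
    fields: tuple[GaussianField, ...] = ()
    baseline_hz: float = 0.1
    rest_hz: float = 2.0
    phenotype: str = "remaining"  # suppressed | disinhibited | remaining
    light_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.light_gain < 0:
            raise InvalidArgumentError("light_gain must be non-negative")
        if self.baseline_hz < 0 or self.rest_hz < 0:
            raise InvalidArgumentError("rates must be non-negative")
        for f in self.fields:
            if f.peak_hz < 0:
                raise InvalidArgumentError("peak rate must be non-negative")

    def rate_at(self, x, y) -> np.ndarray:
        """Tuning curve: baseline plus Gaussian field bumps, in Hz."""
        r = np.full_like(np.asarray(x, dtype=float), self.baseline_hz)
        for f in self.fields:
            cx, cy = f.center_xy
            d2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
            r = r + f.peak_hz * np.exp(-d2 / (2.0 * f.sigma_cm**2))
        return r

    @property
    def max_rate_hz(self) -> float:
        return self.baseline_hz + sum(f.peak_hz for f in self.fields)


@dataclass(frozen=True)
class LightProtocol:
    """Either zone-gated illumination during exploration or a rest-box pulse train."""

    mode: str = "zone-gated"  # or "pulse-train"
    zone: Optional[LightZone] = None
    pulse_duration_s: float = 0.4
    pulse_rate_hz: float = 0.5
    duration_s: float = 1080.0
    immobility_cutoff_s: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("zone-gated", "pulse-train"):
            raise InvalidArgumentError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "zone-gated" and self.zone is None:
            raise InvalidArgumentError("zone-gated protocol requires a zone")
        if self.mode == "pulse-train":
            if self.pulse_duration_s * self.pulse_rate_hz > 1.0:
                raise InvalidArgumentError("pulse train would overlap")

    def pulse_onsets(self) -> np.ndarray:
        n = int(math.floor(self.duration_s * self.pulse_rate_hz))
        return np.arange(n) / self.pulse_rate_hz


@dataclass
class GroundTruth:
    """Per-unit truth used to validate the analysis stages."""

    phenotype: dict[int, str] = field(default_factory=dict)
    cell_type: dict[int, str] = field(default_factory=dict)
    remapped: dict[int, bool] = field(default_factory=dict)
    centers_pre: dict[int, list] = field(default_factory=dict)
    centers_post: dict[int, list] = field(default_factory=dict)
    expected_signs: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phenotype": {str(k): v for k, v in self.phenotype.items()},
            "cell_type": {str(k): v for k, v in self.cell_type.items()},
            "remapped": {str(k): bool(v) for k, v in self.remapped.items()},
            "centers_pre": {str(k): v for k, v in self.centers_pre.items()},
            "centers_post": {str(k): v for k, v in self.centers_post.items()},
            "expected_signs": self.expected_signs,
        }


@dataclass(frozen=True)
class SpeedParams:
    """Foraging-speed model: OU speed around a mean, heading diffusion, and a
    pause (immobility) point process whose bouts exercise the >2-s light
    interruption rule."""

    mean_cm_s: float = 15.0
    sd_cm_s: float = 5.0
    tau_s: float = 1.0
    heading_diffusion: float = 2.0  # rad / sqrt(s)
    pause_rate_hz: float = 1.0 / 40.0
    pause_mean_s: float = 3.0


def simulate_trajectory(
    arena: ArenaSpec,
    duration_s: float,
    speed_params: SpeedParams = SpeedParams(),
    seed: int | np.random.SeedSequence = 0,
    fs: float = 50.0,
) -> Trajectory:
    """Random-foraging path in the arena (reflective circular boundary).

    Heading performs a smoothed random walk while speed follows an
    Ornstein-Uhlenbeck process around ``mean_cm_s``; occasional exponential
    immobility bouts (zero speed) are inserted at rate ``pause_rate_hz``.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    if fs <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    dt = 1.0 / fs
    sp = speed_params
    R = arena.radius_cm * 0.98  # keep samples strictly inside the wall

    x = np.empty(n)
    y = np.empty(n)
    # start mid-radius at a random angle
    a0 = rng.uniform(0, 2 * np.pi)
    px, py = 0.5 * R * math.cos(a0), 0.5 * R * math.sin(a0)
    heading = rng.uniform(0, 2 * np.pi)
    v = max(sp.mean_cm_s, 0.0)

    dheads = rng.normal(0.0, sp.heading_diffusion * math.sqrt(dt), n)
    vnoise = rng.normal(0.0, 1.0, n)
    pause_u = rng.random(n)
    pause_len = rng.exponential(sp.pause_mean_s, n)

    ou_pull = dt / sp.tau_s
    ou_kick = sp.sd_cm_s * math.sqrt(2.0 * dt / sp.tau_s)
    pause_until = -1.0

    for i in range(n):
        t = i * dt
        x[i], y[i] = px, py
        if t < pause_until:
            continue
        if sp.pause_rate_hz > 0 and pause_u[i] < sp.pause_rate_hz * dt:
            pause_until = t + pause_len[i]
            continue
        v = v + (sp.mean_cm_s - v) * ou_pull + ou_kick * vnoise[i]
        if v < 0.0:
            v = 0.0
        heading += dheads[i]
        nx = px + v * math.cos(heading) * dt
        ny = py + v * math.sin(heading) * dt
        rr = math.hypot(nx, ny)
        if rr > R:
            # reflect the velocity about the wall tangent and retry
            nxn, nyn = nx / rr, ny / rr
            vx, vy = v * math.cos(heading), v * math.sin(heading)
            dot = vx * nxn + vy * nyn
            vx, vy = vx - 2 * dot * nxn, vy - 2 * dot * nyn
            heading = math.atan2(vy, vx)
            nx = px + vx * dt
            ny = py + vy * dt
            rr = math.hypot(nx, ny)
            if rr > R:  # corner case: pull back onto the wall
                nx, ny = nx * R / rr, ny * R / rr
        px, py = nx, ny

    t = np.arange(n) * dt
    return Trajectory(t=t, x=x, y=y, fs=fs)


def build_ensemble(
    n_pyr: int,
    n_int: int,
    arena: ArenaSpec,
    phenotype_props: Sequence[float] = DEFAULT_PHENOTYPE_PROPS,
    seed: int | np.random.SeedSequence = 0,
    *,
    gains: dict[str, float] | None = None,
    field_sigma_cm: float = 8.0,
    peak_range_hz: tuple[float, float] = (5.0, 20.0),
    field_count_probs: Sequence[float] = (0.5, 0.35, 0.15),
    baseline_hz: float = 0.1,
    rest_range_hz: tuple[float, float] = (1.0, 5.0),
    interneuron_rate_range_hz: tuple[float, float] = (5.0, 20.0),
    interneuron_suppressed_prob: float = DEFAULT_INTERNEURON_SUPPRESSED_PROB,
) -> tuple[list[PlaceCellModel], GroundTruth]:
    """Draw an ensemble of tuned units with assigned light-response phenotypes.

    Pyramidal cells carry 1..k Gaussian place fields (count drawn from
    ``field_count_probs``, centres uniform over the arena disc, peak rates
    log-uniform over ``peak_range_hz``); interneurons carry no spatial tuning,
    only a high baseline. Phenotypes are multinomial with ``phenotype_props``
    = (suppressed, disinhibited, remaining). Pass ``field_count_probs=(1.0,)``
    for strictly single-field cells.
    """
    if n_pyr < 0 or n_int < 0:
        raise InvalidArgumentError("unit counts must be non-negative")
    props = np.asarray(phenotype_props, dtype=float)
    if props.shape != (3,) or not math.isclose(props.sum(), 1.0, abs_tol=1e-6):
        raise InvalidArgumentError("phenotype_props must be 3 proportions summing to 1")
    gains = dict(DEFAULT_GAINS, **(gains or {}))
    rng = np.random.default_rng(seed)
    labels = ("suppressed", "disinhibited", "remaining")

    models: list[PlaceCellModel] = []
    gt = GroundTruth()
    R = arena.radius_cm
    fprobs = np.asarray(field_count_probs, dtype=float)
    fprobs = fprobs / fprobs.sum()
    for uid in range(n_pyr):
        n_fields = 1 + int(rng.choice(len(fprobs), p=fprobs))
        cell_fields = []
        for _ in range(n_fields):
            ang = rng.uniform(0, 2 * np.pi)
            rad = R * math.sqrt(rng.uniform())
            center = (rad * math.cos(ang), rad * math.sin(ang))
            peak = math.exp(
                rng.uniform(math.log(peak_range_hz[0]), math.log(peak_range_hz[1]))
            )
            cell_fields.append(GaussianField(center, field_sigma_cm, peak))
        rest = math.exp(rng.uniform(math.log(rest_range_hz[0]), math.log(rest_range_hz[1])))
        phen = labels[rng.choice(3, p=props)]
        models.append(
            PlaceCellModel(
                unit_id=uid,
                cell_type="pyramidal",
                fields=tuple(cell_fields),
                baseline_hz=baseline_hz,
                rest_hz=rest,
                phenotype=phen,
                light_gain=gains[phen],
            )
        )
    for j in range(n_int):
        uid = n_pyr + j
        rate = math.exp(
            rng.uniform(
                math.log(interneuron_rate_range_hz[0]),
                math.log(interneuron_rate_range_hz[1]),
            )
        )
        phen = "suppressed" if rng.uniform() < interneuron_suppressed_prob else "remaining"
        models.append(
            PlaceCellModel(
                unit_id=uid,
                cell_type="interneuron",
                fields=(),
                baseline_hz=rate,
                rest_hz=rate,
                phenotype=phen,
                light_gain=gains[phen],
            )
        )
    for m in models:
        gt.phenotype[m.unit_id] = m.phenotype
        gt.cell_type[m.unit_id] = m.cell_type
        gt.remapped[m.unit_id] = False
        gt.centers_pre[m.unit_id] = [list(f.center_xy) for f in m.fields]
        gt.centers_post[m.unit_id] = [list(f.center_xy) for f in m.fields]
    return models, gt


def light_on_mask(
    traj: Trajectory,
    zone: LightZone,
    immobility_cutoff_s: float = 2.0,
    move_eps_cm_s: float = 0.5,
) -> np.ndarray:
    """Per-sample illumination state for zone-gated light.

    Light is on when the animal is inside the zone, except that it is
    interrupted once the animal has been immobile for longer than the cutoff
    (and stays off until movement resumes).
    """
    in_zone = zone.contains(traj.x, traj.y)
    moving = traj.speed() > move_eps_cm_s
    n = len(moving)
    still_for = np.zeros(n)
    run = 0.0
    for i in range(n):
        run = 0.0 if moving[i] else run + traj.dt
        still_for[i] = run
    return in_zone & (still_for <= immobility_cutoff_s)


def mask_to_intervals(mask: np.ndarray, dt: float) -> np.ndarray:
    """Merge a per-sample boolean mask into [on, off) intervals (seconds)."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.empty((0, 2))
    d = np.diff(m.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.insert(starts, 0, 0)
    if m[-1]:
        stops = np.append(stops, len(m))
    return np.column_stack([starts * dt, stops * dt])


def _thin_spikes(
    rng: np.random.Generator,
    duration_s: float,
    rate_max_hz: float,
    rate_fn,
    rate_cap_hz: float,
) -> np.ndarray:
    """Draw an inhomogeneous Poisson train on [0, T) by thinning."""
    if rate_max_hz > rate_cap_hz:
        raise InvalidModelError(
            f"model rate {rate_max_hz:.1f} Hz exceeds cap {rate_cap_hz:.1f} Hz"
        )
    if rate_max_hz <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max_hz * duration_s)
    ts = np.sort(rng.uniform(0.0, duration_s, n_cand))
    lam = rate_fn(ts)
    keep = rng.uniform(0.0, rate_max_hz, n_cand) < lam
    return ts[keep]


def simulate_session(
    models: Sequence[PlaceCellModel],
    traj: Trajectory,
    protocol: Optional[LightProtocol] = None,
    seed: int | np.random.SeedSequence = 0,
    rate_cap_hz: float = 500.0,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Spike trains for one exploration session.

    Each unit fires as an inhomogeneous Poisson process with instantaneous
    rate tuning(position(t)) multiplied by its light gain whenever the light
    is on; spikes are drawn continuously by thinning. Returns the per-unit
    spike-time dict and the light-on intervals (empty array when no light).
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    if protocol is not None and protocol.mode != "zone-gated":
        raise InvalidArgumentError("exploration sessions take zone-gated protocols")
    if protocol is not None:
        mask = light_on_mask(traj, protocol.zone, protocol.immobility_cutoff_s)
        intervals = mask_to_intervals(mask, traj.dt)
    else:
        mask = None
        intervals = np.empty((0, 2))

    T = traj.duration_s
    spikes: dict[int, np.ndarray] = {}
    children = ss.spawn(len(models))
    for m, child in zip(models, children):
        rng = np.random.default_rng(child)
        gain = m.light_gain if protocol is not None else 1.0
        lam_max = m.max_rate_hz * max(1.0, gain)

        def rate_fn(ts, m=m, gain=gain):
            xs = np.interp(ts, traj.t, traj.x)
            ys = np.interp(ts, traj.t, traj.y)
            lam = m.rate_at(xs, ys)
            if mask is not None:
                idx = np.clip((ts * traj.fs).astype(int), 0, len(mask) - 1)
                on = mask[idx]
                lam = np.where(on, lam * gain, lam)
            return lam

        spikes[m.unit_id] = _thin_spikes(rng, T, lam_max, rate_fn, rate_cap_hz)
    return spikes, intervals


def simulate_pulse_session(
    models: Sequence[PlaceCellModel],
    protocol: LightProtocol = LightProtocol(mode="pulse-train"),
    seed: int | np.random.SeedSequence = 0,
    rate_cap_hz: float = 500.0,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Rest-box pulse-test session: baseline at each unit's rest rate, with the
    rate multiplied by the light gain inside each 400-ms pulse. Returns the
    spike trains and pulse onset times (540 pulses at the defaults)."""
    if protocol.mode != "pulse-train":
        raise InvalidArgumentError("simulate_pulse_session requires a pulse-train protocol")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    onsets = protocol.pulse_onsets()
    dur = protocol.pulse_duration_s
    T = protocol.duration_s
    spikes: dict[int, np.ndarray] = {}
    children = ss.spawn(len(models))
    for m, child in zip(models, children):
        rng = np.random.default_rng(child)
        lam_max = m.rest_hz * max(1.0, m.light_gain)

        def rate_fn(ts, m=m):
            k = np.searchsorted(onsets, ts, side="right") - 1
            k = np.clip(k, 0, len(onsets) - 1)
            in_pulse = (ts >= onsets[k]) & (ts < onsets[k] + dur)
            return np.where(in_pulse, m.rest_hz * m.light_gain, m.rest_hz)

        spikes[m.unit_id] = _thin_spikes(rng, T, lam_max, rate_fn, rate_cap_hz)
    return spikes, onsets


def apply_session_transition(
    models: Sequence[PlaceCellModel],
    gt: GroundTruth,
    rule: str,
    zone: Optional[LightZone] = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    prob: float = 1.0,
    factor: float = 1.5,
    redraw: str = "in-zone",
    scale_baseline: bool = False,
    arena: Optional[ArenaSpec] = None,
) -> tuple[list[PlaceCellModel], GroundTruth]:
    """Across-session plasticity rules applied to an ensemble.

    * ``"identity"`` — no change.
    * ``"remap-suppressed-in-zone"`` — with probability ``prob``, each
      suppressed cell that has a field centre inside the zone (the cells whose
      in-field firing the light actually perturbed) has those in-zone field
      centres redrawn, uniformly inside the zone (``redraw="in-zone"``) or
      over the whole arena (``redraw="arena"``); field centres outside the
      zone are left in place, matching the observed stability of out-zone
      place fields.
    * ``"persist-disinhibition"`` — multiplies the in-field peak rates of
      disinhibited cells by ``factor``; with ``scale_baseline=True`` the
      out-of-field baseline scales too, modelling a location-independent
      excitability increase rather than an in-field-only potentiation.

    Unit ids and counts are conserved; unaffected cells are returned unchanged.
    """
    if rule not in ("identity", "remap-suppressed-in-zone", "persist-disinhibition"):
        raise InvalidArgumentError(f"unknown transition rule {rule!r}")
    if not (0.0 <= prob <= 1.0):
        raise InvalidArgumentError("prob must lie in [0, 1]")
    if factor <= 0:
        raise InvalidArgumentError("factor must be positive")
    rng = np.random.default_rng(seed)
    out: list[PlaceCellModel] = []
    if rule == "identity":
        return list(models), gt

    if rule == "remap-suppressed-in-zone":
        if zone is None:
            raise InvalidArgumentError("remap rule requires a zone")
        radius = zone.radius_cm if arena is None else arena.radius_cm
        for m in models:
            eligible = m.phenotype == "suppressed" and any(
                bool(zone.contains(*f.center_xy)) for f in m.fields
            )
            if eligible and rng.uniform() < prob:
                new_fields = []
                for f in m.fields:
                    if not bool(zone.contains(*f.center_xy)):
                        new_fields.append(f)
                        continue
                    while True:
                        ang = rng.uniform(0, 2 * np.pi)
                        rad = radius * math.sqrt(rng.uniform())
                        cx, cy = rad * math.cos(ang), rad * math.sin(ang)
                        if redraw == "arena" or bool(zone.contains(cx, cy)):
                            break
                    new_fields.append(replace(f, center_xy=(cx, cy)))
                out.append(replace(m, fields=tuple(new_fields)))
                gt.remapped[m.unit_id] = True
                gt.centers_post[m.unit_id] = [list(f.center_xy) for f in new_fields]
            else:
                out.append(m)
        return out, gt

    # persist-disinhibition
    for m in models:
        if m.phenotype == "disinhibited":
            new_fields = tuple(replace(f, peak_hz=f.peak_hz * factor) for f in m.fields)
            new_base = m.baseline_hz * factor if scale_baseline else m.baseline_hz
            out.append(replace(m, fields=new_fields, baseline_hz=new_base))
        else:
            out.append(m)
    return out, gt


@dataclass
class ParadigmConfig:
    """Study-condition defaults for a full virtual experiment.

    Session length and pulse protocol follow the recording protocol (25-min
    exploration sessions; an 18-min pulse test at 0.5 Hz, i.e. 540 pulses).
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    zone_center_angle_deg: float = 150.0
    zone_width_deg: float = 180.0
    n_pyr: int = 64
    n_int: int = 6
    session_duration_s: float = 1500.0
    fs: float = 50.0
    speed_params: SpeedParams = field(default_factory=SpeedParams)
    phenotype_props: tuple[float, float, float] = DEFAULT_PHENOTYPE_PROPS
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    remap_prob: float = 1.0
    remap_redraw: str = "in-zone"
    persist_factor: float = 1.5
    persist_scale_baseline: bool = True
    pulse_duration_s: float = 0.4
    pulse_rate_hz: float = 0.5
    pulse_session_duration_s: float = 1080.0
    immobility_cutoff_s: float = 2.0

    def zone(self) -> LightZone:
        if not (120.0 <= self.zone_width_deg <= 180.0):
            raise InvalidArgumentError("zone width must lie in [120, 180] degrees")
        return LightZone(
            center_angle_deg=self.zone_center_angle_deg,
            width_deg=self.zone_width_deg,
            radius_cm=self.arena.radius_cm,
        )


@dataclass
class Dataset:
    """One virtual recording day: exploration sessions plus the pulse test."""

    paradigm: str
    arena: ArenaSpec
    zone: LightZone
    sessions: dict  # session_id -> {"trajectory", "spikes", "light_intervals", "role"}
    pulse_spikes: dict
    pulse_onsets: np.ndarray
    pulse_duration_s: float
    ground_truth: GroundTruth
    unit_ids: list[int]
    cell_types: dict[int, str]
    animal_id: str = "sim-0"

    @property
    def session_ids(self) -> list[str]:
        return list(self.sessions)


def generate_paradigm(
    paradigm: str,
    config: ParadigmConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> Dataset:
    """Generate a complete virtual experiment for one paradigm.

    familiar: identical ensemble in a1 and a2, zone-gated light in a2 only,
    the remap + persistence transition applied a2 -> a3.
    novel: fresh fields in b1 with zone-gated light, transition b1 -> b2,
    b2 -> b3 unchanged.
    """
    if paradigm not in ("familiar", "novel"):
        raise InvalidArgumentError(f"unknown paradigm {paradigm!r}")
    config = config or ParadigmConfig()
    zone = config.zone()
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_ens, s_tr1, s_tr2, s_tr3, s_sp1, s_sp2, s_sp3, s_pulse, s_trans1, s_trans2 = ss.spawn(10)

    models, gt = build_ensemble(
        config.n_pyr,
        config.n_int,
        config.arena,
        config.phenotype_props,
        seed=s_ens,
        gains=config.gains,
    )
    zone_protocol = LightProtocol(
        mode="zone-gated", zone=zone, immobility_cutoff_s=config.immobility_cutoff_s
    )
    pulse_protocol = LightProtocol(
        mode="pulse-train",
        pulse_duration_s=config.pulse_duration_s,
        pulse_rate_hz=config.pulse_rate_hz,
        duration_s=config.pulse_session_duration_s,
    )

    def traj(s):
        return simulate_trajectory(
            config.arena, config.session_duration_s, config.speed_params, seed=s, fs=config.fs
        )

    t1, t2, t3 = traj(s_tr1), traj(s_tr2), traj(s_tr3)
    sessions: dict[str, dict] = {}
    if paradigm == "familiar":
        names = ("a1", "a2", "a3")
        sp1, _ = simulate_session(models, t1, None, seed=s_sp1)
        sp2, light2 = simulate_session(models, t2, zone_protocol, seed=s_sp2)
        models3, gt = apply_session_transition(
            models, gt, "remap-suppressed-in-zone", zone, seed=s_trans1,
            prob=config.remap_prob, redraw=config.remap_redraw, arena=config.arena,
        )
        models3, gt = apply_session_transition(
            models3, gt, "persist-disinhibition", zone, seed=s_trans2,
            factor=config.persist_factor,
            scale_baseline=config.persist_scale_baseline,
        )
        sp3, _ = simulate_session(models3, t3, None, seed=s_sp3)
        sessions[names[0]] = {"trajectory": t1, "spikes": sp1, "light_intervals": None, "role": "a1"}
        sessions[names[1]] = {"trajectory": t2, "spikes": sp2, "light_intervals": light2, "role": "a2"}
        sessions[names[2]] = {"trajectory": t3, "spikes": sp3, "light_intervals": None, "role": "a3"}
        pulse_models = models3
    else:
        names = ("b1", "b2", "b3")
        sp1, light1 = simulate_session(models, t1, zone_protocol, seed=s_sp1)
        models2, gt = apply_session_transition(
            models, gt, "remap-suppressed-in-zone", zone, seed=s_trans1,
            prob=config.remap_prob, redraw=config.remap_redraw, arena=config.arena,
        )
        models2, gt = apply_session_transition(
            models2, gt, "persist-disinhibition", zone, seed=s_trans2,
            factor=config.persist_factor,
            scale_baseline=config.persist_scale_baseline,
        )
        sp2, _ = simulate_session(models2, t2, None, seed=s_sp2)
        sp3, _ = simulate_session(models2, t3, None, seed=s_sp3)
        sessions[names[0]] = {"trajectory": t1, "spikes": sp1, "light_intervals": light1, "role": "b1"}
        sessions[names[1]] = {"trajectory": t2, "spikes": sp2, "light_intervals": None, "role": "b2"}
        sessions[names[2]] = {"trajectory": t3, "spikes": sp3, "light_intervals": None, "role": "b3"}
        pulse_models = models2

    pulse_spikes, onsets = simulate_pulse_session(pulse_models, pulse_protocol, seed=s_pulse)
    gt.expected_signs = {
        "suppressed": {"c_in_light": -1},
        "disinhibited": {"c_in_light": +1, "c_in_post": +1},
    }
    return Dataset(
        paradigm=paradigm,
        arena=config.arena,
        zone=zone,
        sessions=sessions,
        pulse_spikes=pulse_spikes,
        pulse_onsets=onsets,
        pulse_duration_s=config.pulse_duration_s,
        ground_truth=gt,
        unit_ids=[m.unit_id for m in models],
        cell_types={m.unit_id: m.cell_type for m in models},
    )
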