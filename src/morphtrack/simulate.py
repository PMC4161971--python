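"""Synthetic sessions: schedules, foraging trajectories and place-cell spikes.

The generator emulates the alternation task: a rat shuttles between the two
food wells of a morphing U-track while the arms are repositioned during the
reward pauses.  Place cells carry a single, roughly Gaussian field whose
*anchoring* is the experimental variable:

``planar``
    the field is a fixed point of the room; firing depends on the animal's
    room-frame distance to it, wherever the track happens to lie.
``linear_fraction``
    the field sits at a fixed fraction of the track's elastic skeleton, so it
    stretches and shrinks with local deformations (the topological reading).
``segment_bound``
    the field rides a material segment wherever that segment is moved
    (feature binding).
``distance_from_well``
    the field sits at a fixed arc distance from one food well (reduced 1D
    path integration).

Spiking is an inhomogeneous Poisson process realised by thinning against the
cell's maximum rate, with piecewise-constant rates at the position sampling
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .geometry import (
    N_SECTIONS,
    PROTRUSION_SIDES,
    SECTION_WIDTH_CM,
    InvalidParameterError,
    PlanarLayout,
    TrackConfiguration,
    TrackModel,
    layout_planar,
    make_configuration,
    material_span,
    section_of_extent,
    with_protrusion,
)
from .session import ConfigSchedule, Epoch, SpikeTrain, SpikeTrains, Trajectory

__all__ = [
    "BehaviorParams",
    "PlaceCellModel",
    "ANCHORINGS",
    "simulate_schedule",
    "constant_schedule",
    "simulate_trajectory",
    "make_place_cells",
    "apply_rate_remapping",
    "instantaneous_rate",
    "rate_on_trajectory",
    "simulate_spikes",
]

ANCHORINGS = ("planar", "linear_fraction", "segment_bound", "distance_from_well")

_STREAMS = {"schedule": 0, "trajectory": 1, "cells": 2, "spikes": 3}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Deterministic sub-stream of one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, extra)]))


@dataclass(frozen=True)
class BehaviorParams:
    """Running-behaviour parameters of the simulated animal.

    Defaults are calibrated to the task: ~34 s well-to-well runs on the 4 m
    track (mean speed 400/34 ≈ 11.8 cm/s), short reward pauses during which
    the track is repositioned, and a lateral wobble small compared to the
    8 cm track width.
    """

    mean_speed: float = 11.8       # cm/s, mean forward running speed
    speed_sd: float = 1.0          # cm/s, across-run speed variability
    pause_mean_s: float = 8.0      # reward pause at a well
    pause_sd_s: float = 1.0
    lateral_jitter_sd: float = 2.0  # cm, s.d. of lateral wobble while running
    pause_jitter_sd: float = 0.3   # cm, lateral wobble while paused
    sampling_rate: float = 25.0    # Hz

    def __post_init__(self) -> None:
        if self.mean_speed <= 0 or self.sampling_rate <= 0:
            raise InvalidParameterError("speed and sampling rate must be positive")


# ---------------------------------------------------------------------------
# configuration schedules
# ---------------------------------------------------------------------------

def _stratified_extents(rng: np.random.Generator, n: int,
                        track: TrackModel) -> np.ndarray:
    """n well extents covering the 12-section sweep near-uniformly.

    Sections are drawn as shuffled decks of the 12 labels so that every
    section is hit at least floor(n/12) times; the extent within a section is
    uniform.  With iid-uniform draws the coverage contract (every section
    >= 3 visits at n = 40) would essentially never hold.
    """
    reps = max(1, math.ceil(n / N_SECTIONS))
    deck = np.concatenate([rng.permutation(N_SECTIONS) for _ in range(reps)])[:n]
    origin = track.section_grid_origin
    lo = origin + deck * SECTION_WIDTH_CM
    return lo + rng.uniform(0.0, SECTION_WIDTH_CM, size=n)


def simulate_schedule(track: TrackModel, n_moves: int = 40, seed: int = 0,
                      behavior: BehaviorParams | None = None,
                      extent_sampler: Callable[[np.random.Generator, int, TrackModel], np.ndarray] | None = None,
                      ) -> ConfigSchedule:
    """Track A schedule: ``n_moves`` configuration epochs, one run each.

    Both arm extents are re-sampled at every move (executed during the reward
    pause); the two arms' extent sequences are independent.  Epoch durations
    are pre-drawn (pause + one well-to-well run) so that configuration changes
    land exactly on pauses.  The schedule is flagged when some vertical
    section ends up visited fewer than 3 times (possible for n_moves < 36).
    """
    if track.track_id != "A":
        raise InvalidParameterError("simulate_schedule generates Track A sessions")
    if n_moves < 1:
        raise InvalidParameterError("n_moves must be >= 1")
    behavior = behavior or BehaviorParams()
    rng = _rng(seed, "schedule")
    sampler = extent_sampler or _stratified_extents
    top = sampler(rng, n_moves, track)
    bottom = sampler(rng, n_moves, track)

    epochs: list[Epoch] = []
    t = 0.0
    for i in range(n_moves):
        cfg = make_configuration(track, top[i], bottom[i], config_id=f"c{i:03d}")
        pause = max(2.0, rng.normal(behavior.pause_mean_s, behavior.pause_sd_s))
        speed = float(np.clip(rng.normal(behavior.mean_speed, behavior.speed_sd),
                              6.0, 20.0))
        dur = pause + track.total_length / speed
        epochs.append(Epoch(cfg, t, t + dur, start_well=i % 2,
                            pause_s=pause, run_speed=speed))
        t += dur

    counts = {arm: np.zeros(N_SECTIONS, dtype=int) for arm in ("top", "bottom")}
    for e in epochs:
        counts["top"][section_of_extent(track, e.config.top_extent) - 1] += 1
        counts["bottom"][section_of_extent(track, e.config.bottom_extent) - 1] += 1
    bad = [(arm, v + 1) for arm in counts for v in
           np.nonzero(counts[arm] < 3)[0]]
    note = ("" if not bad else
            "sections visited fewer than 3 times: " +
            ", ".join(f"{arm} V={v}" for arm, v in bad))
    return ConfigSchedule(track, epochs, coverage_ok=not bad, coverage_note=note)


def constant_schedule(track: TrackModel, cfg: TrackConfiguration,
                      duration_s: float) -> ConfigSchedule:
    """A single-epoch schedule (used for Track B run sessions)."""
    return ConfigSchedule(track, [Epoch(cfg, 0.0, float(duration_s))])


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(track: TrackModel, schedule: ConfigSchedule,
                        behavior: BehaviorParams | None = None,
                        seed: int = 0) -> Trajectory:
    """Alternation runs between the wells under the scheduled poses.

    Within an epoch the animal pauses at its current well and then runs to
    the other one at a constant (per-run) forward speed, with a smooth
    lateral wobble about the midline; poses change only at epoch boundaries,
    i.e. while the animal is paused at a well.
    """
    behavior = behavior or BehaviorParams()
    rng = _rng(seed, "trajectory")
    dt = 1.0 / behavior.sampling_rate
    L = track.total_length

    # phases: (t0, t1, epoch_idx, x_l at t0, x_l at t1, is_pause)
    phases: list[tuple[float, float, int, float, float, bool]] = []
    well = schedule.epochs[0].start_well
    for ei, ep in enumerate(schedule.epochs):
        t = ep.t_start
        first = True
        well = ep.start_well if ep.pause_s is not None else well
        while t < ep.t_end - 1e-9:
            pause = (ep.pause_s if first and ep.pause_s is not None else
                     max(2.0, rng.normal(behavior.pause_mean_s, behavior.pause_sd_s)))
            speed = (ep.run_speed if first and ep.run_speed is not None else
                     float(np.clip(rng.normal(behavior.mean_speed, behavior.speed_sd),
                                   6.0, 20.0)))
            first = False
            wx = 0.0 if well == 0 else L
            p1 = min(t + pause, ep.t_end)
            phases.append((t, p1, ei, wx, wx, True))
            t = p1
            if t >= ep.t_end - 1e-9:
                break
            run_t = L / speed
            r1 = min(t + run_t, ep.t_end)
            x1 = wx + (L - 2 * wx) * (r1 - t) / run_t
            phases.append((t, r1, ei, wx, x1, False))
            t = r1
            if abs(x1 - (L - wx)) < 1e-6:
                well = 1 - well

    n = int(math.floor(schedule.t_end / dt))
    t_s = np.arange(n) * dt
    x_l = np.empty(n)
    epoch_idx = np.empty(n, dtype=int)
    is_pause = np.zeros(n, dtype=bool)
    for (t0, t1, ei, xa, xb, pz) in phases:
        i0 = int(np.searchsorted(t_s, t0 - 1e-12))
        i1 = int(np.searchsorted(t_s, t1 - 1e-12))
        if i1 <= i0:
            continue
        frac = (t_s[i0:i1] - t0) / max(t1 - t0, 1e-12)
        x_l[i0:i1] = xa + (xb - xa) * frac
        epoch_idx[i0:i1] = ei
        is_pause[i0:i1] = pz

    # smooth lateral wobble: box-smoothed OU, scaled down while paused
    tau = 1.0
    a = math.exp(-dt / tau)
    eps = rng.normal(0.0, math.sqrt(1 - a * a), size=n)
    u = _ou_filter(eps, a)
    k = 13
    u = np.convolve(u, np.ones(k) / k, mode="same")
    sd = np.where(is_pause, behavior.pause_jitter_sd, behavior.lateral_jitter_sd)
    half_w = track.track_width / 2
    y_l = np.clip(u * sd, -half_w, half_w)

    x = np.empty(n)
    y = np.empty(n)
    layouts = schedule.layouts()
    bounds = np.searchsorted(epoch_idx, np.arange(len(schedule.epochs) + 1))
    for ei, (i0, i1) in enumerate(zip(bounds, bounds[1:])):
        if i1 > i0:
            p = layouts[ei].to_planar(x_l[i0:i1], y_l[i0:i1])
            x[i0:i1], y[i0:i1] = p[:, 0], p[:, 1]
    return Trajectory(track, schedule, t_s, x, y, x_l, y_l, epoch_idx)


def _ou_filter(eps: np.ndarray, a: float) -> np.ndarray:
    """Stationary AR(1) recursion u[i] = a u[i-1] + eps[i]."""
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -a], eps)


# ---------------------------------------------------------------------------
# place cells
# ---------------------------------------------------------------------------

@dataclass
class PlaceCellModel:
    """A single-field place cell with Gaussian tuning in its anchored frame."""

    cell_id: str
    anchoring: Literal["planar", "linear_fraction", "segment_bound",
                       "distance_from_well"]
    sigma_cm: float = 10.0
    peak_hz: float = 15.0
    baseline_hz: float = 0.1
    center_planar: tuple[float, float] | None = None
    center_fraction: float | None = None
    segment: int | None = None
    segment_fraction: float | None = None
    well: str | None = None
    well_distance: float | None = None
    gains: dict[str, float] | None = None   # per-config rate-remapping gains

    def __post_init__(self) -> None:
        if self.anchoring not in ANCHORINGS:
            raise InvalidParameterError(f"unknown anchoring {self.anchoring!r}")
        if not (self.peak_hz > self.baseline_hz >= 0):
            raise InvalidParameterError("need peak > baseline >= 0")
        if self.sigma_cm <= 0:
            raise InvalidParameterError("field width must be positive")

    def max_rate(self) -> float:
        g = max(self.gains.values()) if self.gains else 1.0
        return self.baseline_hz + (self.peak_hz - self.baseline_hz) * g

    def gain_for(self, config_id: str) -> float:
        return 1.0 if not self.gains else self.gains.get(config_id, 1.0)


def make_place_cells(track: TrackModel, n: int, anchoring: str, seed: int = 0,
                     sigma_cm: float = 10.0, peak_hz: float = 15.0,
                     baseline_hz: float = 0.1,
                     field_param_sampler: Callable[[np.random.Generator, int], dict] | None = None,
                     ) -> list[PlaceCellModel]:
    """Sample ``n`` place cells with centers uniform over the anchored range."""
    if anchoring not in ANCHORINGS:
        raise InvalidParameterError(f"unknown anchoring {anchoring!r}")
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    rng = _rng(seed, "cells")
    cells: list[PlaceCellModel] = []
    for i in range(n):
        kw: dict = dict(cell_id=f"{anchoring[:3]}{i:03d}", anchoring=anchoring,
                        sigma_cm=sigma_cm, peak_hz=peak_hz, baseline_hz=baseline_hz)
        if anchoring == "linear_fraction":
            kw["center_fraction"] = rng.uniform()
        elif anchoring == "distance_from_well":
            kw["well"] = track.well_ids[int(rng.integers(2))]
            kw["well_distance"] = rng.uniform(0.0, track.total_length)
        elif anchoring == "segment_bound":
            kw["segment"] = int(rng.integers(1, track.n_segments + 1))
            kw["segment_fraction"] = rng.uniform()
        else:  # planar: a point on the midline of a random reachable pose
            if track.track_id == "A":
                lo = track.section_grid_origin
                cfg = make_configuration(track, rng.uniform(lo, track.extent_max),
                                         rng.uniform(lo, track.extent_max))
            else:
                cfg = with_protrusion(track, PROTRUSION_SIDES[int(rng.integers(2))])
            lay = layout_planar(track, cfg)
            p = lay.to_planar(rng.uniform(0.0, lay.total_length))
            kw["center_planar"] = (float(p[0, 0]), float(p[0, 1]))
        if field_param_sampler is not None:
            kw.update(field_param_sampler(rng, i))
        cells.append(PlaceCellModel(**kw))
    return cells


def apply_rate_remapping(cells: Sequence[PlaceCellModel],
                         schedule: ConfigSchedule, gain_sd: float = 0.3,
                         seed: int = 0) -> list[PlaceCellModel]:
    """Give every cell an independent log-normal rate gain per configuration.

    Rate remapping scales the field's peak without moving its anchored
    center.
    """
    rng = _rng(seed, "cells", 1)
    out = []
    for cell in cells:
        gains = {e.config.config_id:
                 float(np.exp(rng.normal(0.0, gain_sd)))
                 for e in schedule.epochs}
        kw = {**cell.__dict__, "gains": gains}
        out.append(PlaceCellModel(**kw))
    return out


# ---------------------------------------------------------------------------
# firing rates and spikes
# ---------------------------------------------------------------------------

def _anchored_distance(cell: PlaceCellModel, track: TrackModel,
                       layout: PlanarLayout, x: np.ndarray, y: np.ndarray,
                       x_l: np.ndarray) -> np.ndarray:
    """Distance from each sample to the field center, in the anchored frame."""
    if cell.anchoring == "planar":
        cx, cy = cell.center_planar
        return np.hypot(x - cx, y - cy)
    if cell.anchoring == "linear_fraction":
        center = cell.center_fraction * layout.axis_length
        return np.abs(layout.axis_of(x_l) - center)
    if cell.anchoring == "distance_from_well":
        xw = x_l if cell.well == track.well_ids[0] else layout.total_length - x_l
        return np.abs(xw - cell.well_distance)
    span = material_span(track, layout.cfg, cell.segment)
    center = span[0] + cell.segment_fraction * (span[1] - span[0])
    return np.abs(x_l - center)


def instantaneous_rate(cell: PlaceCellModel, track: TrackModel,
                       cfg: TrackConfiguration, x: float, y: float,
                       x_l: float) -> float:
    """Firing rate (Hz) at one on-track sample under one pose."""
    layout = layout_planar(track, cfg)
    d = _anchored_distance(cell, track, layout,
                           np.array([x]), np.array([y]), np.array([x_l]))
    g = cell.gain_for(cfg.config_id)
    return float(cell.baseline_hz + (cell.peak_hz - cell.baseline_hz) * g
                 * np.exp(-d[0] ** 2 / (2 * cell.sigma_cm ** 2)))


def rate_on_trajectory(cell: PlaceCellModel, traj: Trajectory,
                       layouts: list[PlanarLayout] | None = None) -> np.ndarray:
    """Vectorized firing rate at every trajectory sample."""
    track = traj.track
    layouts = layouts or traj.schedule.layouts()
    rate = np.empty(traj.n)
    for ei, sl in enumerate(traj.epoch_slices()):
        if sl.stop <= sl.start:
            continue
        d = _anchored_distance(cell, track, layouts[ei],
                               traj.x[sl], traj.y[sl], traj.x_l[sl])
        g = cell.gain_for(traj.schedule.epochs[ei].config.config_id)
        rate[sl] = (cell.baseline_hz + (cell.peak_hz - cell.baseline_hz) * g
                    * np.exp(-d ** 2 / (2 * cell.sigma_cm ** 2)))
    return rate


def simulate_spikes(traj: Trajectory, cells: Sequence[PlaceCellModel],
                    seed: int = 0) -> SpikeTrains:
    """Inhomogeneous Poisson spikes by thinning against each cell's max rate.

    Rates are piecewise constant at the trajectory sampling resolution; the
    expected spike count is the time integral of the rate along the
    trajectory.  Deterministic given the seed (one sub-stream per cell).
    """
    if traj.n < 2:
        return SpikeTrains([])
    t0, t1 = float(traj.t[0]), float(traj.t[-1])
    layouts = traj.schedule.layouts()
    trains = []
    for ci, cell in enumerate(cells):
        rng = _rng(seed, "spikes", ci)
        lam = cell.max_rate()
        rate = rate_on_trajectory(cell, traj, layouts)
        n_cand = rng.poisson(lam * (t1 - t0)) if lam > 0 else 0
        times = np.sort(rng.uniform(t0, t1, size=n_cand))
        si = np.clip(np.searchsorted(traj.t, times, side="right") - 1, 0, traj.n - 1)
        keep = rng.uniform(0.0, 1.0, size=n_cand) * lam < rate[si]
        tt = times[keep]
        pos = traj.interp_at(tt)
        trains.append(SpikeTrain(cell.cell_id, tt, pos["x"], pos["y"],
                                 pos["x_l"], pos["y_l"], pos["epoch_idx"]))
    return SpikeTrains(trains)
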