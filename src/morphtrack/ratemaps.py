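"""Occupancy-normalized rate maps in the planar and linear frames.

Space is binned into 3 x 3 cm squares.  Because the absolute placement of
the bin grid is arbitrary, rates are averaged over several random grid
shifts of up to half a bin in each direction; no other smoothing is applied.
Unvisited bins are *undefined* (NaN), never zero, so correlations can never
be inflated by shared empty space.

Samples (and spikes) taken while the animal moved slower than 3 cm/s are
excluded from everything downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import InvalidParameterError, TrackModel
from .session import SpikeTrain, SpikeTrains, Trajectory

__all__ = [
    "BinGrid",
    "RateMap",
    "EmptyMapError",
    "planar_grid",
    "linear_grid",
    "profile_grid",
    "draw_shifts",
    "speed_filter",
    "compute_occupancy",
    "compute_rate_map",
    "peak_rate",
]

DEFAULT_BIN_CM = 3.0
V_MIN_CM_S = 3.0


class EmptyMapError(ValueError):
    """A rate map with no visited bins where one is required."""


@dataclass(frozen=True)
class BinGrid:
    """A rectangular bin grid in one reference frame.

    Bins are half-open ``[left, right)`` intervals.  The flattening order that
    turns a map into an activity vector starts at the top-right bin and runs
    down each column, moving leftward column by column; it is a fixed
    bijection between bins and vector positions.
    """

    frame: str                  # "planar" or "linear"
    x0: float
    y0: float
    n_x: int
    n_y: int
    bin_w: float = DEFAULT_BIN_CM
    bin_h: float = DEFAULT_BIN_CM

    def __post_init__(self) -> None:
        if self.bin_w <= 0 or self.bin_h <= 0 or self.n_x < 1 or self.n_y < 1:
            raise InvalidParameterError("bin size and counts must be positive")

    @property
    def n_bins(self) -> int:
        return self.n_x * self.n_y

    def bin_indices(self, cx: np.ndarray, cy: np.ndarray,
                    offset: tuple[float, float] = (0.0, 0.0)
                    ) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(cx) - self.x0 - offset[0]) / self.bin_w).astype(int)
        iy = np.floor((np.asarray(cy) - self.y0 - offset[1]) / self.bin_h).astype(int)
        if len(ix) and (ix.min() < 0 or ix.max() >= self.n_x
                        or iy.min() < 0 or iy.max() >= self.n_y):
            raise InvalidParameterError(
                "data fall outside the bin grid; enlarge the grid margins")
        return ix, iy

    def flat_indices(self, cx, cy, offset=(0.0, 0.0)) -> np.ndarray:
        ix, iy = self.bin_indices(cx, cy, offset)
        return ix * self.n_y + iy

    def vector_position(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        """0-based position of bin (ix, iy) in the activity vector."""
        ix, iy = np.asarray(ix), np.asarray(iy)
        return (self.n_x - 1 - ix) * self.n_y + (self.n_y - 1 - iy)

    def flatten(self, values: np.ndarray) -> np.ndarray:
        """Reorder an (n_x, n_y) map into the activity vector."""
        ix, iy = np.meshgrid(np.arange(self.n_x), np.arange(self.n_y),
                             indexing="ij")
        out = np.empty(self.n_bins, dtype=values.dtype)
        out[self.vector_position(ix.ravel(), iy.ravel())] = values.ravel()
        return out

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_x) + 0.5) * self.bin_w

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_y) + 0.5) * self.bin_h


def planar_grid(track: TrackModel, bin_cm: float = DEFAULT_BIN_CM,
                margin: float = 12.0) -> BinGrid:
    """Room-frame grid covering every reachable pose of the track."""
    L = track.segment_length
    if track.track_id == "A":
        x_lo, x_hi = -margin, track.arm_length + margin
        y_lo, y_hi = -L - margin, 2 * L + L + margin
    else:
        x_lo, x_hi = -margin, 4 * L + margin
        y_lo, y_hi = -L - margin, 2 * L + margin
    n_x = int(np.ceil((x_hi - x_lo) / bin_cm))
    n_y = int(np.ceil((y_hi - y_lo) / bin_cm))
    return BinGrid("planar", x_lo, y_lo, n_x, n_y, bin_cm, bin_cm)


def linear_grid(track: TrackModel, bin_cm: float = DEFAULT_BIN_CM) -> BinGrid:
    """Track-frame grid: x_L along the track, three lateral y_L bins.

    One padding bin on each side keeps shifted grids in range; the 8-9 cm
    track width itself maps onto the three central lateral bins.
    """
    n_x = int(np.ceil(track.total_length / bin_cm)) + 2
    return BinGrid("linear", -bin_cm, -2.5 * bin_cm, n_x, 5, bin_cm, bin_cm)


def profile_grid(track: TrackModel, bin_cm: float = DEFAULT_BIN_CM) -> BinGrid:
    """Track-frame 1D profile grid: x_L bins, a single full-width lateral bin."""
    n_x = int(np.ceil(track.total_length / bin_cm)) + 2
    return BinGrid("linear", -bin_cm, -12.5, n_x, 1, bin_cm, 25.0)


def draw_shifts(grid: BinGrid, n_shifts: int,
                rng: np.random.Generator) -> np.ndarray:
    """Random grid offsets, uniform within +/- half a bin per axis.

    For single-row profile grids the lateral bin spans the whole track width,
    so only the along-track axis is shifted.
    """
    if n_shifts < 1:
        raise InvalidParameterError("n_shifts must be >= 1")
    sx = rng.uniform(-grid.bin_w / 2, grid.bin_w / 2, size=n_shifts)
    if grid.n_y == 1:
        sy = np.zeros(n_shifts)
    else:
        sy = rng.uniform(-grid.bin_h / 2, grid.bin_h / 2, size=n_shifts)
    return np.stack([sx, sy], axis=1)


# ---------------------------------------------------------------------------
# speed filtering
# ---------------------------------------------------------------------------

def speed_filter(traj: Trajectory,
                 spikes: SpikeTrains | SpikeTrain | None = None,
                 v_min: float = V_MIN_CM_S, smooth_samples: int = 5):
    """Flag samples and spikes taken below ``v_min`` cm/s as excluded.

    Speed is the central difference of box-smoothed room positions (the
    estimator is a convention; the exclusion criterion is the 3 cm/s floor).
    Returns a new trajectory (with ``speed``/``included`` set) and, when
    spike trains are given, new spike trains with per-spike inclusion flags
    from the speed interpolated at the spike time.  Inputs are not modified.
    """
    if traj.n == 0:
        warnings.warn("speed_filter: empty trajectory")
        return (traj, spikes) if spikes is not None else traj
    k = max(1, int(smooth_samples))
    kern = np.ones(k) / k
    xs = _smooth_edge(traj.x, kern)
    ys = _smooth_edge(traj.y, kern)
    if traj.n == 1:
        v = np.zeros(1)
    else:
        dx = np.gradient(xs, traj.t)
        dy = np.gradient(ys, traj.t)
        v = np.hypot(dx, dy)
    out_traj = dataclasses.replace(traj, speed=v, included=v >= v_min)
    if spikes is None:
        return out_traj
    single = isinstance(spikes, SpikeTrain)
    trains = [spikes] if single else list(spikes)
    out_trains = [dataclasses.replace(
        tr, included=np.interp(tr.t, traj.t, v) >= v_min) for tr in trains]
    return out_traj, (out_trains[0] if single else SpikeTrains(out_trains))


def _smooth_edge(a: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Box smoothing; odd reflection at the edges keeps uniform motion
    uniform right up to the session boundaries."""
    h = len(kern) // 2
    if h == 0 or len(a) < 2:
        return a.astype(float)
    pad = np.pad(a.astype(float), h, mode="reflect", reflect_type="odd")
    return np.convolve(pad, kern, mode="valid")


# ---------------------------------------------------------------------------
# occupancy and rate maps
# ---------------------------------------------------------------------------

def _frame_coords(obj, frame: str) -> tuple[np.ndarray, np.ndarray]:
    return (obj.x, obj.y) if frame == "planar" else (obj.x_l, obj.y_l)


def _sample_weights(traj: Trajectory) -> np.ndarray:
    """Duration of each inter-sample interval, assigned to its first sample."""
    dt = np.diff(traj.t, append=traj.t[-1] if traj.n else 0.0)
    return dt


def compute_occupancy(traj: Trajectory, grid: BinGrid,
                      offset: tuple[float, float] = (0.0, 0.0),
                      sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Seconds spent per bin (included samples only)."""
    sel = traj.included if traj.included is not None else np.ones(traj.n, bool)
    if sample_mask is not None:
        sel = sel & sample_mask
    cx, cy = _frame_coords(traj, grid.frame)
    w = _sample_weights(traj)
    flat = grid.flat_indices(cx[sel], cy[sel], offset)
    occ = np.bincount(flat, weights=w[sel], minlength=grid.n_bins)
    return occ.reshape(grid.n_x, grid.n_y)


@dataclass
class RateMap:
    """Occupancy-normalized rates of one cell on one bin grid.

    ``rate`` is the across-shift average of count/occupancy, NaN on bins
    never visited in any shift; ``occupancy``/``counts`` are the unshifted
    quantities used for masking and conservation checks.
    """

    grid: BinGrid
    occupancy: np.ndarray
    counts: np.ndarray
    rate: np.ndarray
    visited: np.ndarray
    n_shifts: int
    cell_id: str | None = None
    group: str | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    def vector(self) -> np.ndarray:
        """Activity vector: rates in the grid's flattening order."""
        return self.grid.flatten(self.rate)


def compute_rate_map(traj: Trajectory, spikes: SpikeTrain, grid: BinGrid,
                     n_shifts: int = 25, seed: int = 0,
                     shifts: np.ndarray | None = None,
                     sample_mask: np.ndarray | None = None,
                     spike_mask: np.ndarray | None = None) -> RateMap:
    """Grid-shift-averaged occupancy-normalized rate map.

    For each random offset the grid is shifted rigidly, count/occupancy is
    computed per (shifted) bin, and the per-bin rates are averaged over the
    shifts in which the bin was visited.  With ``n_shifts=1`` and a zero
    shift this reduces exactly to count/occupancy.  Pass ``shifts`` to share
    one set of offsets across the maps that will be correlated.
    """
    if shifts is None:
        rng = np.random.default_rng(seed)
        shifts = draw_shifts(grid, n_shifts, rng)
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))

    s_sel = traj.included if traj.included is not None else np.ones(traj.n, bool)
    if sample_mask is not None:
        s_sel = s_sel & sample_mask
    k_sel = spikes.included if spikes.included is not None else np.ones(spikes.n, bool)
    if spike_mask is not None:
        k_sel = k_sel & spike_mask

    cx, cy = _frame_coords(traj, grid.frame)
    cx, cy = cx[s_sel], cy[s_sel]
    w = _sample_weights(traj)[s_sel]
    sx, sy = _frame_coords(spikes, grid.frame)
    sx, sy = sx[k_sel], sy[k_sel]

    nb = grid.n_bins
    rate_sum = np.zeros(nb)
    rate_n = np.zeros(nb, dtype=int)
    occ0 = cnt0 = None
    for j, off in enumerate(shifts):
        flat_s = grid.flat_indices(cx, cy, tuple(off))
        occ = np.bincount(flat_s, weights=w, minlength=nb)
        flat_k = grid.flat_indices(sx, sy, tuple(off))
        cnt = np.bincount(flat_k, minlength=nb).astype(float)
        vis = occ > 0
        rate_sum[vis] += cnt[vis] / occ[vis]
        rate_n[vis] += 1
        if j == 0:
            occ0, cnt0 = occ, cnt
    if np.allclose(shifts[0], 0.0) or len(shifts) == 1:
        occ_ref, cnt_ref = occ0, cnt0
    else:
        occ_ref = np.bincount(grid.flat_indices(cx, cy), weights=w, minlength=nb)
        cnt_ref = np.bincount(grid.flat_indices(sx, sy), minlength=nb).astype(float)
    visited = rate_n > 0
    rate = np.full(nb, np.nan)
    rate[visited] = rate_sum[visited] / rate_n[visited]
    shape = (grid.n_x, grid.n_y)
    return RateMap(grid, occ_ref.reshape(shape), cnt_ref.reshape(shape),
                   rate.reshape(shape), visited.reshape(shape),
                   n_shifts=len(shifts), cell_id=spikes.cell_id)


def peak_rate(rate_map: RateMap) -> float:
    """Maximum occupancy-normalized rate over visited bins (Hz)."""
    if not rate_map.visited.any():
        raise EmptyMapError("rate map has no visited bins")
    return float(np.nanmax(rate_map.rate))


def peak_bin_xl(rate_map: RateMap) -> float:
    """x_L of the peak-rate bin center of a linear-frame map."""
    if rate_map.grid.frame != "linear":
        raise InvalidParameterError("peak_bin_xl needs a linear-frame map")
    if not rate_map.visited.any():
        raise EmptyMapError("rate map has no visited bins")
    flat = np.nanargmax(np.where(rate_map.visited, rate_map.rate, -np.inf))
    ix = flat // rate_map.grid.n_y
    return float(rate_map.grid.x_centers()[ix])
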