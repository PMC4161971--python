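"""In-memory containers for a recording session.

A session is a configuration schedule (which pose the track held when), a
position trajectory sampled at a fixed rate, and one spike train per cell.
Positions and spikes carry both reference frames: room coordinates (x, y)
and track coordinates (x_L, y_L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .geometry import PlanarLayout, TrackConfiguration, TrackModel, layout_planar

__all__ = ["Epoch", "ConfigSchedule", "Trajectory", "SpikeTrain", "SpikeTrains"]


@dataclass(frozen=True)
class Epoch:
    """One configuration epoch: a frozen pose held over [t_start, t_end)."""

    config: TrackConfiguration
    t_start: float
    t_end: float
    start_well: int = 0          # 0 = F1, 1 = F2 (well occupied at epoch start)
    pause_s: float | None = None
    run_speed: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ConfigSchedule:
    """Ordered, contiguous configuration epochs for one session."""

    track: TrackModel
    epochs: list[Epoch]
    coverage_ok: bool = True
    coverage_note: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def n_moves(self) -> int:
        return len(self.epochs)

    @property
    def t_end(self) -> float:
        return self.epochs[-1].t_end

    @property
    def configurations(self) -> list[TrackConfiguration]:
        return [e.config for e in self.epochs]

    def epoch_of(self, times: np.ndarray) -> np.ndarray:
        """Epoch index of each time (clipped to the session)."""
        starts = np.array([e.t_start for e in self.epochs])
        return np.clip(np.searchsorted(starts, np.asarray(times), side="right") - 1,
                       0, len(self.epochs) - 1)

    def layouts(self) -> list[PlanarLayout]:
        return [layout_planar(self.track, e.config) for e in self.epochs]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.epochs:
            row = {"config_id": e.config.config_id,
                   "t_start_s": e.t_start, "t_end_s": e.t_end}
            if self.track.track_id == "A":
                row["top_extent_cm"] = e.config.top_extent
                row["bottom_extent_cm"] = e.config.bottom_extent
            else:
                row["protrusion_side"] = e.config.protrusion_side
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Time-stamped positions in both frames, with per-sample epoch labels.

    ``speed`` and ``included`` are filled by :func:`morphtrack.ratemaps.speed_filter`.
    """

    track: TrackModel
    schedule: ConfigSchedule
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_l: np.ndarray
    y_l: np.ndarray
    epoch_idx: np.ndarray
    speed: np.ndarray | None = None
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def config_ids(self) -> np.ndarray:
        ids = np.array([e.config.config_id for e in self.schedule.epochs])
        return ids[self.epoch_idx]

    def epoch_slices(self) -> list[slice]:
        """Contiguous sample slice per epoch (samples are time ordered)."""
        bounds = np.searchsorted(self.epoch_idx,
                                 np.arange(len(self.schedule.epochs) + 1))
        return [slice(int(a), int(b)) for a, b in zip(bounds, bounds[1:])]

    def interp_at(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """Interpolate positions (both frames) at arbitrary times."""
        out = {}
        for name in ("x", "y", "x_l", "y_l"):
            out[name] = np.interp(times, self.t, getattr(self, name))
        out["epoch_idx"] = self.schedule.epoch_of(times)
        if self.speed is not None:
            out["speed"] = np.interp(times, self.t, self.speed)
        return out

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y,
                           "x_l_cm": self.x_l, "y_l_cm": self.y_l,
                           "config_id": self.config_ids})
        if self.speed is not None:
            df["speed_cm_s"] = self.speed
        if self.included is not None:
            df["included"] = self.included
        return df


@dataclass
class SpikeTrain:
    """Spike times of one cell with interpolated positions in both frames."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_l: np.ndarray
    y_l: np.ndarray
    epoch_idx: np.ndarray
    included: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.t)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_id, "t_s": self.t,
                             "x_cm": self.x, "y_cm": self.y,
                             "x_l_cm": self.x_l, "y_l_cm": self.y_l})


@dataclass
class SpikeTrains:
    """Spike trains of a recorded population, indexable by cell id."""

    trains: list[SpikeTrain] = field(default_factory=list)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __len__(self) -> int:
        return len(self.trains)

    def __getitem__(self, cell_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.cell_id == cell_id:
                return tr
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list[str]:
        return [tr.cell_id for tr in self.trains]

    def frame(self) -> pd.DataFrame:
        if not self.trains:
            return pd.DataFrame(columns=["cell_id", "t_s"])
        return pd.concat([tr.frame() for tr in self.trains], ignore_index=True)
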