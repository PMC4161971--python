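"""Session I/O, analysis configuration, and end-to-end drivers.

``run_track_a`` chains speed filtering, section grouping, dual-frame pooled
rate maps, correlation matrices, decay curves and the per-d frame tests;
``run_track_b`` runs the four-comparison protrusion battery with its
statistics.  Both are deterministic given the configuration seed.

Sessions are stored as delimited text tables (positions, spikes, schedule)
plus a YAML manifest, and reload losslessly; malformed rows are rejected
with line-numbered diagnostics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation as corr
from . import protrusion as prot
from .geometry import (
    PROTRUSION_SIDES,
    TrackModel,
    build_track_a,
    build_track_b,
    make_configuration,
    with_protrusion,
)
from .ratemaps import (
    BinGrid,
    RateMap,
    draw_shifts,
    linear_grid,
    peak_bin_xl,
    peak_rate,
    planar_grid,
    profile_grid,
    speed_filter,
)
from .session import ConfigSchedule, Epoch, SpikeTrain, SpikeTrains, Trajectory
from .simulate import (
    BehaviorParams,
    PlaceCellModel,
    constant_schedule,
    make_place_cells,
    simulate_schedule,
    simulate_spikes,
    simulate_trajectory,
)

__all__ = [
    "AnalysisConfig",
    "SessionBundle",
    "SessionFormatError",
    "ProtocolError",
    "TrackAResult",
    "TrackBResult",
    "write_session",
    "read_session",
    "simulate_session_a",
    "simulate_session_pair_b",
    "run_track_a",
    "run_track_b",
]

logger = logging.getLogger(__name__)


class SessionFormatError(ValueError):
    """A session table violates its column/ordering/referential contract."""


class ProtocolError(ValueError):
    """Sessions violate the experimental protocol (e.g. same-side pair)."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters.  Defaults are the protocol's printed values:
    3 cm bins, 3 cm/s speed floor, 12 vertical sections with N_V >= 3, and
    a 2 Hz peak-rate inclusion threshold."""

    bin_size_cm: float = 3.0
    v_min_cm_s: float = 3.0
    n_shifts: int = 25
    min_bins: int = 10
    n_sections: int = 12
    min_group_size: int = 3
    peak_threshold_hz: float = 2.0
    mask_rule: str = "either"
    direction: str | None = None     # None pools directions; "outbound"/"inbound"
    seed: int = 0


@dataclass
class SessionBundle:
    """One session: track, schedule, trajectory, spikes, and a manifest."""

    track: TrackModel
    schedule: ConfigSchedule
    trajectory: Trajectory
    spikes: SpikeTrains
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simulation drivers
# ---------------------------------------------------------------------------

def simulate_session_a(n_cells: int = 50, anchoring: str = "linear_fraction",
                       n_moves: int = 40, seed: int = 0,
                       track: TrackModel | None = None,
                       behavior: BehaviorParams | None = None,
                       sigma_cm: float = 10.0, peak_hz: float = 15.0,
                       baseline_hz: float = 0.1,
                       ) -> tuple[SessionBundle, list[PlaceCellModel]]:
    """A full synthetic Track A session under one anchoring hypothesis."""
    track = track or build_track_a()
    behavior = behavior or BehaviorParams()
    schedule = simulate_schedule(track, n_moves=n_moves, seed=seed,
                                 behavior=behavior)
    traj = simulate_trajectory(track, schedule, behavior, seed=seed)
    cells = make_place_cells(track, n_cells, anchoring, seed=seed,
                             sigma_cm=sigma_cm, peak_hz=peak_hz,
                             baseline_hz=baseline_hz)
    spikes = simulate_spikes(traj, cells, seed=seed)
    manifest = {"track": _track_dict(track), "seed": seed,
                "anchoring": anchoring, "n_moves": n_moves,
                "n_cells": n_cells}
    return SessionBundle(track, schedule, traj, spikes, manifest), cells


def simulate_session_pair_b(n_cells: int = 100,
                            anchoring: str = "linear_fraction",
                            seed: int = 0, session_s: float = 1200.0,
                            first_side: str = "segments_3_4_5",
                            track: TrackModel | None = None,
                            behavior: BehaviorParams | None = None,
                            sigma_cm: float = 10.0, peak_hz: float = 15.0,
                            baseline_hz: float = 0.1,
                            ) -> tuple[prot.ProtrusionSessionPair, list[PlaceCellModel]]:
    """Two consecutive Track B run sessions with the protrusion flipped.

    The same cell population is observed in both sessions; only the track
    pose (and therefore where each anchoring predicts firing) changes.
    """
    track = track or build_track_b()
    behavior = behavior or BehaviorParams()
    other = PROTRUSION_SIDES[1 - PROTRUSION_SIDES.index(first_side)]
    cells = make_place_cells(track, n_cells, anchoring, seed=seed,
                             sigma_cm=sigma_cm, peak_hz=peak_hz,
                             baseline_hz=baseline_hz)
    sessions = []
    for k, side in enumerate((first_side, other)):
        cfg = with_protrusion(track, side, config_id=f"run{k + 1}-{side}")
        sched = constant_schedule(track, cfg, session_s)
        traj = simulate_trajectory(track, sched, behavior, seed=seed * 4 + k)
        spk = simulate_spikes(traj, cells, seed=seed * 4 + k)
        sessions.append(prot.ProtrusionSession(cfg, traj, spk))
    return prot.ProtrusionSessionPair(track, sessions[0], sessions[1]), cells


# ---------------------------------------------------------------------------
# session files
# ---------------------------------------------------------------------------

def _track_dict(track: TrackModel) -> dict:
    return {"track_id": track.track_id,
            "segment_length_cm": track.segment_length,
            "track_width_cm": track.track_width,
            "joint_connector_cm": track.joint_connector_length}


def _track_from_dict(d: dict) -> TrackModel:
    if d["track_id"] == "A":
        return build_track_a(d["segment_length_cm"], d.get("joint_connector_cm", 0.0),
                             d["track_width_cm"])
    return build_track_b(d["segment_length_cm"], d["track_width_cm"])


def write_session(bundle: SessionBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write positions/spikes/schedule tables (TSV) plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "positions": out / "positions.tsv",
        "spikes": out / "spikes.tsv",
        "schedule": out / "schedule.tsv",
        "manifest": out / "manifest.yaml",
    }
    traj = bundle.trajectory
    pos = pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y,
                        "x_l_cm": traj.x_l, "y_l_cm": traj.y_l,
                        "config_id": traj.config_ids})
    pos.to_csv(paths["positions"], sep="\t", index=False)
    spk = bundle.spikes.frame()[["cell_id", "t_s"]]
    spk.to_csv(paths["spikes"], sep="\t", index=False)
    bundle.schedule.as_frame().to_csv(paths["schedule"], sep="\t", index=False)
    manifest = dict(bundle.manifest)
    manifest["track"] = _track_dict(bundle.track)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths


def read_session(in_dir: str | Path) -> SessionBundle:
    """Load a session written by :func:`write_session`, with validation.

    Raises :class:`SessionFormatError` naming the first offending row for
    missing columns, non-monotone times, or unknown configuration ids.
    Linear coordinates are taken from the table when present; otherwise they
    are reconstructed from the planar samples and the per-epoch pose (an
    off-midline sample very close to a fold vertex can then be assigned to
    the adjacent leg).
    """
    d = Path(in_dir)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    track = _track_from_dict(manifest["track"])

    sched_df = pd.read_csv(d / "schedule.tsv", sep="\t",
                           float_precision="round_trip")
    _require(sched_df, ["config_id", "t_start_s", "t_end_s"], "schedule.tsv")
    epochs = []
    for r, row in sched_df.iterrows():
        if track.track_id == "A":
            _require(sched_df, ["top_extent_cm", "bottom_extent_cm"], "schedule.tsv")
            cfg = make_configuration(track, row["top_extent_cm"],
                                     row["bottom_extent_cm"],
                                     config_id=str(row["config_id"]))
        else:
            _require(sched_df, ["protrusion_side"], "schedule.tsv")
            cfg = with_protrusion(track, str(row["protrusion_side"]),
                                  config_id=str(row["config_id"]))
        epochs.append(Epoch(cfg, float(row["t_start_s"]), float(row["t_end_s"]),
                            start_well=r % 2))
    schedule = ConfigSchedule(track, epochs)
    known = {e.config.config_id for e in epochs}

    pos = pd.read_csv(d / "positions.tsv", sep="\t",
                      float_precision="round_trip")
    _require(pos, ["t_s", "x_cm", "y_cm", "config_id"], "positions.tsv")
    t = pos["t_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise SessionFormatError(
            f"positions.tsv row {int(bad[0]) + 2}: time not strictly increasing")
    unknown = ~pos["config_id"].astype(str).isin(known)
    if unknown.any():
        r = int(np.nonzero(unknown.to_numpy())[0][0])
        raise SessionFormatError(
            f"positions.tsv row {r + 2}: unknown config_id "
            f"{pos['config_id'].iloc[r]!r}")
    epoch_idx = schedule.epoch_of(t)
    x = pos["x_cm"].to_numpy(float)
    y = pos["y_cm"].to_numpy(float)
    if "x_l_cm" in pos.columns and "y_l_cm" in pos.columns:
        x_l = pos["x_l_cm"].to_numpy(float)
        y_l = pos["y_l_cm"].to_numpy(float)
    else:
        x_l = np.empty_like(t)
        y_l = np.empty_like(t)
        layouts = schedule.layouts()
        for ei in range(len(epochs)):
            sl = epoch_idx == ei
            if sl.any():
                xl, yl = layouts[ei].linearize(
                    np.stack([x[sl], y[sl]], axis=1), strict=False)
                x_l[sl], y_l[sl] = xl, yl
    traj = Trajectory(track, schedule, t, x, y, x_l, y_l, epoch_idx)

    spk = pd.read_csv(d / "spikes.tsv", sep="\t",
                      float_precision="round_trip")
    _require(spk, ["cell_id", "t_s"], "spikes.tsv")
    trains = []
    for cid, g in spk.groupby("cell_id", sort=False):
        tt = np.sort(g["t_s"].to_numpy(float))
        posq = traj.interp_at(tt)
        trains.append(SpikeTrain(str(cid), tt, posq["x"], posq["y"],
                                 posq["x_l"], posq["y_l"], posq["epoch_idx"]))
    return SessionBundle(track, schedule, traj, SpikeTrains(trains), manifest)


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{name}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# batched rate-map machinery (equals compute_rate_map; shared occupancies)
# ---------------------------------------------------------------------------

def _coords(obj, frame: str):
    return (obj.x, obj.y) if frame == "planar" else (obj.x_l, obj.y_l)


def _shift_flat(grid: BinGrid, cx: np.ndarray, cy: np.ndarray,
                shifts: np.ndarray) -> np.ndarray:
    ix = np.floor((cx[None, :] - grid.x0 - shifts[:, :1]) / grid.bin_w).astype(int)
    iy = np.floor((cy[None, :] - grid.y0 - shifts[:, 1:]) / grid.bin_h).astype(int)
    if ix.size and (ix.min() < 0 or ix.max() >= grid.n_x
                    or iy.min() < 0 or iy.max() >= grid.n_y):
        raise ValueError("data fall outside the bin grid")
    return ix * grid.n_y + iy


def _group_occupancy(traj: Trajectory, grid: BinGrid, shifts: np.ndarray,
                     mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_shifts, n_bins) occupancy per shift plus the unshifted occupancy."""
    cx, cy = _coords(traj, grid.frame)
    dt = np.diff(traj.t, append=traj.t[-1] if traj.n else 0.0)
    cx, cy, w = cx[mask], cy[mask], dt[mask]
    flat = _shift_flat(grid, cx, cy, shifts)
    nb = grid.n_bins
    occ = np.stack([np.bincount(flat[s], weights=w, minlength=nb)
                    for s in range(len(shifts))])
    occ0 = np.bincount(grid.flat_indices(cx, cy), weights=w, minlength=nb)
    return occ, occ0


def _cell_map(spikes: SpikeTrain, grid: BinGrid, shifts: np.ndarray,
              occ: np.ndarray, occ0: np.ndarray,
              kmask: np.ndarray) -> RateMap:
    sx, sy = _coords(spikes, grid.frame)
    sx, sy = sx[kmask], sy[kmask]
    nshift, nb = occ.shape
    flat = _shift_flat(grid, sx, sy, shifts)
    comb = (flat + np.arange(nshift)[:, None] * nb).ravel()
    cnt = np.bincount(comb, minlength=nshift * nb).reshape(nshift, nb).astype(float)
    vis = occ > 0
    ratio = np.where(vis, cnt / np.where(vis, occ, 1.0), 0.0)
    n_vis = vis.sum(axis=0)
    rate = np.full(nb, np.nan)
    nz = n_vis > 0
    rate[nz] = ratio.sum(axis=0)[nz] / n_vis[nz]
    cnt0 = np.bincount(grid.flat_indices(sx, sy), minlength=nb).astype(float)
    shape = (grid.n_x, grid.n_y)
    return RateMap(grid, occ0.reshape(shape), cnt0.reshape(shape),
                   rate.reshape(shape), nz.reshape(shape), nshift,
                   cell_id=spikes.cell_id)


# ---------------------------------------------------------------------------
# Track A driver
# ---------------------------------------------------------------------------

@dataclass
class TrackAResult:
    """Everything the Track A analysis produces, with table exporters."""

    config: AnalysisConfig
    classification: pd.DataFrame
    matrices: dict[tuple[str, str], corr.CorrelationMatrix]
    mobile_curves: dict[str, corr.DecayCurve] | None
    static_curves: dict[str, corr.DecayCurve] | None
    welch_p: dict[int, float]
    frame_pattern: str
    counters: dict[str, int]

    def matrices_table(self) -> pd.DataFrame:
        rows = []
        for (cid, frame), m in self.matrices.items():
            ii, jj = np.nonzero(m.defined())
            for i, j in zip(ii, jj):
                if i <= j:
                    rows.append({"cell_id": cid, "frame": frame,
                                 "i": int(i + 1), "j": int(j + 1),
                                 "C_ij": float(m.C[i, j]),
                                 "n_bins": int(m.n_bins[i, j])})
        return pd.DataFrame(rows)

    def curves_table(self) -> pd.DataFrame:
        rows = []
        groups = []
        if self.mobile_curves:
            groups.append(("mobile", self.mobile_curves))
        if self.static_curves:
            groups.append(("static", self.static_curves))
        for pop, curves in groups:
            for frame, c in curves.items():
                for d in range(len(c.d)):
                    rows.append({"population": pop, "frame": frame,
                                 "d": int(c.d[d]), "r_d": float(c.r[d]),
                                 "sem": float(c.sem[d]), "n": int(c.n[d])})
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [
            "Track A dual-frame correlation analysis",
            f"  cells: {self.counters['n_cells']} "
            f"(mobile {self.counters['n_mobile']}, static {self.counters['n_static']}, "
            f"unclassified {self.counters['n_unclassified']})",
            f"  samples excluded by speed filter: {self.counters['n_speed_excluded']}",
            f"  undefined matrix entries: {self.counters['n_undefined_entries']}",
            f"  frame pattern: {self.frame_pattern}",
        ]
        if self.mobile_curves is None:
            lines.append("  mobile-field section: empty")
            return "\n".join(lines)
        lin, pla = self.mobile_curves["linear"], self.mobile_curves["planar"]
        for d in range(0, len(lin.d), 2):
            p = self.welch_p.get(d, float("nan"))
            lines.append(f"  d={d:2d}: r_1D={lin.r[d]:+.3f}  r_2D={pla.r[d]:+.3f}"
                         f"  Welch p={p:.2e}")
        return "\n".join(lines)


def run_track_a(bundle: SessionBundle,
                config: AnalysisConfig | None = None) -> TrackAResult:
    """Full Track A chain: filter, group, map, correlate, test."""
    config = config or AnalysisConfig()
    track = bundle.track
    if track.track_id != "A":
        raise ProtocolError("run_track_a needs a Track A session")
    traj, spikes = speed_filter(bundle.trajectory, bundle.spikes,
                                v_min=config.v_min_cm_s)
    n_speed_excluded = int((~traj.included).sum())

    if config.direction is not None:
        sgn = np.sign(np.gradient(traj.x_l))
        want = 1.0 if config.direction == "outbound" else -1.0
        traj.included = traj.included & (sgn == want)
        for tr in spikes:
            si = np.clip(np.searchsorted(traj.t, tr.t), 0, traj.n - 1)
            tr.included = tr.included & (sgn[si] == want)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    grids = {"linear": linear_grid(track, config.bin_size_cm),
             "planar": planar_grid(track, config.bin_size_cm)}
    shifts = {f: draw_shifts(g, config.n_shifts, rng) for f, g in grids.items()}
    prof_grid = profile_grid(track, config.bin_size_cm)
    prof_shifts = draw_shifts(prof_grid, config.n_shifts, rng)

    spans = {"top": (track.segment_span(1)[0], track.segment_span(4)[1]),
             "base": track.static_span(),
             "bottom": (track.segment_span(7)[0], track.segment_span(10)[1])}
    groups = {"top": corr.group_by_section(bundle.schedule, "top",
                                           config.min_group_size),
              "bottom": corr.group_by_section(bundle.schedule, "bottom",
                                              config.min_group_size)}
    # static (base) cells are indexed by the top arm's sections: their data do
    # not depend on either arm's pose, so the choice of indexing arm is moot
    group_arm = {"top": "top", "bottom": "bottom", "base": "top"}

    # classification from the full-session lateral-collapsed linear profile:
    # full-width x_L bins carry far more occupancy per bin than 3 x 3 cm
    # squares, so the peak-bin field-center estimate is stable
    classification = []
    category_of: dict[str, tuple[str | None, str | None]] = {}
    full_maps: dict[str, RateMap] = {}
    occ_full, occ0_full = _group_occupancy(traj, prof_grid, prof_shifts,
                                           traj.included)
    for tr in spikes:
        m = _cell_map(tr, prof_grid, prof_shifts, occ_full,
                      occ0_full, tr.included)
        full_maps[tr.cell_id] = m
        cat, arm = corr.classify_mobile_static(track, m)
        category_of[tr.cell_id] = (cat, arm)
        classification.append({
            "cell_id": tr.cell_id, "category": cat, "arm": arm,
            "peak_hz": peak_rate(m) if m.visited.any() else float("nan"),
            "peak_xl_cm": peak_bin_xl(m) if (cat is not None) else float("nan"),
        })
    classification = pd.DataFrame(classification)

    # shared occupancies per (region arm, frame, section)
    occ_cache: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
    base_mask = traj.included
    sample_masks: dict[tuple[str, int], np.ndarray] = {}
    for region, span in spans.items():
        arm = group_arm[region]
        in_span = (traj.x_l >= span[0]) & (traj.x_l < span[1])
        for g in groups[arm]:
            mask = base_mask & in_span & np.isin(traj.epoch_idx, g.epoch_ids)
            sample_masks[(region, g.section)] = mask
            for frame, grid in grids.items():
                occ_cache[(region, frame, g.section)] = _group_occupancy(
                    traj, grid, shifts[frame], mask)

    matrices: dict[tuple[str, str], corr.CorrelationMatrix] = {}
    undefined = 0
    for tr in spikes:
        cat, arm = category_of[tr.cell_id]
        if cat is None:
            continue
        region = "base" if cat == "static" else arm
        span = spans[region]
        k_span = (tr.x_l >= span[0]) & (tr.x_l < span[1]) & tr.included
        for frame, grid in grids.items():
            maps = {}
            for g in groups[group_arm[region]]:
                occ, occ0 = occ_cache[(region, frame, g.section)]
                kmask = k_span & np.isin(tr.epoch_idx, g.epoch_ids)
                maps[g.section] = _cell_map(tr, grid, shifts[frame],
                                            occ, occ0, kmask)
            m = corr.build_correlation_matrix(
                maps, frame, tr.cell_id, config.n_sections,
                min_bins=config.min_bins, rule=config.mask_rule)
            undefined += int(np.isnan(m.C).sum())
            matrices[(tr.cell_id, frame)] = m

    def curves_for(cat: str) -> dict[str, corr.DecayCurve] | None:
        out = {}
        for frame in ("linear", "planar"):
            mats = [matrices[(cid, frame)] for cid, (c, _) in category_of.items()
                    if c == cat and (cid, frame) in matrices]
            if not mats:
                return None
            out[frame] = corr.ensemble_curves(mats)
        return out

    mobile_curves = curves_for("mobile")
    static_curves = curves_for("static")

    pooled: dict[str, dict[int, list[np.ndarray]]] = {
        "linear": {}, "planar": {}}
    for (cid, frame), m in matrices.items():
        if category_of[cid][0] != "mobile":
            continue
        for d, vals in corr.subdiagonal_entries(m).items():
            pooled[frame].setdefault(d, []).append(vals)
    entries = {frame: {d: (np.concatenate(v) if v else np.array([]))
                       for d, v in pooled[frame].items()}
               for frame in pooled}
    welch_p = corr.frame_comparison_test(entries["linear"], entries["planar"])

    if mobile_curves is None:
        pattern = "indeterminate (no mobile-field cells)"
    else:
        diff = mobile_curves["linear"].r - mobile_curves["planar"].r
        tail = diff[2:][~np.isnan(diff[2:])]
        mean_gap = tail.mean() if len(tail) else float("nan")
        if np.isnan(mean_gap):
            pattern = "indeterminate"
        elif mean_gap > 0.1:
            pattern = "linear-stable"
        elif mean_gap < -0.1:
            pattern = "planar-stable"
        else:
            pattern = "indeterminate"

    cats = [category_of[c][0] for c in category_of]
    counters = {
        "n_cells": len(cats),
        "n_mobile": sum(c == "mobile" for c in cats),
        "n_static": sum(c == "static" for c in cats),
        "n_unclassified": sum(c is None for c in cats),
        "n_speed_excluded": n_speed_excluded,
        "n_undefined_entries": undefined,
    }
    logger.info("track A analysis: %s", counters)
    return TrackAResult(config, classification, matrices, mobile_curves,
                        static_curves, welch_p, pattern, counters)


# ---------------------------------------------------------------------------
# Track B driver
# ---------------------------------------------------------------------------

@dataclass
class TrackBResult:
    """Four-comparison battery for one protrusion-flip session pair."""

    config: AnalysisConfig
    included_cells: list[str]
    comparison: prot.ComparisonResult
    counters: dict[str, int]

    def report(self) -> str:
        c = self.comparison
        lines = ["Track B protrusion-flip comparison battery",
                 f"  included cells (peak >= {self.config.peak_threshold_hz} Hz): "
                 f"{len(self.included_cells)}"]
        for k in prot.COMPARISONS:
            lines.append(f"  {k:9s} r = {c.means[k]:+.3f} +/- {c.sems[k]:.3f} "
                         f"(n={c.n[k]})")
        lines.append(f"  argmax comparison: {c.argmax}")
        lines.append(f"  one-way ANOVA p = {c.anova_p:.3e}")
        for (a, b), p in c.u_pvalues.items():
            lines.append(f"  u-test {a} vs {b}: p = {p:.3e}")
        return "\n".join(lines)


def run_track_b(pair: prot.ProtrusionSessionPair,
                config: AnalysisConfig | None = None) -> TrackBResult:
    """Four linearized cross-session correlations with their statistics."""
    config = config or AnalysisConfig()
    if pair.session1.side == pair.session2.side:
        raise ProtocolError("the two sessions have the same protrusion side; "
                            "the protocol flips it between runs")
    track = pair.track
    grid = profile_grid(track, config.bin_size_cm)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    shifts = draw_shifts(grid, config.n_shifts, rng)

    maps: list[dict[str, RateMap]] = []
    filtered: list[tuple] = []
    for sess in (pair.session1, pair.session2):
        traj, spikes = speed_filter(sess.trajectory, sess.spikes,
                                    v_min=config.v_min_cm_s)
        filtered.append((traj, spikes))
        occ, occ0 = _group_occupancy(traj, grid, shifts, traj.included)
        maps.append({tr.cell_id: _cell_map(tr, grid, shifts, occ, occ0,
                                           tr.included)
                     for tr in spikes})

    active = prot.include_active_cells(maps[0], maps[1],
                                       threshold=config.peak_threshold_hz)
    # All four correlations compare the firing *over the protrusion* of the
    # first configuration against candidate regions of the second; cells that
    # never clear the rate threshold on that span contribute only sampling
    # noise to every comparison, so the battery runs over the protrusion's
    # own cells (the same 2 Hz floor, applied to the protrusion span).
    w1_incl = prot.protrusion_span(track, pair.session1.side)
    included = [cid for cid in active
                if prot.window_peak(maps[0][cid], [w1_incl])
                >= config.peak_threshold_hz]

    # rescaled maps: the coordinate transform is cell-independent, so the
    # transformed occupancy is shared and only counts differ per cell
    w1 = prot.protrusion_span(track, pair.session1.side)
    tgt = prot.projected_straight_span(track, pair.session1.side)
    scale = (tgt[1] - tgt[0]) / (w1[1] - w1[0])
    traj1, spikes1 = filtered[0]
    in_w = ((traj1.x_l >= w1[0]) & (traj1.x_l < w1[1]) & traj1.included)
    traj_t = dataclasses.replace(
        traj1, x_l=np.where(in_w, tgt[0] + (traj1.x_l - w1[0]) * scale,
                            traj1.x_l))
    occ_r, occ0_r = _group_occupancy(traj_t, grid, shifts, in_w)

    values = {k: [] for k in prot.COMPARISONS}
    rows = []
    for cid in included:
        m1, m2 = maps[0][cid], maps[1][cid]
        v = {
            "flip": prot.flip_correlation(m1, m2, pair, config.min_bins,
                                          config.mask_rule),
            "distance": prot.distance_correlation(m1, m2, pair, config.min_bins,
                                                  config.mask_rule),
            "segment": prot.segment_correlation(m1, m2, pair, config.min_bins,
                                                config.mask_rule),
        }
        tr1 = spikes1[cid]
        k_in = (tr1.x_l >= w1[0]) & (tr1.x_l < w1[1]) & tr1.included
        spk_t = dataclasses.replace(
            tr1, x_l=np.where(k_in, tgt[0] + (tr1.x_l - w1[0]) * scale, tr1.x_l))
        m1r = _cell_map(spk_t, grid, shifts, occ_r, occ0_r, k_in)
        v["rescaled"] = prot._window_correlation(
            m1r, m2, tgt, shift_to=None, min_bins=config.min_bins,
            rule=config.mask_rule)
        for k, val in v.items():
            values[k].append(val)
        rows.append({"cell_id": cid, **v})
    per_cell = pd.DataFrame(rows)
    result = prot.comparison_stats({k: np.array(v) for k, v in values.items()},
                                   per_cell=per_cell)
    counters = {"n_cells": len(maps[0]), "n_active": len(active),
                "n_included": len(included)}
    logger.info("track B analysis: %s", counters)
    return TrackBResult(config, included, result, counters)
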