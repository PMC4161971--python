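"""Track B analysis: the four linearized cross-session comparisons.

Between the two run sessions the three-segment detour flips from one side of
the U to the other; four competing accounts of what place fields should do
are each turned into a correlation between linearized rate profiles:

``flip``
    rates on the physical protrusion segments in session 1 against the same
    physical segments (now on the other side) in session 2 — high if fields
    are bound to local segment features.
``distance``
    rates on session 1's protrusion span against session 2's bins at the
    same arc distance from the food well on that arm — high if fields sit at
    a fixed travel distance.
``segment``
    rates on the protrusion's central segment against the in-line section it
    projects onto after the flip — partial credit for fields that stay put
    in the room-like frame of the track skeleton.
``rescaled``
    rates on the protrusion span after linearly compressing it (spikes and
    occupancy) onto the single straight section that replaces it — high if
    fields simply stretch and shrink with the local deformation.

All four are computed on the linearized data so the comparisons are fair,
over cells whose peak occupancy-normalized rate clears 2 Hz in at least one
session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    TrackConfiguration,
    TrackModel,
    center_segment_span,
    projected_straight_span,
    protrusion_span,
)
from .correlation import MIN_BINS, masked_pearson
from .ratemaps import BinGrid, RateMap, compute_rate_map, peak_rate
from .session import SpikeTrain, SpikeTrains, Trajectory

__all__ = [
    "ProtrusionSession",
    "ProtrusionSessionPair",
    "ComparisonResult",
    "COMPARISONS",
    "include_active_cells",
    "window_peak",
    "flip_correlation",
    "distance_correlation",
    "segment_correlation",
    "rescaled_correlation",
    "comparison_stats",
]

COMPARISONS = ("flip", "distance", "segment", "rescaled")
PEAK_THRESHOLD_HZ = 2.0


@dataclass
class ProtrusionSession:
    """One Track B run session: pose, trajectory and population spikes."""

    cfg: TrackConfiguration
    trajectory: Trajectory
    spikes: SpikeTrains

    @property
    def side(self) -> str:
        return self.cfg.protrusion_side


@dataclass
class ProtrusionSessionPair:
    """Two successive run sessions; by protocol the sides are opposite.

    Same-side pairs are accepted here (they serve as degenerate controls in
    which every comparison reduces to a self-correlation); the end-to-end
    driver enforces the opposite-side protocol.
    """

    track: TrackModel
    session1: ProtrusionSession
    session2: ProtrusionSession

    @property
    def sides(self) -> tuple[str, str]:
        return (self.session1.side, self.session2.side)


def window_peak(rate_map: RateMap, spans) -> float:
    """Peak rate over the bins whose centers fall in any of the x_L spans."""
    xc = rate_map.grid.x_centers()
    sel = np.zeros(rate_map.grid.n_x, dtype=bool)
    for a, b in np.atleast_2d(np.asarray(spans, dtype=float)):
        sel |= (xc >= a) & (xc < b)
    vals = rate_map.rate[sel, :]
    vals = vals[rate_map.visited[sel, :]]
    return float(np.nanmax(vals)) if vals.size else float("-inf")


def include_active_cells(maps1: dict[str, RateMap], maps2: dict[str, RateMap],
                         threshold: float = PEAK_THRESHOLD_HZ) -> list[str]:
    """Cells whose peak occupancy-normalized rate clears ``threshold`` (Hz)
    in at least one of the two sessions."""
    kept = []
    for cid in maps1:
        peaks = []
        for maps in (maps1, maps2):
            m = maps.get(cid)
            if m is not None and m.visited.any():
                peaks.append(peak_rate(m))
        if peaks and max(peaks) >= threshold:
            kept.append(cid)
    return kept


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------

def _window_correlation(m1: RateMap, m2: RateMap, w1: tuple[float, float],
                        shift_to: float | None = None,
                        min_bins: int = MIN_BINS, rule: str = "either"
                        ) -> float:
    """Correlate two 1D profiles over a window, bin k of session 1 against
    the session-2 bin at the mapped coordinate (nearest-bin resampling).

    Only bins lying entirely inside the window are used; a bin straddling the
    window edge mixes in-window and out-of-window data.
    """
    g = m1.grid
    xc = g.x_centers()
    h = g.bin_w / 2
    sel1 = np.nonzero((xc - h >= w1[0] - 1e-9) & (xc + h <= w1[1] + 1e-9))[0]
    x2 = xc[sel1] if shift_to is None else xc[sel1] + (shift_to - w1[0])
    sel2 = np.clip(np.floor((x2 - g.x0) / g.bin_w).astype(int), 0, g.n_x - 1)
    r1 = m1.rate[sel1, 0]
    r2 = m2.rate[sel2, 0]
    vis = m1.visited[sel1, 0] & m2.visited[sel2, 0]
    occ = (m1.occupancy[sel1, 0] > 0) & (m2.occupancy[sel2, 0] > 0)
    if rule == "either":
        spk = (m1.counts[sel1, 0] + m2.counts[sel2, 0]) > 0
    else:
        spk = (m1.counts[sel1, 0] > 0) & (m2.counts[sel2, 0] > 0)
    mask = vis & occ & spk
    if mask.sum() < min_bins:
        return float("nan")
    return masked_pearson(r1[mask], r2[mask])


def flip_correlation(m1: RateMap, m2: RateMap, pair: ProtrusionSessionPair,
                     min_bins: int = MIN_BINS, rule: str = "either") -> float:
    """Rates over the physical protrusion segments across the flip, bins
    aligned by material position along those segments."""
    s1, s2 = pair.sides
    w1 = protrusion_span(pair.track, s1)
    w2 = protrusion_span(pair.track, s2)
    return _window_correlation(m1, m2, w1, shift_to=w2[0],
                               min_bins=min_bins, rule=rule)


def distance_correlation(m1: RateMap, m2: RateMap, pair: ProtrusionSessionPair,
                         min_bins: int = MIN_BINS, rule: str = "either") -> float:
    """Rates over session 1's protrusion span against session 2's bins at
    identical arc distance from the food well on the protrusion's arm.

    Both poses have the same total path length, so equal distance from the
    relevant well means equal x_L regardless of which arm protrudes.
    """
    w1 = protrusion_span(pair.track, pair.sides[0])
    return _window_correlation(m1, m2, w1, shift_to=None,
                               min_bins=min_bins, rule=rule)


def segment_correlation(m1: RateMap, m2: RateMap, pair: ProtrusionSessionPair,
                        min_bins: int = MIN_BINS, rule: str = "either") -> float:
    """Rates over the protrusion's central segment against the in-line
    section onto which it projects directly after the flip, bins aligned
    proportionally along each 40-cm span."""
    s1, s2 = pair.sides
    w1 = center_segment_span(pair.track, s1)
    if s1 == s2:                       # degenerate same-side control
        target = w1[0]
    else:
        target = projected_straight_span(pair.track, s1)[0]
    return _window_correlation(m1, m2, w1, shift_to=target,
                               min_bins=min_bins, rule=rule)


def rescaled_correlation(session1: ProtrusionSession, spikes1: SpikeTrain,
                         m2: RateMap, pair: ProtrusionSessionPair,
                         grid: BinGrid, shifts: np.ndarray,
                         min_bins: int = MIN_BINS, rule: str = "either") -> float:
    """Rates after rescaling the protrusion span onto its replacing section.

    Session 1's linear coordinates (occupancy samples and spikes) on the
    protrusion span are compressed affinely onto the single straight section
    that replaces the protrusion in session 2; rates are re-binned on the
    common grid and correlated with session 2's rates there.  The affine map
    moves coordinates only, so total spike count and occupancy on the span
    are conserved exactly.
    """
    s1, s2 = pair.sides
    w1 = protrusion_span(pair.track, s1)
    if s1 == s2:                       # identity rescale for the control
        tgt = w1
    else:
        tgt = projected_straight_span(pair.track, s1)
    scale = (tgt[1] - tgt[0]) / (w1[1] - w1[0])
    traj = session1.trajectory
    in_w = (traj.x_l >= w1[0]) & (traj.x_l < w1[1])
    k_in = (spikes1.x_l >= w1[0]) & (spikes1.x_l < w1[1])
    traj_t = dataclasses.replace(
        traj, x_l=np.where(in_w, tgt[0] + (traj.x_l - w1[0]) * scale, traj.x_l))
    spk_t = dataclasses.replace(
        spikes1, x_l=np.where(k_in, tgt[0] + (spikes1.x_l - w1[0]) * scale,
                              spikes1.x_l))
    m1r = compute_rate_map(traj_t, spk_t, grid, shifts=shifts,
                           sample_mask=in_w, spike_mask=k_in)
    return _window_correlation(m1r, m2, tgt, shift_to=None,
                               min_bins=min_bins, rule=rule)


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Per-cell values and population statistics of the four comparisons."""

    per_cell: pd.DataFrame               # columns: cell_id + the four comparisons
    means: dict[str, float]
    sems: dict[str, float]
    n: dict[str, int]
    u_pvalues: dict[tuple[str, str], float]
    anova_p: float
    tukey: pd.DataFrame | None

    @property
    def argmax(self) -> str:
        return max(self.means, key=lambda k: (self.means[k]
                                              if np.isfinite(self.means[k])
                                              else -np.inf))


def comparison_stats(values: dict[str, np.ndarray],
                     per_cell: pd.DataFrame | None = None) -> ComparisonResult:
    """Means, SEMs, pairwise Mann-Whitney u-tests, and one-way ANOVA with a
    Tukey-Kramer post-hoc over the four comparison value sets.

    Undefined per-cell correlations (NaN) are excluded, not imputed.
    """
    clean = {k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
             for k, v in values.items()}
    means = {k: (float(v.mean()) if len(v) else float("nan"))
             for k, v in clean.items()}
    sems = {k: (float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1
                else float("nan")) for k, v in clean.items()}
    n = {k: int(len(v)) for k, v in clean.items()}

    u_p: dict[tuple[str, str], float] = {}
    keys = list(clean)
    for a_i, a in enumerate(keys):
        for b in keys[a_i + 1:]:
            va, vb = clean[a], clean[b]
            if len(va) < 2 or len(vb) < 2 or (np.ptp(np.concatenate([va, vb])) == 0):
                u_p[(a, b)] = float("nan")
                continue
            u_p[(a, b)] = float(stats.mannwhitneyu(va, vb,
                                                   alternative="two-sided").pvalue)

    groups = [clean[k] for k in keys if len(clean[k]) >= 2]
    if len(groups) == len(keys) and all(len(g) >= 2 for g in groups):
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            anova_p = 1.0
            tukey = None
        else:
            anova_p = float(stats.f_oneway(*groups).pvalue)
            if not np.isfinite(anova_p):
                gm = [g.mean() for g in groups]
                if max(gm) - min(gm) < 1e-12:   # F underflowed at 0
                    anova_p = 1.0
            hsd = stats.tukey_hsd(*groups)
            rows = []
            for i, a in enumerate(keys):
                for j, b in enumerate(keys):
                    if i < j:
                        rows.append({"group_a": a, "group_b": b,
                                     "p": float(hsd.pvalue[i, j]),
                                     "diff": means[a] - means[b]})
            tukey = pd.DataFrame(rows)
    else:
        anova_p = float("nan")
        tukey = None
    return ComparisonResult(per_cell if per_cell is not None else pd.DataFrame(),
                            means, sems, n, u_p, anova_p, tukey)
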