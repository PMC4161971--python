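"""Correlation of place-cell activity across track configurations (Track A).

Configurations are pooled by the vertical section holding each arm's food
well; for every cell and every pair of section groups (i, j) the Pearson
correlation C_ij between the two pooled activity vectors is computed in both
reference frames, using only bins visited in both groups that carry at least
one spike.  The subdiagonal averages r_d = <C_i,i+d> trace how quickly the
spatial firing pattern decorrelates as the compared geometries become more
dissimilar; a frame in which fields are stable keeps r_d flat, a frame in
which they move shows r_d decaying with d.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import N_SECTIONS, TrackModel, vertical_section_of
from .ratemaps import BinGrid, RateMap, compute_rate_map, peak_bin_xl
from .session import ConfigSchedule, SpikeTrain, Trajectory

__all__ = [
    "SectionGroup",
    "CorrelationMatrix",
    "DecayCurve",
    "group_by_section",
    "pooled_rate_map",
    "valid_bin_mask",
    "masked_pearson",
    "pair_correlation",
    "build_correlation_matrix",
    "decay_curve",
    "subdiagonal_entries",
    "classify_mobile_static",
    "frame_comparison_test",
    "ensemble_matrix",
    "ensemble_curves",
]

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 3
MIN_BINS = 10


@dataclass(frozen=True)
class SectionGroup:
    """Configurations whose ``arm`` food well fell in vertical section V."""

    arm: str
    section: int
    epoch_ids: tuple[int, ...]
    config_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.epoch_ids)


def group_by_section(schedule: ConfigSchedule, arm: str,
                     min_count: int = MIN_GROUP_SIZE) -> list[SectionGroup]:
    """Pool a Track A schedule's epochs by the arm's vertical section.

    Sections entered by fewer than ``min_count`` configurations are dropped
    (with a logged notice), mirroring the N_V >= 3 inclusion rule.
    """
    track = schedule.track
    by_section: dict[int, list[int]] = {}
    for ei, ep in enumerate(schedule.epochs):
        v = vertical_section_of(track, ep.config, arm)
        by_section.setdefault(v, []).append(ei)
    groups = []
    for v in sorted(by_section):
        eids = by_section[v]
        if len(eids) < min_count:
            logger.info("dropping %s-arm section %d: only %d configuration(s)",
                        arm, v, len(eids))
            continue
        groups.append(SectionGroup(arm, v, tuple(eids),
                                   tuple(schedule.epochs[e].config.config_id
                                         for e in eids)))
    if not groups:
        raise ValueError(f"no {arm}-arm section reaches N_V >= {min_count}")
    return groups


def pooled_rate_map(traj: Trajectory, spikes: SpikeTrain, group: SectionGroup,
                    grid: BinGrid, span: tuple[float, float] | None = None,
                    shifts: np.ndarray | None = None, n_shifts: int = 25,
                    seed: int = 0) -> RateMap:
    """Rate map pooled over all of a section group's epochs.

    Occupancy and spike counts are pooled across the member epochs *before*
    normalization (not an average of per-epoch maps).  ``span`` optionally
    restricts the data to an arc-length interval (e.g. the mobile stretch of
    one arm).
    """
    in_group = np.isin(traj.epoch_idx, group.epoch_ids)
    k_group = np.isin(spikes.epoch_idx, group.epoch_ids)
    if span is not None:
        a, b = span
        in_group &= (traj.x_l >= a) & (traj.x_l < b)
        k_group &= (spikes.x_l >= a) & (spikes.x_l < b)
    rm = compute_rate_map(traj, spikes, grid, n_shifts=n_shifts, seed=seed,
                          shifts=shifts, sample_mask=in_group,
                          spike_mask=k_group)
    rm.group = f"{group.arm}-V{group.section}"
    return rm


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------

def valid_bin_mask(map_i: RateMap, map_j: RateMap,
                   rule: str = "either") -> np.ndarray:
    """Bins entering the correlation of two maps on a shared grid.

    A bin qualifies if it was visited in both maps and carries at least one
    spike in at least one of them (``rule="either"``, the default reading of
    the inclusion criterion) or in both (``rule="both"``, the stricter
    variant).
    """
    if map_i.grid != map_j.grid:
        raise ValueError("maps must share one bin grid")
    visited = (map_i.occupancy > 0) & (map_j.occupancy > 0)
    if rule == "either":
        spiking = (map_i.counts + map_j.counts) > 0
    elif rule == "both":
        spiking = (map_i.counts > 0) & (map_j.counts > 0)
    else:
        raise ValueError(f"unknown mask rule {rule!r}")
    return visited & spiking


def masked_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either side has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2:
        return float("nan")
    da, db = a - a.mean(), b - b.mean()
    ssa, ssb = (da * da).sum(), (db * db).sum()
    if ssa <= 0 or ssb <= 0:
        return float("nan")
    return float(np.clip((da * db).sum() / np.sqrt(ssa * ssb), -1.0, 1.0))


def pair_correlation(map_i: RateMap, map_j: RateMap,
                     min_bins: int = MIN_BINS, rule: str = "either"
                     ) -> tuple[float, int]:
    """C_ij: Pearson correlation of two masked activity vectors.

    Returns ``(value, n_bins)``; the value is NaN when the mask holds fewer
    than ``min_bins`` bins or either masked vector has zero variance.
    """
    mask = valid_bin_mask(map_i, map_j, rule)
    n = int(mask.sum())
    if n < min_bins:
        return float("nan"), n
    return masked_pearson(map_i.rate[mask], map_j.rate[mask]), n


@dataclass
class CorrelationMatrix:
    """C_ij over section indices for one cell (or an ensemble) in one frame."""

    frame: str
    cell_id: str
    n_sections: int
    C: np.ndarray                    # (n, n), NaN where undefined
    n_bins: np.ndarray               # (n, n) ints, valid bins per entry

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.C)


def build_correlation_matrix(maps: dict[int, RateMap], frame: str,
                             cell_id: str, n_sections: int = N_SECTIONS,
                             min_bins: int = MIN_BINS,
                             rule: str = "either") -> CorrelationMatrix:
    """All-pairs section correlation matrix from per-section pooled maps."""
    C = np.full((n_sections, n_sections), np.nan)
    nb = np.zeros((n_sections, n_sections), dtype=int)
    secs = sorted(maps)
    for a_idx, i in enumerate(secs):
        for j in secs[a_idx:]:
            r, n = pair_correlation(maps[i], maps[j], min_bins=min_bins, rule=rule)
            C[i - 1, j - 1] = C[j - 1, i - 1] = r
            nb[i - 1, j - 1] = nb[j - 1, i - 1] = n
    return CorrelationMatrix(frame, cell_id, n_sections, C, nb)


# ---------------------------------------------------------------------------
# decay curves
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """Subdiagonal averages r_d with dispersion, d = 0 .. N_tot - 1."""

    frame: str
    d: np.ndarray
    r: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def gap_to(self, other: "DecayCurve") -> np.ndarray:
        return self.r - other.r


def subdiagonal_entries(matrix: CorrelationMatrix) -> dict[int, np.ndarray]:
    """Defined entries C_{i,i+d} per dissimilarity d (each pair once)."""
    out = {}
    n = matrix.n_sections
    for d in range(n):
        vals = np.array([matrix.C[i, i + d] for i in range(n - d)])
        out[d] = vals[~np.isnan(vals)]
    return out


def decay_curve(matrix: CorrelationMatrix) -> DecayCurve:
    """r_d and its SEM over the defined entries of each subdiagonal."""
    n = matrix.n_sections
    r = np.full(n, np.nan)
    sem = np.full(n, np.nan)
    cnt = np.zeros(n, dtype=int)
    for d, vals in subdiagonal_entries(matrix).items():
        cnt[d] = len(vals)
        if len(vals):
            r[d] = vals.mean()
            sem[d] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return DecayCurve(matrix.frame, np.arange(n), r, sem, cnt)


def ensemble_matrix(matrices: list[CorrelationMatrix],
                    cell_id: str = "ensemble") -> CorrelationMatrix:
    """Element-wise average of per-cell matrices (undefined entries skipped)."""
    if not matrices:
        raise ValueError("no matrices to combine")
    stack = np.stack([m.C for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries stay NaN
        C = np.nanmean(stack, axis=0)
    nb = np.sum(np.stack([m.n_bins for m in matrices]), axis=0)
    return CorrelationMatrix(matrices[0].frame, cell_id,
                             matrices[0].n_sections, C, nb)


def ensemble_curves(matrices: list[CorrelationMatrix]) -> DecayCurve:
    """Ensemble decay curve: subdiagonal means of the cell-averaged matrix,
    with SEM across the contributing cells' own r_d values."""
    ens = ensemble_matrix(matrices)
    curve = decay_curve(ens)
    per_cell = np.stack([decay_curve(m).r for m in matrices])  # (cells, d)
    n_cells = np.sum(~np.isnan(per_cell), axis=0)
    sem = np.full(curve.r.shape, np.nan)
    for d in range(len(sem)):
        vals = per_cell[:, d]
        vals = vals[~np.isnan(vals)]
        if len(vals) > 1:
            sem[d] = vals.std(ddof=1) / np.sqrt(len(vals))
        elif len(vals) == 1:
            sem[d] = 0.0
    return DecayCurve(curve.frame, curve.d, curve.r, sem, n_cells)


# ---------------------------------------------------------------------------
# cell classification and frame tests
# ---------------------------------------------------------------------------

def classify_mobile_static(track: TrackModel, linear_map: RateMap
                           ) -> tuple[str | None, str | None]:
    """(category, arm) of a cell from its linear-frame peak bin.

    ``static`` if the peak falls in the arc-length span of the fixed base
    segments (half-open interval), else ``mobile`` on the top or bottom arm.
    Cells with no spikes are unclassified (``(None, None)``).
    """
    if linear_map.n_spikes == 0 or not linear_map.visited.any():
        return None, None
    xl = peak_bin_xl(linear_map)
    lo, hi = track.static_span()
    if lo <= xl < hi:
        return "static", "base"
    return ("mobile", "top") if xl < lo else ("mobile", "bottom")


def frame_comparison_test(entries_1d: dict[int, np.ndarray],
                          entries_2d: dict[int, np.ndarray]) -> dict[int, float]:
    """Welch two-sample t-test of 1D vs 2D subdiagonal entries at each d."""
    out = {}
    for d in sorted(set(entries_1d) | set(entries_2d)):
        a = entries_1d.get(d, np.array([]))
        b = entries_2d.get(d, np.array([]))
        if len(a) < 2 or len(b) < 2:
            out[d] = float("nan")
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            out[d] = 1.0
            continue
        out[d] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return out
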