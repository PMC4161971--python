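"""Parametric geometry of the two morphing U-tracks.

Track A is an accordion U-track: ten rigid 35--40 cm segments joined in a U,
whose two arms (segments 1--4 and 7--10) fold concertina-style while the base
(segments 5 and 6) stays fixed.  A configuration is one frozen pose of the
track, described by the horizontal reach ("extent") of each arm's food well,
or equivalently by the fold angles alpha (top arm) and beta (bottom arm);
the equal-angle constraint ang(1,2) = ang(3,4) = alpha (and ang(7,8) =
ang(9,10) = beta) holds in every pose.

Track B is a protrusion-flip U-track: eleven segments of which three form a
rectangular detour (out, across, back) on one side of the U; between sessions
the detour flips to the other side and a single straight segment replaces it.

Two coordinate systems are maintained throughout:

* the planar (room, 2D) frame: Cartesian cm, origin at the outer corner of
  the base arm, y increasing toward the top arm;
* the linear (track, 1D) frame: x_L = arc length along the track midline from
  food well F1, y_L = signed lateral offset from the midline (positive to the
  left of the direction of increasing x_L).

Because the segments are rigid, the arc-length coordinate of a material point
on Track A is the same in every configuration; only its room position changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidParameterError",
    "OffTrackError",
    "UnsupportedTrackError",
    "Segment",
    "TrackModel",
    "TrackConfiguration",
    "PlanarLayout",
    "build_track_a",
    "build_track_b",
    "make_configuration",
    "with_protrusion",
    "layout_planar",
    "linearize_point",
    "vertical_section_of",
    "section_of_extent",
    "N_SECTIONS",
    "SECTION_WIDTH_CM",
    "PROTRUSION_SIDES",
]

N_SECTIONS = 12          # vertical sections per arm (Track A)
SECTION_WIDTH_CM = 9.0   # width of one vertical section
TRAVEL_SPAN_CM = 140.0   # physical travel span of the arm endpoints
DEFAULT_TRACK_WIDTH = 8.0

PROTRUSION_SIDES = ("segments_3_4_5", "segments_7_8_9")

# Traversal order of Track B's eleven material segments in each configuration.
# Materials are named by their traversal position when the protrusion sits at
# 3-4-5; when it flips, the detour materials (3, 4, 5) occupy traversal
# positions 7, 8, 9 and the in-line materials close ranks.
_TRACK_B_TRAVERSAL = {
    "segments_3_4_5": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11),
    "segments_7_8_9": (1, 2, 6, 7, 8, 9, 3, 4, 5, 10, 11),
}


class GeometryError(ValueError):
    """A requested pose is outside the track's physical range."""


class InvalidParameterError(ValueError):
    """A track/configuration parameter is out of its allowed range."""


class OffTrackError(ValueError):
    """A planar point is farther from the midline than the tolerance."""


class UnsupportedTrackError(TypeError):
    """Operation is defined only for the other track."""


@dataclass(frozen=True)
class Segment:
    index: int                       # 1-based traversal index from F1
    length: float                    # cm
    arm: Literal["top", "base", "bottom"]
    mobility: Literal["mobile", "static"]


@dataclass(frozen=True)
class TrackModel:
    """A morphing track: ordered rigid segments plus fixed width and wells."""

    track_id: Literal["A", "B"]
    segments: tuple[Segment, ...]
    joint_connector_length: float = 0.0
    track_width: float = DEFAULT_TRACK_WIDTH
    well_ids: tuple[str, str] = ("F1", "F2")

    def __post_init__(self) -> None:
        if any(s.length <= 0 for s in self.segments):
            raise InvalidParameterError("segment lengths must be positive")
        if self.track_width <= 0:
            raise InvalidParameterError("track width must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_length(self) -> float:
        return self.segments[0].length

    @property
    def total_length(self) -> float:
        """Total linearized length: segments plus inter-segment connectors."""
        return (sum(s.length for s in self.segments)
                + (self.n_segments - 1) * self.joint_connector_length)

    @property
    def arm_length(self) -> float:
        """Fully extended reach of one mobile arm (Track A) / arm axis (B)."""
        return 4 * self.segment_length

    # ---- Track A extent range ----------------------------------------
    @property
    def extent_max(self) -> float:
        return self.arm_length

    @property
    def extent_min_physical(self) -> float:
        return self.arm_length - TRAVEL_SPAN_CM

    @property
    def section_grid_origin(self) -> float:
        """Base of the operational sweep covered by the 12 x 9 cm sections."""
        return self.extent_max - N_SECTIONS * SECTION_WIDTH_CM

    def segment_span(self, index: int) -> tuple[float, float]:
        """Arc-length interval [x0, x1) of traversal segment ``index``."""
        lengths = [s.length for s in self.segments]
        x0 = sum(lengths[: index - 1])
        return (x0, x0 + lengths[index - 1])

    def static_span(self) -> tuple[float, float]:
        """Arc-length interval covered by the static (base) segments."""
        idx = [s.index for s in self.segments if s.mobility == "static"]
        return (self.segment_span(min(idx))[0], self.segment_span(max(idx))[1])


@dataclass(frozen=True)
class TrackConfiguration:
    """One frozen pose of a track.

    Track A poses carry the two arm extents (well reach, cm) and derived fold
    angles; Track B poses carry the protrusion side.
    """

    config_id: str
    top_extent: float | None = None
    bottom_extent: float | None = None
    protrusion_side: str | None = None

    def angle_deg(self, track: TrackModel, arm: str) -> float:
        """Fold angle alpha (top) or beta (bottom) of a Track A pose."""
        extent = self.top_extent if arm == "top" else self.bottom_extent
        theta = math.acos(min(1.0, extent / track.arm_length))
        return 180.0 - 2 * math.degrees(theta)

    def well_positions(self, track: TrackModel) -> dict[str, tuple[float, float]]:
        layout = layout_planar(track, self)
        return {
            track.well_ids[0]: tuple(layout.starts[0]),
            track.well_ids[1]: tuple(layout.ends[-1]),
        }


def build_track_a(segment_length_cm: float = 40.0,
                  joint_connector_cm: float = 0.0,
                  track_width_cm: float = DEFAULT_TRACK_WIDTH) -> TrackModel:
    """Build the ten-segment accordion U-track.

    Defaults give a 4 m track (10 x 40 cm segments, zero-length joint
    connectors).  Segments 1--4 form the mobile top arm, 5--6 the static
    base, 7--10 the mobile bottom arm.
    """
    if not (segment_length_cm > 0):
        raise InvalidParameterError("segment length must be positive")
    if not (35.0 <= segment_length_cm <= 40.0):
        raise InvalidParameterError(
            "Track A segments are 35-40 cm long; got %r" % (segment_length_cm,))
    if joint_connector_cm < 0:
        raise InvalidParameterError("joint connector length cannot be negative")
    segs = []
    for i in range(1, 11):
        arm = "top" if i <= 4 else ("base" if i <= 6 else "bottom")
        mobility = "static" if i in (5, 6) else "mobile"
        segs.append(Segment(i, segment_length_cm, arm, mobility))
    return TrackModel("A", tuple(segs), joint_connector_cm, track_width_cm)


def build_track_b(segment_length_cm: float = 40.0,
                  track_width_cm: float = DEFAULT_TRACK_WIDTH) -> TrackModel:
    """Build the eleven-segment protrusion-flip U-track.

    Materials are named by their traversal position in the 3-4-5 pose;
    the three detour materials (3, 4, 5) are the mobile ones.
    """
    if not (segment_length_cm > 0):
        raise InvalidParameterError("segment length must be positive")
    segs = []
    for i in range(1, 12):
        arm = "top" if i <= 6 else ("base" if i == 7 else "bottom")
        mobility = "mobile" if i in (3, 4, 5) else "static"
        segs.append(Segment(i, segment_length_cm, arm, mobility))
    return TrackModel("B", tuple(segs), 0.0, track_width_cm)


def make_configuration(track: TrackModel, top_extent: float,
                       bottom_extent: float, config_id: str = "cfg") -> TrackConfiguration:
    """A Track A pose from the two arm extents (well reach, cm)."""
    if track.track_id != "A":
        raise UnsupportedTrackError("extent-based configurations are Track A only")
    for e in (top_extent, bottom_extent):
        if not (track.extent_min_physical - 1e-9 <= e <= track.extent_max + 1e-9):
            raise GeometryError(
                f"extent {e:.1f} cm outside reachable range "
                f"[{track.extent_min_physical:.1f}, {track.extent_max:.1f}]")
    return TrackConfiguration(config_id, float(top_extent), float(bottom_extent))


def with_protrusion(track: TrackModel, side: str,
                    config_id: str | None = None) -> TrackConfiguration:
    """A Track B pose with the detour on the given side."""
    if track.track_id != "B":
        raise UnsupportedTrackError("protrusion poses are Track B only")
    if side not in PROTRUSION_SIDES:
        raise InvalidParameterError(f"unknown protrusion side {side!r}")
    return TrackConfiguration(config_id or side, protrusion_side=side)


# ---------------------------------------------------------------------------
# planar layout
# ---------------------------------------------------------------------------

@dataclass
class PlanarLayout:
    """Planar pose of every segment plus the linearization maps.

    ``starts``/``ends`` are (n_segments, 2) arrays in room cm, traversal
    order from F1; the midline polyline is their concatenation.
    """

    track: TrackModel
    cfg: TrackConfiguration
    starts: np.ndarray
    ends: np.ndarray

    _dirs: np.ndarray = field(init=False, repr=False)
    _lengths: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d = self.ends - self.starts
        self._lengths = np.linalg.norm(d, axis=1)
        self._dirs = d / self._lengths[:, None]
        self._cum = np.concatenate([[0.0], np.cumsum(self._lengths)])

    @property
    def total_length(self) -> float:
        return float(self._cum[-1])

    @property
    def segment_lengths(self) -> np.ndarray:
        return self._lengths

    def polyline(self) -> np.ndarray:
        """Midline vertices, (n_segments + 1, 2)."""
        return np.vstack([self.starts, self.ends[-1]])

    # ---- planar -> linear --------------------------------------------
    def linearize(self, points: np.ndarray, tolerance: float = 4.0,
                  strict: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Map planar points (m, 2) to (x_L, y_L).

        ``tolerance`` is the allowed distance beyond the midline (cm); points
        farther than ``track_width/2 + tolerance`` raise :class:`OffTrackError`
        when ``strict`` (else they get y_L = nan and the nearest x_L).
        """
        P = np.atleast_2d(np.asarray(points, dtype=float))
        A, D, L = self.starts, self._dirs, self._lengths
        # (m, n) projections onto each segment
        rel = P[:, None, :] - A[None, :, :]
        t = np.clip(np.einsum("mnk,nk->mn", rel, D), 0.0, L[None, :])
        proj = A[None, :, :] + t[:, :, None] * D[None, :, :]
        v = P[:, None, :] - proj
        dist = np.linalg.norm(v, axis=2)
        best = np.argmin(dist, axis=1)
        m = np.arange(len(P))
        x_l = self._cum[best] + t[m, best]
        cross = (D[best, 0] * v[m, best, 1] - D[best, 1] * v[m, best, 0])
        y_l = np.sign(cross) * dist[m, best]
        limit = self.track.track_width / 2 + tolerance
        off = dist[m, best] > limit
        if off.any():
            if strict:
                raise OffTrackError(
                    f"{int(off.sum())} point(s) farther than {limit:.1f} cm "
                    "from the track midline")
            y_l = y_l.copy()
            y_l[off] = np.nan
        return x_l, y_l

    # ---- linear -> planar --------------------------------------------
    def to_planar(self, x_l: np.ndarray, y_l: np.ndarray | float = 0.0) -> np.ndarray:
        """Map linear coordinates back to room cm, (m, 2)."""
        x_l = np.atleast_1d(np.asarray(x_l, dtype=float))
        y_l = np.broadcast_to(np.asarray(y_l, dtype=float), x_l.shape)
        seg = np.clip(np.searchsorted(self._cum, x_l, side="right") - 1,
                      0, len(self._lengths) - 1)
        local = x_l - self._cum[seg]
        d = self._dirs[seg]
        left = np.stack([-d[:, 1], d[:, 0]], axis=1)   # left normal
        return self.starts[seg] + d * local[:, None] + left * y_l[:, None]

    # ---- elastic skeleton (axis) coordinate --------------------------
    @property
    def axis_length(self) -> float:
        """Length of the track's elastic skeleton.

        Track A: the (configuration-invariant) arc length.  Track B: the
        main-line footprint of the U (440 cm path over a 360 cm skeleton;
        the detour stretches one 40 cm stretch of skeleton into 120 cm of
        path).
        """
        if self.track.track_id == "A":
            return self.total_length
        return self.total_length - 2 * self.track.segment_length

    def axis_of(self, x_l: np.ndarray) -> np.ndarray:
        """Elastic-skeleton coordinate of a path position x_L."""
        x_l = np.asarray(x_l, dtype=float)
        if self.track.track_id == "A":
            return x_l
        p0, p1 = protrusion_span(self.track, self.cfg.protrusion_side)
        a = np.where(
            x_l < p0, x_l,
            np.where(x_l <= p1, p0 + (x_l - p0) / 3.0, x_l - (p1 - p0) * 2 / 3.0))
        return a

    def path_of_axis(self, a: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`axis_of` (maps skeleton to path x_L)."""
        a = np.asarray(a, dtype=float)
        if self.track.track_id == "A":
            return a
        p0, p1 = protrusion_span(self.track, self.cfg.protrusion_side)
        a1 = p0 + (p1 - p0) / 3.0   # skeleton footprint end
        return np.where(
            a < p0, a,
            np.where(a <= a1, p0 + (a - p0) * 3.0, a + (p1 - p0) * 2 / 3.0))


def layout_planar(track: TrackModel, cfg: TrackConfiguration) -> PlanarLayout:
    """Place every rigid segment in the room frame for one pose."""
    if track.track_id == "A":
        return _layout_track_a(track, cfg)
    return _layout_track_b(track, cfg)


def _layout_track_a(track: TrackModel, cfg: TrackConfiguration) -> PlanarLayout:
    if cfg.top_extent is None or cfg.bottom_extent is None:
        raise InvalidParameterError("Track A pose needs top/bottom extents")
    L = track.segment_length
    arm = track.arm_length
    base_h = 2 * L
    for e in (cfg.top_extent, cfg.bottom_extent):
        if not (track.extent_min_physical - 1e-9 <= e <= arm + 1e-9):
            raise GeometryError(f"extent {e:.1f} cm outside reachable range")

    def fold_vertices(extent: float, y0: float, outward: bool) -> np.ndarray:
        """Vertices of one folded arm from well to corner (5 points)."""
        c = min(1.0, extent / arm)
        s = math.sqrt(max(0.0, 1.0 - c * c))
        dy = (L * s) * (1.0 if outward else -1.0)
        xs = np.array([extent, extent - L * c, extent - 2 * L * c,
                       extent - 3 * L * c, 0.0])
        ys = np.array([y0, y0 + dy, y0, y0 + dy, y0])
        return np.stack([xs, ys], axis=1)

    top = fold_vertices(cfg.top_extent, base_h, outward=True)      # F1 -> corner
    bot = fold_vertices(cfg.bottom_extent, 0.0, outward=False)     # corner -> F2, reversed
    verts = [top[0], top[1], top[2], top[3], top[4],        # segs 1-4 end at (0, 80)
             np.array([0.0, L]),                            # seg 5 end
             np.array([0.0, 0.0]),                          # seg 6 end (origin corner)
             bot[3], bot[2], bot[1], bot[0]]                # segs 7-10 to F2
    verts = np.array(verts)
    return PlanarLayout(track, cfg, verts[:-1], verts[1:])


def _layout_track_b(track: TrackModel, cfg: TrackConfiguration) -> PlanarLayout:
    if cfg.protrusion_side not in PROTRUSION_SIDES:
        raise InvalidParameterError(f"unknown protrusion side {cfg.protrusion_side!r}")
    L = track.segment_length
    top_y, arm = L, 4 * L
    if cfg.protrusion_side == "segments_3_4_5":
        verts = [(arm, top_y), (3 * L, top_y), (2 * L, top_y),     # segs 1, 2
                 (2 * L, 2 * L), (L, 2 * L), (L, top_y),           # detour 3, 4, 5
                 (0, top_y),                                       # seg 6
                 (0, 0),                                           # base (7)
                 (L, 0), (2 * L, 0), (3 * L, 0), (arm, 0)]         # segs 8-11
    else:
        verts = [(arm, top_y), (3 * L, top_y), (2 * L, top_y), (L, top_y),
                 (0, top_y),                                       # segs 1-4
                 (0, 0),                                           # base (5)
                 (L, 0),                                           # seg 6
                 (L, -L), (2 * L, -L), (2 * L, 0),                 # detour 7, 8, 9
                 (3 * L, 0), (arm, 0)]                             # segs 10, 11
    verts = np.array(verts, dtype=float)
    return PlanarLayout(track, cfg, verts[:-1], verts[1:])


def linearize_point(track: TrackModel, cfg: TrackConfiguration,
                    p_planar: Sequence[float], tolerance: float = 4.0
                    ) -> tuple[float, float]:
    """Linearize a single planar point; see :meth:`PlanarLayout.linearize`."""
    layout = layout_planar(track, cfg)
    x_l, y_l = layout.linearize(np.asarray(p_planar, dtype=float)[None, :],
                                tolerance=tolerance)
    return float(x_l[0]), float(y_l[0])


# ---------------------------------------------------------------------------
# vertical sections (Track A)
# ---------------------------------------------------------------------------

def section_of_extent(track: TrackModel, extent: float) -> int:
    """Vertical-section index (1..12) of a well at the given extent."""
    origin = track.section_grid_origin
    if not (origin - 1e-9 <= extent <= track.extent_max + 1e-9):
        raise GeometryError(
            f"extent {extent:.1f} cm outside the section grid "
            f"[{origin:.1f}, {track.extent_max:.1f}]")
    s = int(math.floor((extent - origin) / SECTION_WIDTH_CM)) + 1
    return min(max(s, 1), N_SECTIONS)


def vertical_section_of(track: TrackModel, cfg: TrackConfiguration,
                        arm: str) -> int:
    """Section index of the given arm's food well in a Track A pose."""
    if track.track_id != "A":
        raise UnsupportedTrackError("vertical sections are defined for Track A")
    if arm not in ("top", "bottom"):
        raise InvalidParameterError("arm must be 'top' or 'bottom'")
    extent = cfg.top_extent if arm == "top" else cfg.bottom_extent
    return section_of_extent(track, extent)


# ---------------------------------------------------------------------------
# Track B comparison spans (all in path arc length, cm from F1)
# ---------------------------------------------------------------------------

def protrusion_span(track: TrackModel, side: str) -> tuple[float, float]:
    """Path interval occupied by the three detour segments on ``side``."""
    L = track.segment_length
    if side == "segments_3_4_5":
        return (2 * L, 5 * L)
    if side == "segments_7_8_9":
        return (6 * L, 9 * L)
    raise InvalidParameterError(f"unknown protrusion side {side!r}")


def center_segment_span(track: TrackModel, side: str) -> tuple[float, float]:
    """Path interval of the detour's central ("across") segment."""
    p0, p1 = protrusion_span(track, side)
    L = track.segment_length
    return (p0 + L, p1 - L)


def projected_straight_span(track: TrackModel, side: str) -> tuple[float, float]:
    """Path interval, in the *opposite* pose, of the single straight segment
    that replaces this side's protrusion after the flip."""
    L = track.segment_length
    if side == "segments_3_4_5":
        return (2 * L, 3 * L)        # traversal section 3 of the 7-8-9 pose
    if side == "segments_7_8_9":
        return (8 * L, 9 * L)        # traversal section 9 of the 3-4-5 pose
    raise InvalidParameterError(f"unknown protrusion side {side!r}")


def material_span(track: TrackModel, cfg: TrackConfiguration,
                  material: int) -> tuple[float, float]:
    """Path interval occupied by material segment ``material`` in ``cfg``.

    On Track A materials never change their arc-length span.  On Track B the
    three detour materials (3, 4, 5) move across the flip.
    """
    L = track.segment_length
    if track.track_id == "A":
        return track.segment_span(material)
    order = _TRACK_B_TRAVERSAL[cfg.protrusion_side]
    pos = order.index(material)          # 0-based traversal slot
    return (pos * L, (pos + 1) * L)
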