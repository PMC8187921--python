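"""Rotor-tip detection and trajectory linking.

A rotor's tip (phase singularity) is the point where the wavefront
meets the waveback.  It is located as the intersection of the
u = V_iso isoline at one tracked frame with the same isoline at the
next frame (V_iso = 0.8): away from the pivot the isoline sweeps
forward between frames, so only the pivot is common to both.  Isolines
are extracted sub-pixel by marching squares and intersected segment by
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from shapely.geometry import MultiLineString, Point
from skimage import measure

V_ISO_DEFAULT = 0.8


@dataclass(frozen=True)
class TipObservation:
    """One tip sighting: position in mm, time in ms."""

    x: float
    y: float
    t: float

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class RotorTrajectory:
    """Time-ordered tip observations of one rotor."""

    observations: list[TipObservation] = field(default_factory=list)

    @property
    def birth(self) -> float:
        return self.observations[0].t if self.observations else float("nan")

    @property
    def death(self) -> float:
        return self.observations[-1].t if self.observations else float("nan")

    @property
    def lifetime(self) -> float:
        return self.death - self.birth if self.observations else 0.0

    def last(self) -> TipObservation:
        return self.observations[-1]


def _contours_mm(frame: np.ndarray, v_iso: float, pixel_size: float):
    """Marching-squares isolines of u = v_iso as (x, y) mm polylines."""
    lines = []
    for contour in measure.find_contours(np.asarray(frame, dtype=float), v_iso):
        if len(contour) < 2:
            continue
        # find_contours returns fractional (row, col); pixel centre i is
        # at (i + 0.5) * pixel_size
        xy = np.empty_like(contour)
        xy[:, 0] = (contour[:, 1] + 0.5) * pixel_size
        xy[:, 1] = (contour[:, 0] + 0.5) * pixel_size
        lines.append(xy)
    return lines


def _cluster_points(points: np.ndarray, radius: float) -> np.ndarray:
    """Merge points closer than ``radius`` into their centroid (greedy)."""
    if len(points) == 0:
        return points
    used = np.zeros(len(points), dtype=bool)
    out = []
    for i in range(len(points)):
        if used[i]:
            continue
        group = [i]
        used[i] = True
        for j in range(i + 1, len(points)):
            if not used[j] and np.hypot(*(points[j] - points[i])) < radius:
                group.append(j)
                used[j] = True
        out.append(points[group].mean(axis=0))
    return np.asarray(out)


def _interior_mask(mask: np.ndarray, margin_px: int) -> np.ndarray:
    if margin_px <= 0:
        return mask
    from scipy import ndimage

    return ndimage.binary_erosion(mask, iterations=margin_px)


CLUSTER_RADIUS_DEFAULT = 10.0   # mm ~ one rotor core diameter


def find_tips(frame_n: np.ndarray, frame_n1: np.ndarray,
              v_iso: float = V_ISO_DEFAULT, pixel_size: float = 0.3,
              t: float = 0.0,
              cluster_radius_mm: float = CLUSTER_RADIUS_DEFAULT,
              mask: np.ndarray | None = None,
              boundary_margin_px: int = 0) -> list[TipObservation]:
    """Tips as intersections of the v_iso isolines of consecutive frames.

    Point intersections only: where the two isolines share whole
    segments (e.g. identical frames) the overlap is a line, not a
    pivot, and is discarded.  Nearby intersection points (within
    ``cluster_radius_mm``) are merged into one tip: an oblique
    front/back crossing can yield two nearby intersection points for
    one pivot.  When a ``mask`` is given (typically a pre-eroded
    :func:`tracking_mask`; ``boundary_margin_px`` erodes it further if
    set), candidate points outside it are dropped.  Returns an empty
    list when either frame has no isoline.
    """
    lines_a = _contours_mm(frame_n, v_iso, pixel_size)
    lines_b = _contours_mm(frame_n1, v_iso, pixel_size)
    if not lines_a or not lines_b:
        return []
    mls_a = MultiLineString([ln.tolist() for ln in lines_a])
    mls_b = MultiLineString([ln.tolist() for ln in lines_b])
    inter = mls_a.intersection(mls_b)
    points = []
    geoms = getattr(inter, "geoms", [inter])
    for geom in geoms:
        if isinstance(geom, Point):
            points.append((geom.x, geom.y))
    if not points:
        return []
    pts = np.asarray(points)
    if mask is not None:
        interior = _interior_mask(mask, boundary_margin_px)
        rows = np.clip(np.round(pts[:, 1] / pixel_size - 0.5).astype(int),
                       0, mask.shape[0] - 1)
        cols = np.clip(np.round(pts[:, 0] / pixel_size - 0.5).astype(int),
                       0, mask.shape[1] - 1)
        pts = pts[interior[rows, cols]]
        if len(pts) == 0:
            return []
    merged = _cluster_points(pts, cluster_radius_mm)
    return [TipObservation(x=float(p[0]), y=float(p[1]), t=t) for p in merged]


LINKING_RADIUS_DEFAULT = 20.0   # mm; tip meander/orbit steps reach ~7 mm per 10 ms frame


def stitch_trajectories(trajs: list[RotorTrajectory],
                        stitch_gap_ms: float = 50.0,
                        stitch_radius: float = 25.0,
                        frame_ms: float = 10.0) -> list[RotorTrajectory]:
    """Gap-closing: merge trajectory fragments that are one rotor.

    When a meandering tip is double-detected for a frame, frame-wise
    assignment can hand the continuation to the fresh duplicate and
    close the old track even though the rotor never disappeared.  As in
    standard particle-tracking gap closing, a trajectory ending at time
    t and position p absorbs one starting within ``stitch_gap_ms`` after
    t (one frame of overlap tolerated) and ``stitch_radius`` mm of p.
    """
    trajs = sorted((t for t in trajs if t.observations),
                   key=lambda t: t.birth)
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(trajs):
            for j, b in enumerate(trajs):
                if i == j:
                    continue
                if a.death - frame_ms <= b.birth <= a.death + stitch_gap_ms:
                    la, fb = a.observations[-1], b.observations[0]
                    if np.hypot(la.x - fb.x, la.y - fb.y) <= stitch_radius:
                        a.observations.extend(
                            o for o in b.observations if o.t > a.death)
                        trajs.pop(j)
                        changed = True
                        break
            if changed:
                break
    return trajs


def link_trajectories(tips_per_frame: list[list[TipObservation]],
                      linking_radius: float = LINKING_RADIUS_DEFAULT,
                      max_gap_frames: int = 2,
                      stitch_gap_ms: float = 50.0,
                      stitch_radius: float = 25.0) -> list[RotorTrajectory]:
    """Link per-frame tips into trajectories by optimal assignment.

    Frame by frame, active trajectories are matched to new tips by the
    assignment minimising total distance (pairs beyond
    ``linking_radius`` mm are forbidden); unmatched tips start new
    trajectories; a trajectory survives ``max_gap_frames`` frames
    without a match before it is closed.  Fragments are then merged by
    :func:`stitch_trajectories` (disable with ``stitch_gap_ms=0``).
    """
    finished: list[RotorTrajectory] = []
    active: list[tuple[RotorTrajectory, int]] = []  # (traj, frames since match)
    for tips in tips_per_frame:
        tips = list(tips)
        matched_traj = set()
        matched_tip = set()
        if active and tips:
            cost = np.full((len(active), len(tips)), 1e6)
            for i, (traj, _) in enumerate(active):
                last = traj.last()
                for j, tip in enumerate(tips):
                    d = np.hypot(tip.x - last.x, tip.y - last.y)
                    if d <= linking_radius:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e6:
                    active[i][0].observations.append(tips[j])
                    matched_traj.add(i)
                    matched_tip.add(j)
        next_active = []
        for i, (traj, gap) in enumerate(active):
            if i in matched_traj:
                next_active.append((traj, 0))
            elif gap < max_gap_frames:
                next_active.append((traj, gap + 1))
            else:
                finished.append(traj)
        for j, tip in enumerate(tips):
            if j not in matched_tip:
                next_active.append((RotorTrajectory([tip]), 0))
        active = next_active
    finished.extend(traj for traj, _ in active)
    if stitch_gap_ms > 0:
        finished = stitch_trajectories(finished, stitch_gap_ms, stitch_radius)
    return finished


def is_stable_rotor(traj: RotorTrajectory, min_lifetime: float = 2000.0) -> bool:
    """A stable rotor is a re-entrant circuit lasting >= 2000 ms."""
    if not traj.observations:
        return False
    return traj.lifetime >= min_lifetime


def tracking_mask(template, edge_margin_mm: float = 3.0) -> np.ndarray:
    """Disk mask eroded by ``edge_margin_mm`` from the outer border only.

    Wavefronts grazing the disk (mitral) border bend their isolines
    there between frames, producing intersection points that are not
    pivots, so a band along the outer edge is excluded.  The PV/LAA
    rims are deliberately *not* excluded: a rotor that drifts onto an
    opening and pins circulates as anatomical re-entry whose tip rides
    within half a pixel of the rim — masking the rims would blind the
    tracker to exactly the anchored rotors that matter.  Rim-grazing
    artifacts from passing far-field waves do slip through, but they
    are intermittent (one burst per wave passage) and fall apart into
    short trajectories, while a genuine pinned tip is present every
    frame.
    """
    margin_px = max(1, int(round(edge_margin_mm / template.pixel_size)))
    return _interior_mask(template.disk_mask(), margin_px)


class TipTracker:
    """Streaming observer: feed u frames, get tips and trajectories.

    Usable as the ``observers`` callback of the simulator (called with
    (t, u)); keeps only the previous frame in memory.  ``mask`` is the
    region in which tips are accepted (typically
    :func:`tracking_mask`).
    """

    def __init__(self, pixel_size: float = 0.3, v_iso: float = V_ISO_DEFAULT,
                 linking_radius: float = LINKING_RADIUS_DEFAULT,
                 mask: np.ndarray | None = None,
                 boundary_margin_px: int = 0):
        self.pixel_size = pixel_size
        self.v_iso = v_iso
        self.linking_radius = linking_radius
        self.interior = None if mask is None \
            else _interior_mask(mask, boundary_margin_px)
        self.tips_per_frame: list[list[TipObservation]] = []
        self.times: list[float] = []
        self._prev: np.ndarray | None = None
        self._prev_t: float | None = None

    def reset(self) -> None:
        """Drop all accumulated frames (called between retry attempts)."""
        self.tips_per_frame = []
        self.times = []
        self._prev = None
        self._prev_t = None

    def __call__(self, t: float, u: np.ndarray) -> None:
        if self._prev is not None:
            tips = find_tips(self._prev, u, self.v_iso, self.pixel_size,
                             t=self._prev_t, mask=self.interior,
                             boundary_margin_px=0)
            self.tips_per_frame.append(tips)
            self.times.append(self._prev_t)
        self._prev = u.copy()
        self._prev_t = t

    def trajectories(self) -> list[RotorTrajectory]:
        return link_trajectories(self.tips_per_frame, self.linking_radius)

    def longest_lifetime(self) -> float:
        trajs = self.trajectories()
        return max((t.lifetime for t in trajs), default=0.0)

    def latest_tip(self) -> TipObservation | None:
        for tips in reversed(self.tips_per_frame):
            if tips:
                return tips[-1]
        return None
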