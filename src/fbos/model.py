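"""Functional base-of-support polygons: hulls, averaging, metrics.

The fBOS of one foot is the convex hull of the selected flat-foot COP
samples in the foot frame. Per participant, the right-foot hull is
mirrored mediolaterally into the left-foot convention, the two hulls are
averaged by arc-length-indexed boundary averaging, shape metrics are
taken in metres, and the polygon is normalised by foot width and length
(x/W, y/L). Group templates are arc-length averages of the normalised
participant polygons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely.geometry as sgeom
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry.polygon import orient

from .cop import COPSegment
from .foot import FootFrame, FootprintPolygon, footprint_polygon, project_to_foot

METRIC = "m"
NORMALIZED = "normalized"


@dataclass
class FBOSPolygon:
    """Closed convex polygon of COP extremes in foot-frame coordinates.

    ``vertices`` is an open (N, 2) CCW ring; ``units`` is ``"m"`` or
    ``"normalized"`` (x/W, y/L); ``side`` records provenance
    (left/right/both).
    """

    vertices: np.ndarray
    units: str = METRIC
    side: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must have shape (n, 2)")
        if self.vertices.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.units not in (METRIC, NORMALIZED):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    @property
    def perimeter(self) -> float:
        ring = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.linalg.norm(np.diff(ring, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(sgeom.Polygon(self.vertices).centroid.coords[0])

    def as_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon, independent of orientation."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def convex_hull(points: np.ndarray, units: str = METRIC,
                side: Optional[str] = None) -> FBOSPolygon:
    """Minimal convex polygon containing the points, CCW, no collinear
    boundary points. Raises ``ValueError`` for fewer than 3 points or a
    degenerate (collinear) set."""
    pts = np.asarray(points, dtype=float)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 finite points for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (collinear?): {exc}") from exc
    return FBOSPolygon(pts[hull.vertices], units=units, side=side)  # CCW in 2D


def reflect_ml(poly: FBOSPolygon) -> FBOSPolygon:
    """Mirror a polygon mediolaterally (x → −x), restoring CCW order."""
    v = poly.vertices.copy()
    v[:, 0] = -v[:, 0]
    side = {"left": "right", "right": "left"}.get(poly.side, poly.side)
    return FBOSPolygon(v[::-1], units=poly.units, side=side)


def _anchor_point(ring: sgeom.LinearRing, centroid: np.ndarray) -> np.ndarray:
    """Boundary intersection with the +y ray from the centroid.

    Ties (ray grazing an edge) are broken by smallest x, then smallest y.
    """
    span = ring.length  # ray longer than any chord
    ray = sgeom.LineString([centroid, centroid + np.array([0.0, span])])
    hit = ray.intersection(ring)
    if hit.is_empty:
        raise ValueError("anchor ray does not intersect the boundary")
    pts: List[Tuple[float, float]] = []
    geoms = getattr(hit, "geoms", [hit])
    for g in geoms:
        pts.extend(np.atleast_2d(np.asarray(g.coords)))
    pts = sorted(pts, key=lambda p: (p[0], p[1]))
    return np.asarray(pts[0], dtype=float)


def resample_arclength(poly: FBOSPolygon, n_points: int) -> np.ndarray:
    """Resample a polygon boundary at equal arc-length fractions.

    Returns ``n_points`` CCW boundary points starting at a canonical
    anchor: the intersection of the boundary with the +y (anterior) ray
    from the centroid. The result is independent of which vertex the
    polygon storage starts at.
    """
    if n_points < 8:
        raise ValueError("n_points must be at least 8")
    shp = orient(sgeom.Polygon(poly.vertices), sign=1.0)
    ring = sgeom.LinearRing(shp.exterior.coords)
    perim = ring.length
    if perim <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    centroid = np.asarray(shp.centroid.coords[0])
    anchor = _anchor_point(ring, centroid)
    s0 = ring.project(sgeom.Point(anchor))
    s = (s0 + np.arange(n_points) * perim / n_points) % perim
    out = np.array([ring.interpolate(si).coords[0] for si in s])
    return out


def average_polygons(
    polygons: Sequence[FBOSPolygon], n_points: int = 100
) -> Tuple[FBOSPolygon, np.ndarray]:
    """Arc-length-indexed average of closed convex boundaries.

    Each polygon is resampled at ``n_points`` equal perimeter fractions
    from its anchor, boundaries are averaged vertex-wise, and the mean
    boundary is re-hulled. Returns the averaged polygon and the
    per-vertex dispersion (standard deviation of the resampled boundary
    points about their mean, one radial value per vertex).
    """
    if len(polygons) == 0:
        raise ValueError("need at least one polygon")
    units = polygons[0].units
    if any(p.units != units for p in polygons):
        raise ValueError("cannot average polygons with mixed units")
    stacks = np.stack([resample_arclength(p, n_points) for p in polygons])
    mean = stacks.mean(axis=0)
    # per-vertex RMS distance of each replicate boundary from the mean
    dispersion = (np.sqrt(((stacks - mean) ** 2).sum(axis=2).mean(axis=0))
                  if len(polygons) > 1 else np.zeros(n_points))
    side = polygons[0].side if len({p.side for p in polygons}) == 1 else "both"
    return convex_hull(mean, units=units, side=side), dispersion


@dataclass
class FBOSMetrics:
    """Normalised shape metrics of a metric fBOS polygon in its frame."""

    area_ratio: float      # hull area / footprint hexagon area
    norm_length: float     # AP extent / foot length
    norm_width: float      # ML extent / foot width
    d_toe: float           # inward distance from toe tip, fraction of L
    d_heel: float          # inward distance from heel, fraction of L
    d_lat_ankle: float     # inward distance from lateral ankle, fraction of W
    d_little_toe: float    # inward distance from MTP5, fraction of W
    outside_footprint: bool = False


@dataclass
class GroupTemplate:
    """Age-group average fBOS in normalised coordinates."""

    group: str
    polygon: FBOSPolygon          # units == "normalized"
    dispersion: np.ndarray        # per-vertex radial SD
    n_participants: int


@dataclass
class ParticipantFBOS:
    """Per-participant averaged fBOS with metrics and provenance."""

    polygon_normalized: FBOSPolygon
    polygon_metric: FBOSPolygon
    metrics: FBOSMetrics
    frame: FootFrame              # combined left-convention frame
    feet_used: str                # "both", "left", or "right"


def fbos_metrics(poly: FBOSPolygon, frame: FootFrame) -> FBOSMetrics:
    """Shape metrics of a metric polygon relative to its foot frame.

    AP inward distances are measured from the toe-tip and heel markers to
    the polygon's bounding box; ML inward distances from the lateral
    ankle and MTP5 markers to the polygon's extreme extent on the
    little-toe side, all normalised by foot length L or width W.
    """
    if poly.units != METRIC:
        raise ValueError("metrics are defined on a metric polygon")
    L, W = frame.foot_length, frame.foot_width
    v = poly.vertices
    min_y, max_y = float(v[:, 1].min()), float(v[:, 1].max())
    min_x, max_x = float(v[:, 0].min()), float(v[:, 0].max())
    y_toe = frame.marker_foot["toe_tip"][1]
    y_heel = frame.marker_foot["heel"][1]
    s = frame.mtp5_sign  # lateral (little-toe) side on the x axis
    lat_extent = max_x if s > 0 else -min_x
    fp = footprint_polygon(frame)
    inside = sgeom.Polygon(fp.vertices).buffer(1e-9).contains(
        sgeom.Polygon(v))
    return FBOSMetrics(
        area_ratio=poly.area / fp.area,
        norm_length=(max_y - min_y) / L,
        norm_width=(max_x - min_x) / W,
        d_toe=(y_toe - max_y) / L,
        d_heel=(min_y - y_heel) / L,
        d_lat_ankle=(abs(frame.marker_foot["lat_ankle"][0]) - lat_extent) / W,
        d_little_toe=(abs(frame.marker_foot["mtp5"][0]) - lat_extent) / W,
        outside_footprint=not inside,
    )


def _mirror_frame(frame: FootFrame) -> FootFrame:
    """Mirror a right-foot frame's marker coordinates into left convention."""
    mirrored = {k: np.array([-xy[0], xy[1]]) for k, xy in frame.marker_foot.items()}
    return FootFrame(
        side="left",
        origin=frame.origin,
        anterior=frame.anterior,
        lateral=frame.lateral,
        foot_length=frame.foot_length,
        foot_width=frame.foot_width,
        marker_foot=mirrored,
    )


def _combine_frames(frames: List[FootFrame]) -> FootFrame:
    """Average marker coordinates of left-convention frames."""
    first = frames[0]
    if len(frames) == 1:
        return first
    marker = {
        k: np.mean([f.marker_foot[k] for f in frames], axis=0)
        for k in first.marker_foot
    }
    heel = marker["heel"]
    marker = {k: v - heel for k, v in marker.items()}  # re-anchor at heel
    L = float(np.linalg.norm(marker["toe_tip"]))
    W = float(abs(marker["mtp1"][0] - marker["mtp5"][0]))
    return FootFrame(
        side="left",
        origin=first.origin,
        anterior=first.anterior,
        lateral=first.lateral,
        foot_length=L,
        foot_width=W,
        marker_foot=marker,
    )


def extract_participant_fbos(
    segments_left: Sequence[COPSegment],
    segments_right: Sequence[COPSegment],
    frame_left: Optional[FootFrame],
    frame_right: Optional[FootFrame],
    n_points: int = 100,
) -> ParticipantFBOS:
    """Participant fBOS from per-foot COP segments.

    Per foot: pool the segment COP samples (lab frame), project into the
    foot frame and take the convex hull. The right-foot hull is mirrored
    mediolaterally into the left convention. The available hulls are
    averaged arc-length-wise; metrics are computed in metres against the
    combined frame, and the polygon is then normalised by (W, L). If only
    one foot yields data, that foot is used alone and flagged.
    """
    hulls: List[FBOSPolygon] = []
    frames: List[FootFrame] = []
    used: List[str] = []
    for side, segments, frame in (
        ("left", segments_left, frame_left),
        ("right", segments_right, frame_right),
    ):
        if not segments or frame is None:
            continue
        pts = project_to_foot(frame, np.vstack([s.xy for s in segments]))
        hull = convex_hull(pts, units=METRIC, side=side)
        if side == "right":
            hull = reflect_ml(hull)
            frame = _mirror_frame(frame)
        hulls.append(hull)
        frames.append(frame)
        used.append(side)
    if not hulls:
        raise ValueError("no valid segments on either foot")

    avg, _ = average_polygons(hulls, n_points=n_points)
    combined = _combine_frames(frames)
    metrics = fbos_metrics(avg, combined)
    norm_v = avg.vertices / np.array([combined.foot_width, combined.foot_length])
    poly_norm = FBOSPolygon(norm_v, units=NORMALIZED, side=avg.side)
    return ParticipantFBOS(
        polygon_normalized=poly_norm,
        polygon_metric=avg,
        metrics=metrics,
        frame=combined,
        feet_used="both" if len(used) == 2 else used[0],
    )


def make_group_template(
    group: str, polygons: Sequence[FBOSPolygon], n_points: int = 100
) -> GroupTemplate:
    """Average normalised participant polygons into a group template."""
    if any(p.units != NORMALIZED for p in polygons):
        raise ValueError("group templates are built from normalised polygons")
    poly, disp = average_polygons(polygons, n_points=n_points)
    return GroupTemplate(group=group, polygon=poly, dispersion=disp,
                         n_participants=len(polygons))


def scale_template(
    template: GroupTemplate, foot_length: float, foot_width: float,
    side: str = "left",
) -> FBOSPolygon:
    """Scale a normalised group template to a participant's foot.

    Multiplies x by W and y by L, mirrors mediolaterally for a right
    foot, and leaves the heel at the frame origin.
    """
    if foot_length <= 0 or foot_width <= 0:
        raise ValueError("foot length and width must be positive")
    v = template.polygon.vertices * np.array([foot_width, foot_length])
    poly = FBOSPolygon(v, units=METRIC, side="left")
    if side == "right":
        poly = reflect_ml(poly)
        poly.side = "right"
    return poly
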