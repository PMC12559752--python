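"""Foot-fixed planar frames and footprint geometry.

The foot frame has its origin at the heel marker's floor projection and
its +y axis along the heel→toe-tip floor projection (anterior). The +x
axis completes a right-handed planar frame with z up, i.e. +x points to
the anatomical right of the anterior axis. The little-toe (MTP5) side is
therefore +x for the right foot and −x for the left foot; pooling across
feet mirrors right-foot data into the left convention (see
:mod:`fbos.model`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import shapely.geometry as sgeom
from shapely.geometry.polygon import orient

from .trial import FOOT_MARKERS, MarkerTrajectory, foot_marker_labels

#: anatomical hexagon ordering, heel first (left foot; mirrored for right)
FOOTPRINT_ORDER: Tuple[str, ...] = (
    "heel", "lat_ankle", "mtp5", "toe_tip", "mtp1", "med_ankle",
)


@dataclass
class FootFrame:
    """Planar foot-fixed coordinate frame built from quiet standing."""

    side: str
    origin: np.ndarray            # (2,) lab floor position of heel
    anterior: np.ndarray          # (2,) unit vector, heel→toe
    lateral: np.ndarray           # (2,) unit vector, right-handed with z up
    foot_length: float            # heel → toe-tip distance [m]
    foot_width: float             # |x(MTP1) − x(MTP5)| in frame [m]
    marker_foot: Dict[str, np.ndarray]  # marker name → (2,) foot-frame coords

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        if not np.isclose(np.linalg.norm(self.anterior), 1.0):
            raise ValueError("anterior must be a unit vector")
        if not np.isclose(self.anterior @ self.lateral, 0.0, atol=1e-9):
            raise ValueError("frame axes must be orthogonal")
        if not (self.foot_length > 0 and self.foot_width > 0):
            raise ValueError("foot length and width must be positive")

    @property
    def mtp5_sign(self) -> float:
        """Sign of the little-toe side on the frame x axis (+1 or −1)."""
        return float(np.sign(self.marker_foot["mtp5"][0]))


class MarkerGapError(ValueError):
    """Raised when marker gaps cover too much of the requested window."""


def _floor(points: np.ndarray) -> np.ndarray:
    """Project lab points to the floor plane by discarding z."""
    return np.asarray(points, dtype=float)[..., :2]


def fit_foot_frame(
    markers: MarkerTrajectory,
    side: str,
    quiet_window: Tuple[float, float] = (0.0, 2.0),
) -> FootFrame:
    """Build a foot frame from time-averaged markers over a quiet window.

    Marker positions are averaged over valid samples in ``quiet_window``
    (seconds) and projected vertically to the floor. Raises
    :class:`MarkerGapError` if any required marker is missing for more
    than half of the window.
    """
    labels = foot_marker_labels(side)
    t = markers.time
    in_win = (t >= quiet_window[0]) & (t < quiet_window[1])
    if not in_win.any():
        raise ValueError(f"quiet window {quiet_window} contains no samples")

    mean_pos: Dict[str, np.ndarray] = {}
    for name, label in zip(FOOT_MARKERS, labels):
        idx = markers.index(label)
        valid = in_win & markers.mask[:, idx]
        if valid.sum() < 0.5 * in_win.sum():
            raise MarkerGapError(
                f"marker {label!r} has gaps over >50% of quiet window {quiet_window}"
            )
        mean_pos[name] = markers.positions[valid, idx, :].mean(axis=0)

    heel = _floor(mean_pos["heel"])
    toe = _floor(mean_pos["toe_tip"])
    axis = toe - heel
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("heel and toe-tip coincide; cannot orient foot")
    anterior = axis / length
    # right-handed with z up: lateral = anterior rotated −90° about z
    lateral = np.array([anterior[1], -anterior[0]])

    marker_foot = {
        name: np.array([
            (pos2 := _floor(p) - heel) @ lateral,
            pos2 @ anterior,
        ])
        for name, p in mean_pos.items()
    }
    width = float(abs(marker_foot["mtp1"][0] - marker_foot["mtp5"][0]))
    return FootFrame(
        side=side,
        origin=heel,
        anterior=anterior,
        lateral=lateral,
        foot_length=length,
        foot_width=width,
        marker_foot=marker_foot,
    )


def project_to_foot(frame: FootFrame, points: np.ndarray) -> np.ndarray:
    """Rigidly map lab-frame points into the planar foot frame.

    Accepts (..., 2) floor points or (..., 3) lab points (z discarded).
    Returns (..., 2) foot-frame coordinates; distances in the floor plane
    are preserved.
    """
    pts = np.asarray(points, dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    rel = pts[..., :2] - frame.origin
    return np.stack([rel @ frame.lateral, rel @ frame.anterior], axis=-1)


@dataclass
class FootprintPolygon:
    """Hexagon through the six projected foot markers."""

    vertices: np.ndarray  # (6, 2) CCW, foot frame
    area: float           # m²


def footprint_polygon(frame: FootFrame) -> FootprintPolygon:
    """Hexagon enclosed by the six foot markers, CCW, shoelace area.

    Vertices follow the anatomical boundary order heel → lateral ankle →
    MTP5 → toe tip → MTP1 → medial ankle. If that ordering self-intersects
    (pathological marker placement) the convex hull of the six markers is
    used instead, with a warning.
    """
    verts = np.array([frame.marker_foot[name] for name in FOOTPRINT_ORDER])
    poly = sgeom.Polygon(verts)
    if not poly.is_valid or poly.area <= 0:
        warnings.warn(
            "anatomical footprint ordering self-intersects; "
            "falling back to convex hull of the six markers",
            stacklevel=2,
        )
        poly = sgeom.MultiPoint(verts).convex_hull
    poly = orient(poly, sign=1.0)  # CCW
    coords = np.asarray(poly.exterior.coords)[:-1]
    return FootprintPolygon(vertices=coords, area=float(poly.area))
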