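"""Core containers for marker and force-plate recordings.

Conventions: lab frame is right-handed with z up, units are metres,
newtons and newton-metres; sample indexing is 0-based and a record of
``n`` samples at rate ``r`` covers the half-open interval [0, n/r).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

#: canonical per-foot marker names (IOR-style shoe set)
FOOT_MARKERS: Tuple[str, ...] = (
    "heel", "med_ankle", "lat_ankle", "mtp1", "mtp5", "toe_tip",
)


def foot_marker_labels(side: str) -> Tuple[str, ...]:
    """Marker labels for one foot, e.g. ``L_heel`` ... ``L_toe_tip``."""
    side = side.lower()
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    prefix = "L" if side == "left" else "R"
    return tuple(f"{prefix}_{m}" for m in FOOT_MARKERS)


@dataclass
class MarkerTrajectory:
    """Time-indexed 3D marker positions.

    Parameters
    ----------
    labels : sequence of str
        Marker names, one per column of ``positions``.
    positions : ndarray, shape (n_samples, n_markers, 3)
        Positions in metres, lab frame. NaN marks gaps.
    rate : float
        Sampling rate in Hz.
    mask : ndarray of bool, shape (n_samples, n_markers), optional
        True where the sample is valid. Defaults to finite positions.
    """

    labels: Sequence[str]
    positions: np.ndarray
    rate: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_samples, n_markers, 3)")
        if len(self.labels) != self.positions.shape[1]:
            raise ValueError("labels length must match number of marker columns")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.positions).all(axis=2)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.positions.shape[:2]:
                raise ValueError("mask shape must be (n_samples, n_markers)")
        self.labels = list(self.labels)

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"marker {label!r} not present; have {self.labels}") from None

    def get(self, label: str) -> np.ndarray:
        """Positions of one marker, shape (n_samples, 3)."""
        return self.positions[:, self.index(label), :]

    def has(self, label: str) -> bool:
        return label in self.labels


@dataclass
class ForcePlateRecord:
    """Forces and moments of one force plate.

    ``F`` and ``M`` are (n_samples, 3) arrays of forces [N] and moments
    [N·m] about the plate origin. ``origin`` is the lab-frame position of
    the plate origin; ``origin_depth`` is how far the origin sits below
    the walking surface (0 for a surface-level origin). Plate axes are
    assumed aligned with the lab frame.
    """

    F: np.ndarray
    M: np.ndarray
    rate: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    origin_depth: float = 0.0
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.F.shape != self.M.shape or self.F.ndim != 2 or self.F.shape[1] != 3:
            raise ValueError("F and M must both have shape (n_samples, 3)")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.F.shape[0]

    @property
    def fz(self) -> np.ndarray:
        return self.F[:, 2]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class SyntheticTrial:
    """A generated standing trial with its ground truth.

    ``truth`` holds, per foot, the true fBOS polygon (foot-frame metres),
    the noise-free lab-frame COP at force rate, the flat-foot mask at
    marker rate, and the true body weight in newtons.
    """

    markers: MarkerTrajectory
    plates: Dict[str, ForcePlateRecord]
    truth: Dict[str, object]
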