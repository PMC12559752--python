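"""Walking-stance COP path length and stride speed.

Stance is detected as a contiguous stretch of vertical force above 50 N
on force data low-passed at 10 Hz (zero phase). The foot-normalised COP
path length P is the range of the COP along the instructed direction of
travel divided by foot length; the mediolateral direction is not
assessed because the COP does not traverse the foot width during gait.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .cop import COPTrajectory, compute_cop, lowpass_zero_phase
from .foot import FootFrame
from .trial import ForcePlateRecord, MarkerTrajectory


@dataclass
class StanceWindow:
    """One supra-threshold loading of a plate (filtered at 10 Hz)."""

    plate_id: str
    start: int                # first sample with Fz > threshold
    stop: int                 # one past the last such sample
    cop: np.ndarray           # (n, 2) lab-frame COP over the window
    fz: np.ndarray            # (n,) filtered vertical force
    rate: float

    @property
    def duration(self) -> float:
        return (self.stop - self.start) / self.rate


def detect_stance(
    plate: ForcePlateRecord,
    min_fz: float = 50.0,
    filter_cutoff: float = 10.0,
    min_duration: float = 0.2,
) -> List[StanceWindow]:
    """Maximal contiguous windows with filtered Fz above ``min_fz``.

    Force and moment channels are zero-phase low-passed at
    ``filter_cutoff`` before thresholding; windows shorter than
    ``min_duration`` seconds are discarded as artifacts.
    """
    F = lowpass_zero_phase(plate.F, filter_cutoff, plate.rate)
    M = lowpass_zero_phase(plate.M, filter_cutoff, plate.rate)
    filtered = ForcePlateRecord(F=F, M=M, rate=plate.rate, origin=plate.origin,
                                origin_depth=plate.origin_depth,
                                plate_id=plate.plate_id)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cop = compute_cop(filtered, min_fz=min_fz)
    above = cop.valid
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], above.view(np.int8), [0]))))
    windows: List[StanceWindow] = []
    for a, b in zip(edges[::2], edges[1::2]):
        if (b - a) / plate.rate < min_duration:
            continue
        windows.append(StanceWindow(
            plate_id=plate.plate_id, start=int(a), stop=int(b),
            cop=cop.xy[a:b].copy(), fz=cop.fz[a:b].copy(), rate=plate.rate,
        ))
    return windows


def cop_path_length(
    window: StanceWindow,
    frame: FootFrame,
    travel_axis: np.ndarray,
) -> float:
    """Foot-normalised COP path length P during one stance.

    P = (max − min of the COP projected on the unit travel axis) divided
    by the foot length; invariant to lab translation and, when the axis
    transforms with the data, rotation. P < 1 for a COP confined to the
    foot.
    """
    if frame.foot_length <= 0:
        raise ValueError("foot length must be positive")
    axis = np.asarray(travel_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("travel axis must be a nonzero vector")
    axis = axis / nrm
    proj = window.cop @ axis
    return float((proj.max() - proj.min()) / frame.foot_length)


def travel_axis_from_markers(
    markers: MarkerTrajectory, heel_label: str
) -> np.ndarray:
    """Unit direction of net heel-marker floor displacement over a trial."""
    heel = markers.get(heel_label)
    idx = markers.index(heel_label)
    valid = np.flatnonzero(markers.mask[:, idx])
    if valid.size < 2:
        raise ValueError("heel marker not visible long enough")
    disp = heel[valid[-1], :2] - heel[valid[0], :2]
    nrm = np.linalg.norm(disp)
    if nrm == 0:
        return np.array([0.0, 1.0])
    return disp / nrm


def stride_speed(markers: MarkerTrajectory, heel_label: str,
                 window: Optional[StanceWindow] = None) -> float:
    """Mean horizontal heel-marker speed over one full stride.

    Net floor-plane displacement of the heel marker over the record
    divided by its duration; invariant to lab-frame rotation.
    """
    heel = markers.get(heel_label)
    idx = markers.index(heel_label)
    valid = np.flatnonzero(markers.mask[:, idx])
    if valid.size < 2:
        raise ValueError("heel marker not visible long enough")
    disp = np.linalg.norm(heel[valid[-1], :2] - heel[valid[0], :2])
    dt = (valid[-1] - valid[0]) / markers.rate
    return float(disp / dt)
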