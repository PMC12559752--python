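"""Centre-of-pressure computation, filtering and flat-foot selection.

The fBOS sample set is the COP restricted to stretches where the foot is
demonstrably flat and well loaded: runs of at least ``min_run``
consecutive samples carrying at least ``min_weight_share`` of body
weight, with heel and toe-tip markers at their quiet-standing height and
nearly motionless, after discarding the largest ``transition_exclusion``
fraction of frame-to-frame COP displacements.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.signal

from .trial import ForcePlateRecord, MarkerTrajectory, foot_marker_labels


def lowpass_zero_phase(
    signal: np.ndarray, cutoff: float, rate: float, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    Filters along axis 0. The effective magnitude response is the square
    of a Butterworth of the given order; phase lag is zero and DC gain is
    exactly 1. ``cutoff`` must lie below the Nyquist frequency.
    """
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be in (0, Nyquist={nyq} Hz)")
    b, a = scipy.signal.butter(order, cutoff / nyq, btype="low")
    return scipy.signal.filtfilt(b, a, np.asarray(signal, dtype=float), axis=0)


@dataclass
class COPTrajectory:
    """Planar COP in the lab frame with the vertical force per sample.

    ``xy`` is NaN wherever ``valid`` is False (vertical force at or below
    the threshold used to compute it).
    """

    xy: np.ndarray          # (n, 2) lab-frame COP [m]
    fz: np.ndarray          # (n,) vertical force [N]
    valid: np.ndarray       # (n,) bool
    rate: float
    plate_id: str = "plate"

    @property
    def n_samples(self) -> int:
        return self.xy.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def compute_cop(plate: ForcePlateRecord, min_fz: float = 50.0) -> COPTrajectory:
    """COP from plate forces and moments; samples with Fz ≤ min_fz masked.

    For a surface-level plate origin: COPx = −My/Fz + ox and
    COPy = Mx/Fz + oy. For an origin ``origin_depth`` below the surface
    the horizontal-force lever terms are subtracted:
    COPx = (−My + Fx·d)/Fz + ox, COPy = (Mx + Fy·d)/Fz + oy.

    Returns an all-masked trajectory (with a warning) if no sample
    exceeds the threshold.
    """
    fz = plate.fz
    valid = fz > min_fz
    d = plate.origin_depth
    xy = np.full((plate.n_samples, 2), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (-plate.M[:, 1] + plate.F[:, 0] * d) / fz + plate.origin[0]
        y = (plate.M[:, 0] + plate.F[:, 1] * d) / fz + plate.origin[1]
    xy[valid, 0] = x[valid]
    xy[valid, 1] = y[valid]
    if not valid.any():
        warnings.warn(
            f"no sample on {plate.plate_id!r} exceeds Fz={min_fz} N; "
            "returning an empty COP trajectory",
            stacklevel=2,
        )
    return COPTrajectory(xy=xy, fz=fz.copy(), valid=valid,
                         rate=plate.rate, plate_id=plate.plate_id)


def downsample_to_markers(
    cop: COPTrajectory, marker_rate: float
) -> COPTrajectory:
    """Decimate a (pre-filtered) COP trajectory to the marker rate.

    Keeps every k-th sample with k = force_rate / marker_rate, which must
    be a whole number; output timestamps then coincide with the marker
    clock. The caller is responsible for having low-pass filtered the
    signal at or below half the marker rate first.
    """
    ratio = cop.rate / marker_rate
    k = int(round(ratio))
    if not np.isclose(ratio, k) or k < 1:
        raise ValueError(
            f"force rate {cop.rate} Hz is not an integer multiple of "
            f"marker rate {marker_rate} Hz"
        )
    return COPTrajectory(
        xy=cop.xy[::k].copy(),
        fz=cop.fz[::k].copy(),
        valid=cop.valid[::k].copy(),
        rate=marker_rate,
        plate_id=cop.plate_id,
    )


@dataclass
class SelectionCriteria:
    """Thresholds defining flat-foot, well-loaded COP samples.

    ``min_run`` is in samples at the marker rate (150 samples = 1 s at
    150 Hz). ``min_weight_share`` is the fraction of body weight the
    plate must carry. Foot-flatness is marker-based: heel and toe-tip
    height within ``flat_height_tol`` of their quiet-standing baseline
    and vertical speed below ``flat_velocity_tol`` (computed on marker
    height low-passed at ``flat_filter_cutoff``). ``transition_exclusion``
    is the fraction of the largest frame-to-frame COP displacements
    removed from the retained runs.
    """

    min_run: int = 150
    min_weight_share: float = 0.40
    flat_height_tol: float = 0.005       # m
    flat_velocity_tol: float = 0.02      # m/s
    transition_exclusion: float = 0.001
    min_fz: float = 50.0                 # N
    flat_filter_cutoff: float = 10.0     # Hz

    def __post_init__(self) -> None:
        if self.min_run <= 0 or self.min_weight_share <= 0:
            raise ValueError("min_run and min_weight_share must be positive")
        if not (0 <= self.transition_exclusion <= 0.05):
            raise ValueError("transition_exclusion must be in [0, 0.05]")
        if self.flat_height_tol <= 0 or self.flat_velocity_tol <= 0:
            raise ValueError("flatness tolerances must be positive")


@dataclass
class COPSegment:
    """A maximal run of COP samples satisfying all selection criteria."""

    xy: np.ndarray           # (n, 2) lab frame
    start: int               # first sample index into the marker-rate COP
    stop: int                # one past the last retained index
    kept: np.ndarray         # (n,) original sample indices (transition gaps removed)
    mean_weight_share: float


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def estimate_body_weight(
    plates, quiet_window: Tuple[float, float] = (0.5, 2.5)
) -> float:
    """Body weight [N] as mean total vertical force over a quiet window."""
    total = None
    for plate in plates:
        t = plate.time
        sel = (t >= quiet_window[0]) & (t < quiet_window[1])
        if not sel.any():
            raise ValueError(f"quiet window {quiet_window} is empty")
        fz = plate.fz[sel]
        total = fz if total is None else total + fz
    return float(total.mean())


def select_fbos_samples(
    cop: COPTrajectory,
    markers: MarkerTrajectory,
    side: str,
    body_weight: float,
    criteria: Optional[SelectionCriteria] = None,
    quiet_window: Tuple[float, float] = (0.0, 2.0),
) -> Tuple[List[COPSegment], Dict[str, object]]:
    """Select flat-foot, well-loaded COP runs for one foot.

    ``cop`` must already be filtered and down-sampled to the marker rate.
    Returns the retained segments together with a per-criterion rejection
    report (weight share is typically the dominant excluder). An empty
    list, not an exception, signals that nothing qualified.
    """
    criteria = criteria or SelectionCriteria()
    n = cop.n_samples
    if markers.n_samples < n:
        raise ValueError("marker record shorter than COP record")
    if not np.isclose(markers.rate, cop.rate):
        raise ValueError("COP must be down-sampled to the marker rate first")

    share = np.where(body_weight > 0, cop.fz / body_weight, 0.0)
    ok_load = cop.valid & (share >= criteria.min_weight_share)

    # marker-based foot-flat test on heel and toe tip
    labels = foot_marker_labels(side)
    flat = np.ones(n, dtype=bool)
    t = markers.time[:n]
    in_quiet = (t >= quiet_window[0]) & (t < quiet_window[1])
    if not in_quiet.any():
        raise ValueError(f"quiet window {quiet_window} contains no samples")
    for name in ("heel", "toe_tip"):
        label = labels[0][:2] + name  # e.g. "L_" + name
        idx = markers.index(label)
        z = markers.positions[:n, idx, 2]
        if criteria.flat_filter_cutoff < markers.rate / 2:
            z_f = lowpass_zero_phase(z, criteria.flat_filter_cutoff, markers.rate)
        else:
            z_f = z
        baseline = z_f[in_quiet].mean()
        vz = np.gradient(z_f, 1.0 / markers.rate)
        flat &= np.abs(z_f - baseline) <= criteria.flat_height_tol
        flat &= np.abs(vz) < criteria.flat_velocity_tol

    joint = ok_load & flat
    runs = [(a, b) for a, b in _runs(joint) if b - a >= criteria.min_run]

    report: Dict[str, object] = {
        "n_samples": int(n),
        "rejected_load": int(n - ok_load.sum()),
        "rejected_flat": int(n - flat.sum()),
        "rejected_short_run": int(joint.sum() - sum(b - a for a, b in runs)),
        "transition_removed": 0,
        "transition_threshold": None,
        "transition_scope": "per-foot",
    }
    if not runs:
        return [], report

    # largest-transition exclusion over the retained runs
    keep = np.zeros(n, dtype=bool)
    for a, b in runs:
        keep[a:b] = True
    if criteria.transition_exclusion > 0:
        disps, targets = [], []
        for a, b in runs:
            d = np.linalg.norm(np.diff(cop.xy[a:b], axis=0), axis=1)
            disps.append(d)
            targets.append(np.arange(a + 1, b))  # sample after each step
        disps = np.concatenate(disps)
        targets = np.concatenate(targets)
        if disps.size:
            thresh = float(np.quantile(disps, 1.0 - criteria.transition_exclusion))
            bad = targets[disps > thresh]
            keep[bad] = False
            report["transition_removed"] = int(bad.size)
            report["transition_threshold"] = thresh

    # re-split and enforce min_run again ("consecutive" taken literally)
    segments: List[COPSegment] = []
    for a, b in _runs(keep):
        if b - a < criteria.min_run:
            continue
        idx = np.arange(a, b)
        segments.append(
            COPSegment(
                xy=cop.xy[a:b].copy(),
                start=int(a),
                stop=int(b),
                kept=idx,
                mean_weight_share=float(share[a:b].mean()),
            )
        )
    report["n_segments"] = len(segments)
    report["retained_samples"] = int(sum(s.stop - s.start for s in segments))
    return segments, report
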