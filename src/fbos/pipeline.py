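"""End-to-end convenience: raw trial → participant fBOS.

Chains the processing stages exactly as the analysis prescribes: COP
from plate forces/moments above 50 N, zero-phase second-order low-pass
at half the marker rate, decimation to the marker clock, flat-foot
high-load segment selection per foot, per-foot convex hulls, right-foot
reflection, arc-length averaging, metrics and normalisation.
"""
from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .cop import (SelectionCriteria, compute_cop, downsample_to_markers,
                  estimate_body_weight, lowpass_zero_phase,
                  select_fbos_samples)
from .foot import fit_foot_frame
from .model import ParticipantFBOS, extract_participant_fbos
from .trial import ForcePlateRecord, MarkerTrajectory


def process_standing_trial(
    markers: MarkerTrajectory,
    plates: Dict[str, ForcePlateRecord],
    criteria: Optional[SelectionCriteria] = None,
    quiet_window: Tuple[float, float] = (0.0, 2.0),
    body_weight: Optional[float] = None,
    n_points: int = 100,
) -> Tuple[ParticipantFBOS, Dict[str, dict]]:
    """Full standing-trial pipeline for one participant.

    ``plates`` maps "left"/"right" to that foot's plate. Body weight
    defaults to the mean total vertical force over the quiet window.
    Returns the participant fBOS and the per-foot selection reports.
    """
    criteria = criteria or SelectionCriteria()
    if body_weight is None:
        body_weight = estimate_body_weight(plates.values(),
                                           quiet_window=quiet_window)
    segments = {}
    frames = {}
    reports: Dict[str, dict] = {}
    for side, plate in plates.items():
        cop = compute_cop(plate, min_fz=criteria.min_fz)
        cutoff = markers.rate / 2.0
        filtered = cop
        if cutoff < plate.rate / 2.0 and cop.valid.any():
            xy = cop.xy
            if not cop.valid.all():
                # bridge sub-threshold gaps before filtering; these
                # samples stay masked and are rejected downstream
                idx = np.arange(cop.n_samples)
                xy = xy.copy()
                for col in range(2):
                    xy[:, col] = np.interp(idx, idx[cop.valid],
                                           xy[cop.valid, col])
            xy = lowpass_zero_phase(xy, cutoff, plate.rate)
            filtered = type(cop)(xy=xy, fz=cop.fz, valid=cop.valid,
                                 rate=cop.rate, plate_id=cop.plate_id)
        down = downsample_to_markers(filtered, markers.rate)
        frames[side] = fit_foot_frame(markers, side, quiet_window=quiet_window)
        segs, report = select_fbos_samples(
            down, markers, side, body_weight, criteria,
            quiet_window=quiet_window)
        segments[side] = segs
        reports[side] = report
    participant = extract_participant_fbos(
        segments.get("left", []), segments.get("right", []),
        frames.get("left"), frames.get("right"), n_points=n_points)
    return participant, reports
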