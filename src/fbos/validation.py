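"""Synthetic-recovery experiments for pipeline validation.

These run the full extraction pipeline on generated recordings with
known ground truth and report recovery errors; they are what the test
suite and the reproduction script use to quantify accuracy in the
absence of deposited raw recordings.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .foot import fit_foot_frame
from .pipeline import process_standing_trial
from .synthetic import (WalkingStrideConfig, generate_walking_stride,
                        standing_config_for_participant)
from .walking import cop_path_length, detect_stance, travel_axis_from_markers


def standing_recovery_experiment(
    n_participants: int = 200,
    seed: int = 0,
    duration: float = 60.0,
) -> pd.DataFrame:
    """Recover known per-participant fBOS geometry through the pipeline.

    Each participant gets a true fBOS polygon with area ratio drawn from
    U(0.10, 0.33) and normalised length from U(0.45, 0.75) on a foot of
    length N(0.27, 0.02) m, then a full standing trial at default noise
    is generated and processed end to end. Returns one row per
    participant with true and recovered area ratio, length and width.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        while True:
            area = rng.uniform(0.10, 0.33)
            length = rng.uniform(0.45, 0.75)
            if 0.12 < area / length < 0.62:
                break
        foot_length = float(np.clip(rng.normal(0.27, 0.02), 0.22, 0.33))
        cfg = standing_config_for_participant(
            area_ratio_target=area, norm_length=length,
            seed=int(rng.integers(2 ** 31)), foot_length=foot_length,
            duration=duration)
        trial = generate_standing_trial_cached(cfg)
        participant, _ = process_standing_trial(trial.markers, trial.plates)
        m = participant.metrics
        rows.append({
            "true_area_ratio": area, "area_ratio": m.area_ratio,
            "true_norm_length": length, "norm_length": m.norm_length,
            "true_norm_width": area / length, "norm_width": m.norm_width,
            "foot_length": foot_length,
        })
    df = pd.DataFrame(rows)
    for k in ("area_ratio", "norm_length", "norm_width"):
        df[f"err_{k}"] = df[k] - df[f"true_{k}"]
    return df


def generate_standing_trial_cached(cfg):
    # indirection point for tests that want to monkeypatch generation
    from .synthetic import generate_standing_trial
    return generate_standing_trial(cfg)


def walking_recovery_experiment(
    n_strides: int = 50,
    seed: int = 0,
    target_path_norm: Optional[float] = None,
) -> pd.DataFrame:
    """Recover the normalised COP path length of noisy synthetic strides.

    Targets are drawn from U(0.40, 0.80) unless fixed; headings vary.
    Returns per-stride truth, estimate and error.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_strides):
        target = (target_path_norm if target_path_norm is not None
                  else float(rng.uniform(0.40, 0.80)))
        cfg = WalkingStrideConfig(
            seed=int(rng.integers(2 ** 31)), target_path_norm=target,
            heading_deg=float(rng.uniform(0, 360)),
            stride_speed=float(rng.uniform(0.82, 1.63)))
        stride = generate_walking_stride(cfg)
        windows = detect_stance(stride.plate)
        frame = fit_foot_frame(stride.markers, cfg.side,
                               quiet_window=stride.truth["stance_interval"])
        axis = travel_axis_from_markers(stride.markers,
                                        f"{'L' if cfg.side == 'left' else 'R'}_heel")
        p = cop_path_length(windows[0], frame, axis)
        rows.append({"true_path_norm": target, "path_norm": p,
                     "err": p - target})
    return pd.DataFrame(rows)
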