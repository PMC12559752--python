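"""Synthetic standing trials, walking strides and participant cohorts.

The generator produces physically consistent recordings with known
ground truth so every downstream stage is testable without any lab data:

* standing trials — slow circular COP loops confined to a configurable
  true fBOS polygon, weight share oscillating between the configured
  bounds, optional heel/toe-lift contamination, marker noise and COP
  tremor; plate moments are synthesised from the COP and vertical force
  so that :func:`fbos.cop.compute_cop` inverts them exactly;
* walking strides — single-foot stance with a monotone heel→forefoot COP
  progression of known normalised extent;
* cohorts — per-participant outcome tables whose group medians, ranges
  and rank-correlation structure follow a single-latent-factor model
  with configurable targets.

The COP loop uses support-style boundary sampling: a slowly rotating ray
from the polygon centroid whose radius factor repeatedly plateaus at 1,
so the convex hull of the flat-foot samples converges to the true
polygon.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from scipy.special import expit, logit, ndtr, ndtri

from .foot import FootFrame
from .model import FBOSPolygon, METRIC, reflect_ml
from .trial import (FOOT_MARKERS, ForcePlateRecord, MarkerTrajectory,
                    SyntheticTrial, foot_marker_labels)

# ---------------------------------------------------------------------------
# foot layout
# ---------------------------------------------------------------------------

#: foot-frame marker layout as fractions of (W, L); left-foot convention
#: (little-toe/MTP5 side at negative x), z heights in metres (shoe surface)
_LAYOUT = {
    "heel": (0.0, 0.0, 0.02),
    "lat_ankle": (-0.30, 0.20, 0.07),
    "mtp5": (-0.60, 0.72, 0.02),
    "toe_tip": (0.0, 1.0, 0.02),
    "mtp1": (0.40, 0.72, 0.02),
    "med_ankle": (0.30, 0.20, 0.07),
}


def foot_layout(foot_length: float, foot_width: float,
                side: str = "left") -> Dict[str, np.ndarray]:
    """Foot-frame marker positions (x, y, z) for one foot in metres.

    The hexagon through the six floor projections spans exactly
    ``foot_length`` anterior–posterior and ``foot_width`` mediolateral.
    Right-foot layouts are the mediolateral mirror of left ones.
    """
    s = -1.0 if side == "right" else 1.0
    return {
        name: np.array([s * fx * foot_width, fy * foot_length, z])
        for name, (fx, fy, z) in _LAYOUT.items()
    }


def footprint_vertices(foot_length: float, foot_width: float,
                       side: str = "left") -> np.ndarray:
    """Floor projections of the six markers in boundary order."""
    lay = foot_layout(foot_length, foot_width, side)
    order = ("heel", "lat_ankle", "mtp5", "toe_tip", "mtp1", "med_ankle")
    return np.array([lay[name][:2] for name in order])


def scaled_footprint_fbos(foot_length: float, foot_width: float,
                          norm_width: float, norm_length: float) -> FBOSPolygon:
    """A true fBOS polygon: the footprint hexagon scaled about its centroid.

    Axis scales equal the target normalised width and length, so the
    resulting polygon has area ratio ``norm_width * norm_length`` and
    sits strictly inside the footprint for scales < 1 (left convention).
    """
    if not (0 < norm_width < 1 and 0 < norm_length < 1):
        raise ValueError("normalised scales must lie in (0, 1)")
    fp = footprint_vertices(foot_length, foot_width)
    c = np.asarray(sgeom.Polygon(fp).centroid.coords[0])
    v = c + (fp - c) * np.array([norm_width, norm_length])
    return FBOSPolygon(v[::-1] if _signed_area(v) < 0 else v, units=METRIC,
                       side="left")


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return float((np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


# ---------------------------------------------------------------------------
# standing trials
# ---------------------------------------------------------------------------


@dataclass
class LiftEvent:
    """A brief heel or toe lift contaminating one foot."""

    start: float           # s
    duration: float        # s
    side: str              # "left" / "right"
    marker: str = "heel"   # "heel" or "toe_tip"
    height: float = 0.03   # peak marker rise [m]


@dataclass
class StandingTrialConfig:
    """Conditions of one synthetic standing fBOS trial.

    Defaults emulate the study protocol: 150 Hz markers, 900 Hz plates,
    slow circular COP loops reaching the true fBOS boundary, weight
    share oscillating between 40 and 60% of body weight. Noise defaults
    (0.5 mm COP tremor, 0.5 mm marker noise) reflect research-grade
    plates under high load and optical capture residuals.
    """

    duration: float = 60.0
    quiet_duration: float = 3.0
    marker_rate: float = 150.0
    force_rate: float = 900.0
    body_weight: float = 700.0
    true_fbos: Optional[FBOSPolygon] = None       # left convention, metres
    weight_share_range: Tuple[float, float] = (0.40, 0.60)
    lift_events: Sequence[LiftEvent] = ()
    marker_noise_sd: float = 0.0005
    cop_tremor_sd: float = 0.0005
    foot_length: float = 0.27
    foot_width: float = 0.09
    stance_width: float = 0.30     # heel-to-heel mediolateral distance
    loop_freq: float = 0.10        # COP loop rotation [Hz]
    # boundary-reach modulation; a golden-ratio multiple of the loop rate
    # so successive boundary plateaus fall at well-spread angles instead
    # of revisiting the same ones
    radius_freq: float = 0.10 * 2.6180339887
    share_freq: float = 0.05       # weight-share oscillation [Hz]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.weight_share_range
        if not (0 < lo < hi < 1):
            raise ValueError("weight_share_range must be within (0, 1)")
        ratio = self.force_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("force_rate must be an integer multiple of marker_rate")
        if self.true_fbos is None:
            self.true_fbos = scaled_footprint_fbos(
                self.foot_length, self.foot_width, 0.33, 0.60)
        fp = sgeom.Polygon(footprint_vertices(self.foot_length, self.foot_width))
        if not fp.buffer(1e-9).contains(sgeom.Polygon(self.true_fbos.vertices)):
            raise ValueError(
                "true_fbos extends outside the footprint hexagon; "
                "a flat foot could never reach it"
            )


def _ray_boundary(vertices: np.ndarray, centre: np.ndarray,
                  theta: np.ndarray) -> np.ndarray:
    """Boundary intersections of rays from an interior point (vectorised).

    For a convex polygon and interior ``centre``, returns the boundary
    point along direction ``theta`` for every angle.
    """
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)         # (n, 2)
    p = vertices                                                 # (E, 2)
    q = np.roll(vertices, -1, axis=0)
    e = q - p                                                    # (E, 2)
    rel = p[None, :, :] - centre[None, None, :]                  # (1, E, 2)
    cross_de = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    cross_rel_e = rel[..., 0] * e[None, :, 1] - rel[..., 1] * e[None, :, 0]
    cross_rel_d = rel[..., 0] * d[:, None, 1] - rel[..., 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_rel_e / cross_de           # distance along ray
        u = cross_rel_d / cross_de           # position along edge
    ok = (t > 0) & (u >= -1e-12) & (u <= 1 + 1e-12)
    t = np.where(ok, t, np.inf)
    tmin = t.min(axis=1)
    return centre[None, :] + d * tmin[:, None]


def _loop_cop(cfg: StandingTrialConfig, truth: FBOSPolygon,
              t: np.ndarray) -> np.ndarray:
    """Noise-free foot-frame COP: centroid-anchored rotating-ray loops."""
    c = np.asarray(sgeom.Polygon(truth.vertices).centroid.coords[0])
    tt = np.clip(t - cfg.quiet_duration, 0.0, None)
    theta = 2 * np.pi * cfg.loop_freq * tt
    # radius factor: clipped raised sinusoid, 0 at loop start, plateauing
    # at exactly 1 over ~38% of each modulation cycle so the rotating ray
    # traces the true boundary densely
    raw = 1.08 * (0.5 + 0.5 * np.sin(2 * np.pi * cfg.radius_freq * tt - np.pi / 2))
    factor = np.clip(raw, 0.0, 1.0)
    factor[tt <= 0] = 0.0
    boundary = _ray_boundary(truth.vertices, c, theta)
    return c[None, :] + factor[:, None] * (boundary - c[None, :])


def generate_standing_trial(config: StandingTrialConfig) -> SyntheticTrial:
    """Generate one two-plate standing trial with known ground truth.

    Identical configs (including seed) produce bit-identical trials.
    ``truth`` carries per-foot true polygons, noise-free COP at force
    rate, flat-foot masks at marker rate, noise-free foot frames and the
    true body weight.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_f = int(round(cfg.duration * cfg.force_rate))
    n_m = int(round(cfg.duration * cfg.marker_rate))
    t_f = np.arange(n_f) / cfg.force_rate
    t_m = np.arange(n_m) / cfg.marker_rate

    lo, hi = cfg.weight_share_range
    mid, amp = (lo + hi) / 2, (hi - lo) / 2
    share_left = np.where(
        t_f < cfg.quiet_duration, mid,
        mid + amp * np.sin(2 * np.pi * cfg.share_freq * (t_f - cfg.quiet_duration)),
    )

    # lift events: raised-cosine weight-share dips and marker-height bumps
    def lift_weight(tvec: np.ndarray, ev: LiftEvent) -> np.ndarray:
        w = np.zeros_like(tvec)
        sel = (tvec >= ev.start) & (tvec <= ev.start + ev.duration)
        w[sel] = 0.5 * (1 - np.cos(2 * np.pi * (tvec[sel] - ev.start) / ev.duration))
        return w

    for ev in cfg.lift_events:
        w = lift_weight(t_f, ev)
        if ev.side == "left":
            share_left = share_left * (1 - 0.45 * w)
        else:
            share_right = (1 - share_left) * (1 - 0.45 * w)
            share_left = 1 - share_right

    heels = {"left": np.array([-cfg.stance_width / 2, 0.0]),
             "right": np.array([cfg.stance_width / 2, 0.0])}
    truth_polys = {"left": cfg.true_fbos, "right": reflect_ml(cfg.true_fbos)}
    plates: Dict[str, ForcePlateRecord] = {}
    truth: Dict[str, object] = {
        "body_weight": cfg.body_weight,
        "fbos": {}, "cop_noise_free": {}, "flat_mask": {}, "frames": {},
    }

    labels: List[str] = []
    marker_cols: List[np.ndarray] = []
    for side in ("left", "right"):
        share = share_left if side == "left" else 1 - share_left
        fz = share * cfg.body_weight
        truth_poly = truth_polys[side]
        cop_foot = _loop_cop(cfg, truth_poly, t_f)
        # both feet point along +y; frame axes are lab-aligned
        cop_lab = heels[side][None, :] + cop_foot
        cop_meas = cop_lab + rng.normal(0, cfg.cop_tremor_sd, cop_lab.shape) \
            if cfg.cop_tremor_sd > 0 else cop_lab.copy()
        origin = np.array([heels[side][0], 0.10, 0.0])
        M = np.zeros((n_f, 3))
        M[:, 0] = (cop_meas[:, 1] - origin[1]) * fz
        M[:, 1] = -(cop_meas[:, 0] - origin[0]) * fz
        F = np.zeros((n_f, 3))
        F[:, 2] = fz
        plates[side] = ForcePlateRecord(F=F, M=M, rate=cfg.force_rate,
                                        origin=origin, plate_id=side)

        layout = foot_layout(cfg.foot_length, cfg.foot_width, side)
        flat = np.ones(n_m, dtype=bool)
        for name in FOOT_MARKERS:
            base = layout[name]
            pos = np.tile(base, (n_m, 1))
            pos[:, 0] += heels[side][0]
            pos[:, 1] += heels[side][1]
            for ev in cfg.lift_events:
                if ev.side != side:
                    continue
                w_m = lift_weight(t_m, ev)
                if name == ev.marker:
                    pos[:, 2] += ev.height * w_m
                flat &= w_m <= 0
            if cfg.marker_noise_sd > 0:
                pos = pos + rng.normal(0, cfg.marker_noise_sd, pos.shape)
            marker_cols.append(pos)
        labels.extend(foot_marker_labels(side))

        lay2 = {k: v[:2] - np.array([0.0, 0.0]) for k, v in layout.items()}
        frame = FootFrame(
            side=side,
            origin=heels[side],
            anterior=np.array([0.0, 1.0]),
            lateral=np.array([1.0, 0.0]),
            foot_length=cfg.foot_length,
            foot_width=cfg.foot_width,
            marker_foot=lay2,
        )
        truth["fbos"][side] = truth_poly
        truth["cop_noise_free"][side] = cop_lab
        truth["flat_mask"][side] = flat
        truth["frames"][side] = frame

    positions = np.stack(marker_cols, axis=1)
    markers = MarkerTrajectory(labels=labels, positions=positions,
                               rate=cfg.marker_rate)
    return SyntheticTrial(markers=markers, plates=plates, truth=truth)


# ---------------------------------------------------------------------------
# walking strides
# ---------------------------------------------------------------------------


@dataclass
class WalkingStrideConfig:
    """Conditions of one synthetic walking stride on one plate."""

    stance_duration: float = 0.7
    target_path_norm: float = 0.60   # (max−min AP COP) / foot length
    foot_length: float = 0.27
    foot_width: float = 0.09
    stride_speed: float = 1.2        # m/s
    body_weight: float = 700.0
    force_rate: float = 900.0
    marker_rate: float = 150.0
    cop_noise_sd: float = 0.001
    marker_noise_sd: float = 0.0005
    lead: float = 0.3                # zero-force padding before/after stance [s]
    heading_deg: float = 0.0         # travel direction in the lab floor plane
    side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be positive")
        if not (0 <= self.target_path_norm < 1):
            raise ValueError(
                "target normalised path length must be in [0, 1): the COP "
                "cannot travel farther than the foot is long"
            )


@dataclass
class SyntheticStride:
    """A generated stride with its ground truth."""

    markers: MarkerTrajectory
    plate: ForcePlateRecord
    truth: Dict[str, object]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3 - 2 * u)


def generate_walking_stride(config: WalkingStrideConfig) -> SyntheticStride:
    """Single-foot stance: Fz rises above and falls below 50 N once and
    the noise-free COP progresses monotonically from the heel region to
    the forefoot, spanning exactly the target AP extent."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    total = cfg.stance_duration + 2 * cfg.lead
    n_f = int(round(total * cfg.force_rate))
    n_m = int(round(total * cfg.marker_rate))
    t_f = np.arange(n_f) / cfg.force_rate
    t_m = np.arange(n_m) / cfg.marker_rate
    u_f = (t_f - cfg.lead) / cfg.stance_duration

    h = np.deg2rad(cfg.heading_deg)
    fwd = np.array([-np.sin(h), np.cos(h)])       # travel direction
    rot3 = np.array([[np.cos(h), -np.sin(h), 0],
                     [np.sin(h), np.cos(h), 0],
                     [0, 0, 1]])

    in_stance = (u_f >= 0) & (u_f <= 1)
    fz = np.where(in_stance, cfg.body_weight * np.sin(np.pi * np.clip(u_f, 0, 1)),
                  0.0)

    L = cfg.foot_length
    y0 = (1 - cfg.target_path_norm) * L / 2.0
    cop_y = y0 + cfg.target_path_norm * L * _smoothstep(u_f)
    cop_foot = np.stack([np.zeros(n_f), cop_y], axis=1)
    cop_lab = (rot3[:2, :2] @ cop_foot.T).T       # heel at lab origin
    cop_meas = cop_lab + rng.normal(0, cfg.cop_noise_sd, cop_lab.shape) \
        if cfg.cop_noise_sd > 0 else cop_lab.copy()

    origin = rot3[:2, :2] @ np.array([0.0, L / 2])
    F = np.zeros((n_f, 3))
    F[:, 2] = fz
    M = np.zeros((n_f, 3))
    M[:, 0] = (cop_meas[:, 1] - origin[1]) * fz
    M[:, 1] = -(cop_meas[:, 0] - origin[0]) * fz
    plate = ForcePlateRecord(F=F, M=M, rate=cfg.force_rate,
                             origin=np.array([origin[0], origin[1], 0.0]),
                             plate_id="stance")

    # markers: foot planted during stance, heel advances one stride length
    # over the sampled record via a smooth swing after toe-off
    t_last = (n_m - 1) / cfg.marker_rate
    stride_length = cfg.stride_speed * t_last
    swing_start = cfg.lead + cfg.stance_duration
    prog = _smoothstep((t_m - swing_start) / max(t_last - swing_start, 1e-9))
    layout = foot_layout(cfg.foot_length, cfg.foot_width, cfg.side)
    labels = list(foot_marker_labels(cfg.side))
    cols = []
    for name in FOOT_MARKERS:
        base = layout[name]
        pos = np.tile(rot3 @ base, (n_m, 1))
        pos[:, 0] += fwd[0] * stride_length * prog
        pos[:, 1] += fwd[1] * stride_length * prog
        pos[:, 2] += 0.05 * np.sin(np.pi * prog) ** 2   # swing foot clearance
        if cfg.marker_noise_sd > 0:
            pos = pos + rng.normal(0, cfg.marker_noise_sd, pos.shape)
        cols.append(pos)
    markers = MarkerTrajectory(labels=labels, positions=np.stack(cols, axis=1),
                               rate=cfg.marker_rate)

    truth = {
        "path_norm": cfg.target_path_norm,
        "stride_speed": cfg.stride_speed,
        "foot_length": L,
        "travel_axis": fwd,
        "stance_interval": (cfg.lead, cfg.lead + cfg.stance_duration),
        "cop_noise_free": cop_lab,
    }
    return SyntheticStride(markers=markers, plate=plate, truth=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

GROUPS = ("young", "middle", "old")

#: per-group (median, low, high) of each fBOS outcome; the defaults
#: emulate the observed age-group structure (areas 22/22/13% of the
#: footprint, lengths 65/61/53% of foot length, widths 35/35/21% of foot
#: width, toe distances 21/21/28%, heel distances 17/18/20%)
DEFAULT_METRIC_DISTRIBUTIONS: Dict[str, Dict[str, Tuple[float, float, float]]] = {
    "area_ratio": {"young": (0.22, 0.09, 0.36), "middle": (0.22, 0.17, 0.29),
                   "old": (0.13, 0.06, 0.28)},
    "norm_length": {"young": (0.65, 0.49, 0.81), "middle": (0.61, 0.50, 0.65),
                    "old": (0.53, 0.22, 0.72)},
    "norm_width": {"young": (0.35, 0.21, 0.62), "middle": (0.35, 0.24, 0.39),
                   "old": (0.21, 0.12, 0.40)},
    "d_toe": {"young": (0.21, 0.10, 0.36), "middle": (0.21, 0.16, 0.30),
              "old": (0.28, 0.16, 0.43)},
    "d_heel": {"young": (0.17, 0.09, 0.29), "middle": (0.18, 0.14, 0.28),
               "old": (0.20, 0.13, 0.39)},
    "d_lat_ankle": {g: (0.10, 0.03, 0.20) for g in GROUPS},
    "d_little_toe": {g: (0.08, 0.02, 0.18) for g in GROUPS},
}

DEFAULT_AGE_RANGES = {"young": (21, 39), "middle": (41, 63), "old": (66, 89)}

#: loadings of each outcome's Gaussian score on the latent balance
#: capacity (positive = larger with better capacity)
DEFAULT_LOADINGS = {
    "norm_length": 0.90,
    "norm_width": 0.70,
    "d_toe": -0.80,
    "d_heel": -0.60,
    "d_lat_ankle": 0.0,
    "d_little_toe": 0.0,
}


class InfeasibleCorrelationError(ValueError):
    """The requested correlation targets exceed the single-factor model."""


@dataclass
class CohortConfig:
    """Latent-factor cohort model with configurable rank-correlation targets.

    Each participant carries a standard-normal latent balance capacity
    ``u``; the normalised fBOS area is a strictly monotone per-group map
    of ``u`` so group medians and ranges hit their configured targets.
    Other outcomes load on ``u`` through a Gaussian copula; Spearman/
    Kendall targets are converted to copula correlations via
    r = 2·sin(πρ/6) and r = sin(πτ/2).

    ``age_area_coupling`` adds a within-group dependence of ``u`` on the
    (reversed) age percentile. With the default group-level area
    distributions the between-group differences alone already induce a
    cohort-wide Spearman(age, area) near ``target_spearman_age_area``
    (checked by simulation), so the default coupling is 0; raise it to
    steepen the age effect inside groups.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"young": 38, "middle": 14, "old": 34})
    metric_distributions: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_METRIC_DISTRIBUTIONS.items()})
    age_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_RANGES))
    target_spearman_age_area: float = -0.52
    age_area_coupling: float = 0.0      # see class docstring
    tau_area_sppb: float = 0.28
    tau_area_gait_speed: float = 0.25
    tau_area_sit_to_stand: float = 0.0
    tau_area_fes: float = 0.0
    spearman_length_walking_p: float = 0.49
    tau_walking_p_stride_speed: float = 0.0
    frailty_coupling: float = 0.35
    frailty_counts: Tuple[int, int, int, int] = (7, 13, 10, 4)  # levels 1..4
    female_fraction: Dict[str, float] = field(
        default_factory=lambda: {"young": 16 / 38, "middle": 6 / 14,
                                 "old": 22 / 34})
    spread: float = 1.1                 # steepness of the bounded quantile maps
    n_walking_missing: int = 1
    n_barefoot: Dict[str, int] = field(
        default_factory=lambda: {"young": 0, "middle": 8, "old": 3})
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")


def _bounded_map(z: np.ndarray, med: float, lo: float, hi: float,
                 spread: float) -> np.ndarray:
    """Strictly monotone map of a standard-normal score into (lo, hi)
    with median ``med``."""
    if not (lo < med < hi):
        raise ValueError(f"need lo < median < hi, got {(lo, med, hi)}")
    c = logit((med - lo) / (hi - lo))
    return lo + (hi - lo) * expit(spread * z + c)


def _loading_spearman(rho: float) -> float:
    if not -1.0 <= rho <= 1.0:
        raise InfeasibleCorrelationError(
            f"Spearman target {rho} lies outside [-1, 1]")
    return 2.0 * np.sin(np.pi * rho / 6.0)


def _loading_kendall(tau: float) -> float:
    if not -1.0 <= tau <= 1.0:
        raise InfeasibleCorrelationError(
            f"Kendall target {tau} lies outside [-1, 1]")
    return float(np.sin(np.pi * tau / 2.0))


def _check_loading(r: float, what: str) -> float:
    if not -1.0 <= r <= 1.0:
        raise InfeasibleCorrelationError(
            f"target for {what} implies copula loading {r:.3f} outside [-1, 1]; "
            "the latent covariance would not be positive definite"
        )
    return float(r)


def generate_cohort(config: Optional[CohortConfig] = None
                    ) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Generate a participant outcome table with known latent structure.

    Returns the cohort table (one row per participant) and a dict of the
    true latent parameters (per-participant capacity, loadings used).
    Group-wise medians converge to the configured targets and induced
    rank correlations to the configured values as n grows.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    rows: List[dict] = []
    latents: List[float] = []

    r_sppb = _check_loading(_loading_kendall(cfg.tau_area_sppb), "area~SPPB")
    r_gait = _check_loading(_loading_kendall(cfg.tau_area_gait_speed),
                            "area~gait speed")
    r_sts = _check_loading(_loading_kendall(cfg.tau_area_sit_to_stand),
                           "area~sit-to-stand")
    r_fes = _check_loading(_loading_kendall(cfg.tau_area_fes), "area~FES-I")
    r_walk = _check_loading(_loading_spearman(cfg.spearman_length_walking_p),
                            "length~walking P")

    pid = 0
    for g in GROUPS:
        n = cfg.n_per_group.get(g, 0)
        if n == 0:
            continue
        a_lo, a_hi = cfg.age_ranges[g]
        age = rng.uniform(a_lo, a_hi, n)
        # within-group age percentile as a normal score (mid-ranks)
        pct = (pd.Series(age).rank().to_numpy() - 0.5) / n
        z_age = ndtri(pct)
        q = cfg.age_area_coupling
        u = -q * z_age + np.sqrt(max(1 - q * q, 0.0)) * rng.standard_normal(n)

        def score(r: float) -> np.ndarray:
            return r * u + np.sqrt(max(1 - r * r, 0.0)) * rng.standard_normal(n)

        vals: Dict[str, np.ndarray] = {}
        for metric, per_group in cfg.metric_distributions.items():
            med, lo, hi = per_group[g]
            loading = 1.0 if metric == "area_ratio" else DEFAULT_LOADINGS.get(
                metric, 0.0)
            z = u if metric == "area_ratio" else score(loading)
            vals[metric] = _bounded_map(z, med, lo, hi, cfg.spread)

        female = rng.random(n) < cfg.female_fraction.get(g, 0.5)
        shoe = rng.normal({"young": 0.27, "middle": 0.30, "old": 0.27}[g],
                          0.02, n)

        if g == "old":
            sppb = np.clip(np.round(
                _bounded_map(score(r_sppb), 10.0, 5.5, 12.49, cfg.spread)),
                0, 12).astype(int)
            gait_speed = _bounded_map(score(r_gait), 1.05, 0.55, 1.60, cfg.spread)
            sts = _bounded_map(score(-r_sts), 12.0, 7.0, 25.0, cfg.spread)
            fes = np.clip(np.round(
                _bounded_map(score(-r_fes), 8.0, 6.51, 20.0, cfg.spread)),
                7, 28).astype(int)
            # frailty: exact level counts, ordered by a noisy reversed capacity
            counts = np.array(cfg.frailty_counts, dtype=float)
            counts = np.round(counts / counts.sum() * n).astype(int)
            counts[0] += n - counts.sum()
            w = -cfg.frailty_coupling * u + np.sqrt(
                1 - cfg.frailty_coupling ** 2) * rng.standard_normal(n)
            order = np.argsort(w)   # fittest first
            frailty = np.empty(n, dtype=int)
            bounds = np.cumsum(counts)
            frailty[order[:bounds[0]]] = 1
            for lvl in range(1, 4):
                frailty[order[bounds[lvl - 1]:bounds[lvl]]] = lvl + 1
            # walking COP path length linked to standing fBOS length
            z_len_rank = ndtri(
                (pd.Series(vals["norm_length"]).rank().to_numpy() - 0.5) / n)
            z_p = r_walk * z_len_rank + np.sqrt(1 - r_walk ** 2) * \
                rng.standard_normal(n)
            walking_p = _bounded_map(z_p, 0.78, 0.55, 0.95, cfg.spread)
            stride_speed = rng.uniform(0.82, 1.63, n)
            if cfg.tau_walking_p_stride_speed:
                r_ws = _check_loading(
                    _loading_kendall(cfg.tau_walking_p_stride_speed),
                    "walking P~stride speed")
                z_s = r_ws * z_p + np.sqrt(1 - r_ws ** 2) * rng.standard_normal(n)
                stride_speed = 0.82 + 0.81 * ndtr(z_s)
            miss = rng.choice(n, size=min(cfg.n_walking_missing, n),
                              replace=False)
            walking_p = walking_p.astype(float)
            walking_p[miss] = np.nan
            stride_speed[miss] = np.nan
        else:
            sppb = np.full(n, np.nan)
            gait_speed = np.full(n, np.nan)
            sts = np.full(n, np.nan)
            fes = np.full(n, np.nan)
            frailty = np.full(n, np.nan)
            walking_p = np.full(n, np.nan)
            stride_speed = np.full(n, np.nan)

        barefoot = np.full(n, np.nan)
        nb = min(cfg.n_barefoot.get(g, 0), n)
        if nb:
            sel = rng.choice(n, size=nb, replace=False)
            barefoot[sel] = vals["area_ratio"][sel] * np.exp(
                rng.normal(0, 0.18, nb))

        for i in range(n):
            rows.append({
                "participant": f"P{pid:03d}", "group": g,
                "age": float(age[i]), "sex": "F" if female[i] else "M",
                "frailty": frailty[i] if g == "old" else np.nan,
                "sppb": sppb[i] if g == "old" else np.nan,
                "gait_speed": gait_speed[i], "sit_to_stand": sts[i],
                "fes_i": fes[i], "shoe_length": float(shoe[i]),
                **{m: float(vals[m][i]) for m in vals},
                "walking_p": walking_p[i], "stride_speed": stride_speed[i],
                "barefoot_area_ratio": barefoot[i],
            })
            latents.append(float(u[i]))
            pid += 1

    table = pd.DataFrame(rows)
    truth = {
        "latent": np.array(latents),
        "loadings": {"sppb": r_sppb, "gait_speed": r_gait,
                     "walking_p": r_walk},
        "config": cfg,
    }
    return table, truth


def standing_config_for_participant(
    area_ratio_target: float, norm_length: float, seed: int,
    foot_length: float = 0.27, foot_width: float = 0.09,
    duration: float = 60.0, **kwargs,
) -> StandingTrialConfig:
    """Standing-trial config whose true fBOS has the requested normalised
    area and length (width follows as area/length)."""
    norm_width = area_ratio_target / norm_length
    if not (0 < norm_width < 1):
        raise ValueError("area/length targets imply a width outside (0, 1)")
    truth = scaled_footprint_fbos(foot_length, foot_width, norm_width,
                                  norm_length)
    return StandingTrialConfig(
        duration=duration, foot_length=foot_length, foot_width=foot_width,
        true_fbos=truth, seed=seed, **kwargs,
    )
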