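"""Plain-text I/O for trials, polygon models and cohort tables.

Trial layout (one directory per trial, diff-able TSV):

* ``meta.json`` — rates, plate origins, format version;
* ``markers.tsv`` — one header line of labels, then one row per marker
  sample with seconds in column 1 and ``<label>_x/_y/_z`` columns;
* ``forces_<plate>.tsv`` — per plate, at native rate: seconds, Fx..Mz.

Polygon models are JSON with a declared format version; the reader
normalises orientation to counter-clockwise, deduplicates repeated
vertices and rejects non-convex boundaries.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import FBOSPolygon, GroupTemplate, NORMALIZED
from .trial import (ForcePlateRecord, MarkerTrajectory, SyntheticTrial,
                    foot_marker_labels)

log = logging.getLogger(__name__)

FORMAT_VERSION = 1


class UnsupportedFormatError(ValueError):
    """File format not handled by this package."""


class MissingMarkerError(KeyError):
    """Required foot markers absent from a marker file."""


class FormatError(ValueError):
    """Structurally invalid or inconsistent trial files."""


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------


def write_trial(trial: SyntheticTrial, path) -> Path:
    """Write a trial to a directory of TSV files plus meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = trial.markers
    header = ["time"] + [f"{lab}_{ax}" for lab in m.labels for ax in "xyz"]
    flat = m.positions.reshape(m.n_samples, -1).copy()
    flat[~np.repeat(m.mask, 3, axis=1)] = np.nan
    data = np.column_stack([m.time, flat])
    np.savetxt(path / "markers.tsv", data, delimiter="\t", fmt="%.10g",
               header="\t".join(header), comments="")
    meta = {
        "format_version": FORMAT_VERSION,
        "marker_rate_hz": m.rate,
        "plates": {},
    }
    for pid, plate in trial.plates.items():
        rows = np.column_stack([plate.time, plate.F, plate.M])
        np.savetxt(path / f"forces_{pid}.tsv", rows, delimiter="\t",
                   fmt="%.10g",
                   header="\t".join(["time", "Fx", "Fy", "Fz",
                                     "Mx", "My", "Mz"]),
                   comments="")
        meta["plates"][pid] = {
            "rate_hz": plate.rate,
            "origin": list(map(float, plate.origin)),
            "origin_depth": plate.origin_depth,
        }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _check_rate(time: np.ndarray, declared: float, what: str) -> None:
    if time.shape[0] >= 2:
        dt = np.median(np.diff(time))
        if not np.isclose(dt, 1.0 / declared, rtol=1e-4):
            raise FormatError(
                f"{what}: time column spacing {dt:.6g} s does not match "
                f"declared rate {declared} Hz")


def read_trial(path,
               require_feet: Tuple[str, ...] = ("left", "right"),
               ) -> Tuple[MarkerTrajectory, Dict[str, ForcePlateRecord]]:
    """Read a trial directory written by :func:`write_trial`.

    Validates that all six foot markers of each required foot are
    present (raising :class:`MissingMarkerError` naming any that are
    not) and that declared rates match the time columns. ``.c3d`` input
    is not supported by this build and raises
    :class:`UnsupportedFormatError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".c3d":
        raise UnsupportedFormatError(
            "C3D input is not supported; export the trial to the "
            "documented TSV layout instead")
    if not path.is_dir():
        raise FormatError(f"{path} is not a trial directory")
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise FormatError(f"unknown trial format version "
                          f"{meta.get('format_version')!r}")

    mk = pd.read_csv(path / "markers.tsv", sep="\t")
    if mk.shape[0] == 0:
        raise FormatError("markers.tsv contains no samples")
    cols = list(mk.columns[1:])
    if len(cols) % 3:
        raise FormatError("marker columns are not x/y/z triplets "
                          "(truncated file?)")
    labels = [c[:-2] for c in cols[::3]]
    missing: List[str] = []
    for side in require_feet:
        missing += [lab for lab in foot_marker_labels(side)
                    if lab not in labels]
    if missing:
        raise MissingMarkerError(
            f"required foot markers missing: {', '.join(missing)}")
    rate = float(meta["marker_rate_hz"])
    _check_rate(mk["time"].to_numpy(), rate, "markers.tsv")
    positions = mk.iloc[:, 1:].to_numpy(dtype=float).reshape(len(mk), -1, 3)
    markers = MarkerTrajectory(labels=labels, positions=positions, rate=rate)

    plates: Dict[str, ForcePlateRecord] = {}
    for pid, pmeta in meta.get("plates", {}).items():
        f = pd.read_csv(path / f"forces_{pid}.tsv", sep="\t")
        expected = ["time", "Fx", "Fy", "Fz", "Mx", "My", "Mz"]
        if list(f.columns) != expected:
            raise FormatError(f"forces_{pid}.tsv: expected columns {expected}")
        _check_rate(f["time"].to_numpy(), float(pmeta["rate_hz"]),
                    f"forces_{pid}.tsv")
        plates[pid] = ForcePlateRecord(
            F=f[["Fx", "Fy", "Fz"]].to_numpy(dtype=float),
            M=f[["Mx", "My", "Mz"]].to_numpy(dtype=float),
            rate=float(pmeta["rate_hz"]),
            origin=np.asarray(pmeta["origin"], dtype=float),
            origin_depth=float(pmeta.get("origin_depth", 0.0)),
            plate_id=pid,
        )
    return markers, plates


# ---------------------------------------------------------------------------
# polygon models
# ---------------------------------------------------------------------------


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return float((np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def _validate_convex(v: np.ndarray) -> np.ndarray:
    """Deduplicate, enforce CCW order and verify convexity."""
    keep = [0]
    for i in range(1, len(v)):
        if not np.allclose(v[i], v[keep[-1]], atol=1e-12):
            keep.append(i)
    if len(keep) > 1 and np.allclose(v[keep[-1]], v[keep[0]], atol=1e-12):
        keep = keep[:-1]
    v = v[keep]
    if len(v) < 3:
        raise ValueError("polygon has fewer than 3 distinct vertices")
    if _signed_area(v) < 0:
        log.info("polygon model was clockwise; re-ordering counter-clockwise")
        v = v[::-1]
    # convexity: all cross products of consecutive edges non-negative
    a = np.roll(v, -1, axis=0) - v
    b = np.roll(a, -1, axis=0)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    if np.any(cross < -1e-12 * max(1.0, np.abs(v).max() ** 2)):
        raise ValueError("polygon model is non-convex or self-intersecting")
    return v


def write_polygon_model(template: GroupTemplate, path,
                        marker_set: str = "IOR",
                        provenance: Optional[dict] = None) -> Path:
    """Serialise a normalised group template to JSON."""
    path = Path(path)
    obj = {
        "format_version": FORMAT_VERSION,
        "group": template.group,
        "marker_set": marker_set,
        "units": "normalized (x/W, y/L)",
        "n_participants": template.n_participants,
        "vertices": template.polygon.vertices.tolist(),
        "dispersion": np.asarray(template.dispersion).tolist(),
        "provenance": provenance or {},
    }
    path.write_text(json.dumps(obj, indent=1))
    return path


def read_polygon_model(path) -> GroupTemplate:
    """Read and validate a polygon model JSON file."""
    path = Path(path)
    obj = json.loads(path.read_text())
    if obj.get("format_version") != FORMAT_VERSION:
        raise FormatError(
            f"unknown polygon model version {obj.get('format_version')!r}")
    v = _validate_convex(np.asarray(obj["vertices"], dtype=float))
    poly = FBOSPolygon(v, units=NORMALIZED, side=obj.get("side"))
    disp = np.asarray(obj.get("dispersion", np.zeros(len(v))), dtype=float)
    return GroupTemplate(group=obj.get("group", "unknown"), polygon=poly,
                         dispersion=disp,
                         n_participants=int(obj.get("n_participants", 0)))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

#: canonical column → accepted aliases (case-insensitive); extend via the
#: ``aliases`` argument when the exact headers of an external workbook
#: are known
DEFAULT_ALIASES: Dict[str, List[str]] = {
    "participant": ["participant", "id", "subject", "participant_id"],
    "group": ["group", "age_group", "agegroup", "cohort"],
    "age": ["age", "age_yr", "age_years"],
    "sex": ["sex", "gender"],
    "frailty": ["frailty", "cfs", "frailty_level", "clinical_frailty_scale"],
    "sppb": ["sppb", "sppb_total", "sppb_score"],
    "gait_speed": ["gait_speed", "gaitspeed", "walking_speed_4m",
                   "gait_speed_4m"],
    "sit_to_stand": ["sit_to_stand", "sts", "sit_to_stand_time",
                     "five_times_sit_to_stand"],
    "fes_i": ["fes_i", "fes", "fesi", "short_fes_i"],
    "area_ratio": ["area_ratio", "fbos_area", "fbos_area_norm",
                   "norm_area", "normalised_fbos_area"],
    "norm_length": ["norm_length", "fbos_length", "fbos_length_norm"],
    "norm_width": ["norm_width", "fbos_width", "fbos_width_norm"],
    "d_toe": ["d_toe", "dist_toe", "inward_toe"],
    "d_heel": ["d_heel", "dist_heel", "inward_heel"],
    "d_lat_ankle": ["d_lat_ankle", "dist_lat_ankle", "inward_lat_ankle"],
    "d_little_toe": ["d_little_toe", "dist_little_toe", "inward_little_toe",
                     "d_mtp5"],
    "walking_p": ["walking_p", "cop_path", "cop_path_norm",
                  "walking_cop_path"],
    "stride_speed": ["stride_speed", "walking_stride_speed"],
    "barefoot_area_ratio": ["barefoot_area_ratio", "area_ratio_barefoot",
                            "fbos_area_barefoot"],
    "shoe_length": ["shoe_length", "foot_length"],
}

GROUP_LABELS = {
    "young": "young", "y": "young", "ya": "young", "younger": "young",
    "middle": "middle", "m": "middle", "ma": "middle",
    "middle-aged": "middle", "middle_aged": "middle",
    "old": "old", "o": "old", "oa": "old", "older": "old",
}


def read_cohort_table(path, aliases: Optional[Dict[str, List[str]]] = None
                      ) -> pd.DataFrame:
    """Read a per-participant outcome table from CSV or XLSX.

    Columns are mapped to canonical names through the (extendable) alias
    map; group labels are normalised to young/middle/old; missing cells
    stay missing. Columns that match no alias raise a mapping error
    listing the accepted candidates.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    elif path.suffix.lower() in (".csv", ".tsv", ".txt"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        raw = pd.read_csv(path, sep=sep)
    else:
        raise UnsupportedFormatError(
            f"unsupported cohort table format {path.suffix!r}")
    def norm(name: str) -> str:
        return str(name).strip().lower().replace(" ", "_")

    amap = {k: [norm(a) for a in v] for k, v in DEFAULT_ALIASES.items()}
    for k, v in (aliases or {}).items():
        amap.setdefault(k, [])
        amap[k] = [norm(a) for a in v] + amap[k]
    lookup = {a: canon for canon, al in amap.items() for a in al}
    renames, unknown = {}, []
    for col in raw.columns:
        key = norm(col)
        if key in lookup:
            renames[col] = lookup[key]
        else:
            unknown.append(str(col))
    if unknown:
        raise FormatError(
            "unmapped cohort table columns: "
            f"{unknown}; accepted names include "
            f"{sorted(set(a for al in amap.values() for a in al))}")
    table = raw.rename(columns=renames)
    if "group" in table.columns:
        table["group"] = (table["group"].astype(str).str.strip().str.lower()
                          .map(GROUP_LABELS))
        if table["group"].isna().any():
            raise FormatError("unrecognised group labels in cohort table")
    return table


def write_cohort_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
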