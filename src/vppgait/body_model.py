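"""Body-segment-parameter model: CoM, angular momentum, torque, angles.

The whole-body centre of mass (CoM) is reconstructed from marker
trajectories with a body-segment-parameter table: each segment is a
two-point rod between a proximal and a distal marker, carrying a fixed
fraction of body mass with its own CoM at a fixed fraction of the
proximal-to-distal axis, and a radius of gyration expressed as a fraction
of segment length.  The shipped default table is an approximate
whole-body set adapted from the classical cadaver-based literature
(head+trunk pooled, bilateral limb segments); the numerical values are
conventional, not measured here, and all correctness tests in this
package use synthetic tables so the pipeline's validity does not hinge on
any specific constants.

Sagittal-plane sign convention: x forward, z up; rotations are measured
counterclockwise in the x-z plane as seen from the subject's left, so
negative angular momentum means clockwise (forward-pitching) rotation.
Joint angles are interior angles in degrees with 180 deg = fully
extended.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigurationError, ValidationError

__all__ = [
    "SegmentParameterTable",
    "default_segment_table",
    "compute_com",
    "compute_segment_states",
    "compute_angular_momentum",
    "compute_ankle_torque",
    "compute_angles",
]

_TABLE_COLUMNS = ["segment", "proximal_marker", "distal_marker",
                  "mass_fraction", "com_fraction", "gyration_fraction"]


@dataclasses.dataclass
class SegmentParameterTable:
    """Per-segment mass/geometry fractions keyed to marker names."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"segment table lacks columns {missing}")
        f = self.frame
        total = float(f["mass_fraction"].sum())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"segment mass fractions must sum to 1, got {total:.8f}")
        for col in ("mass_fraction", "com_fraction", "gyration_fraction"):
            vals = f[col].to_numpy(float)
            # mass_fraction may be exactly 1 for a single-segment body
            hi_ok = vals <= 1 if col == "mass_fraction" else vals < 1
            if np.any(vals <= 0) or not np.all(hi_ok):
                raise ValidationError(f"{col} values must lie in (0, 1)")

    def __iter__(self):
        return (row for _, row in self.frame.iterrows())

    def __len__(self) -> int:
        return len(self.frame)

    def required_markers(self) -> set[str]:
        return set(self.frame["proximal_marker"]) | set(self.frame["distal_marker"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentParameterTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame[_TABLE_COLUMNS].to_csv(path, index=False)


_DEFAULT_TABLE_CSV = """\
segment,proximal_marker,distal_marker,mass_fraction,com_fraction,gyration_fraction
head_trunk,C7,L5,0.551,0.45,0.50
upper_arm_R,R_acromion,R_elbow,0.0325,0.447,0.30
upper_arm_L,L_acromion,L_elbow,0.0325,0.447,0.30
forearm_R,R_elbow,R_wrist,0.0187,0.432,0.30
forearm_L,L_elbow,L_wrist,0.0187,0.432,0.30
hand_R,R_wrist,R_finger,0.0065,0.468,0.30
hand_L,L_wrist,L_finger,0.0065,0.468,0.30
thigh_R,R_trochanter,R_knee,0.105,0.433,0.32
thigh_L,L_trochanter,L_knee,0.105,0.433,0.32
shank_R,R_knee,R_lat_malleolus,0.0475,0.433,0.30
shank_L,L_knee,L_lat_malleolus,0.0475,0.433,0.30
foot_R,R_lat_malleolus,R_toe,0.0143,0.50,0.35
foot_L,L_lat_malleolus,L_toe,0.0143,0.50,0.35
"""


def default_segment_table() -> SegmentParameterTable:
    """Approximate whole-body segment-parameter table for the shipped
    marker set (two-point rods; head pooled into the trunk segment)."""
    return SegmentParameterTable(pd.read_csv(_io.StringIO(_DEFAULT_TABLE_CSV)))


def _resolve(markers, names: set[str]) -> None:
    missing = sorted(n for n in names if n not in markers.positions)
    if missing:
        raise ConfigurationError(f"markers not found in trial: {missing}")


def compute_segment_states(markers, table: SegmentParameterTable,
                           total_mass: float):
    """Per-segment CoM positions (n,3), masses (kg) and rod endpoints."""
    _resolve(markers, table.required_markers())
    states = []
    for row in table:
        prox = markers[row["proximal_marker"]]
        dist = markers[row["distal_marker"]]
        cf = float(row["com_fraction"])
        states.append({
            "name": row["segment"],
            "mass": float(row["mass_fraction"]) * total_mass,
            "com": prox + cf * (dist - prox),
            "proximal": prox,
            "distal": dist,
            "gyration_fraction": float(row["gyration_fraction"]),
        })
    return states


def compute_com(markers, table: SegmentParameterTable,
                total_mass: float = 1.0) -> np.ndarray:
    """Whole-body CoM trajectory (n,3): mass-fraction-weighted sum of
    segment CoMs.  Independent of ``total_mass`` (fractions sum to 1)."""
    states = compute_segment_states(markers, table, total_mass)
    total = sum(s["mass"] for s in states)
    com = sum(s["mass"] * s["com"] for s in states) / total
    return np.asarray(com)


def _cross_sagittal(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x-z plane cross product, counterclockwise positive: a_x b_z - a_z b_x."""
    return a[..., 0] * b[..., -1] - a[..., -1] * b[..., 0]


def _central_diff(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.gradient(y, t, axis=0)


def compute_angular_momentum(markers, table: SegmentParameterTable,
                             total_mass: float,
                             mean_speed: float | None = None,
                             com_height: float | None = None,
                             ) -> dict[str, np.ndarray]:
    """Sagittal whole-body angular momentum about the CoM.

    Each segment contributes an orbital term m_s (r_s - r_com) x (v_s -
    v_com) and a spin term I_s w_s, with the rod inertia
    I_s = m_s (gyration_fraction * length)^2 and w_s the derivative of the
    segment's sagittal orientation angle.  Velocities come from central
    finite differences of the (already filtered) positions.

    If ``mean_speed`` and ``com_height`` are given, also returns the
    dimensionless momentum L / (M * V * H) conventionally used to compare
    gaits across body sizes and speeds.
    """
    t = markers.time
    states = compute_segment_states(markers, table, total_mass)
    r_com = compute_com(markers, table, total_mass)
    v_com = _central_diff(r_com, t)
    L = np.zeros(t.size)
    for s in states:
        v_s = _central_diff(s["com"], t)
        L += s["mass"] * _cross_sagittal(s["com"] - r_com, v_s - v_com)
        axis = s["distal"] - s["proximal"]
        length = np.linalg.norm(axis[:, [0, -1]], axis=1)
        phi = np.unwrap(np.arctan2(axis[:, -1], axis[:, 0]))
        omega = _central_diff(phi, t)
        inertia = s["mass"] * (s["gyration_fraction"] * length) ** 2
        L += inertia * omega
    out = {"angular_momentum": L}
    if mean_speed is not None and com_height is not None:
        if mean_speed <= 0 or com_height <= 0:
            raise ValidationError("normalisation speed and CoM height must "
                                  "be positive")
        out["normalized"] = L / (total_mass * mean_speed * com_height)
    return out


def compute_ankle_torque(grf: np.ndarray, cop: np.ndarray,
                         ankle: np.ndarray, mass: float) -> np.ndarray:
    """Quasi-static sagittal ankle (or wrist) torque, N*m/kg.

    tau = [(CoP - ankle) x F]_sagittal / mass, neglecting the inertia of
    the foot segment — a standard quasi-static approximation during
    stance.  Samples with an undefined CoP (unloaded plate) come out NaN.
    """
    if mass <= 0:
        raise ValidationError("mass must be positive")
    grf = np.asarray(grf, float)
    cop = np.asarray(cop, float)
    ankle = np.asarray(ankle, float)
    lever = np.empty_like(ankle[:, [0, -1]])
    lever[:, 0] = cop[:, 0] - ankle[:, 0]
    lever[:, 1] = 0.0 - ankle[:, -1]  # CoP lies on the ground plane
    f_sag = grf[:, [0, -1]] if grf.shape[1] == 3 else grf
    return _cross_sagittal(lever, f_sag) / mass


def _interior_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between vector series in degrees; NaN for degenerate vectors."""
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    out[(nu < 1e-12) | (nv < 1e-12)] = np.nan
    return out


def compute_angles(markers, side: str = "R",
                   handstand: bool = False) -> dict[str, np.ndarray]:
    """Sagittal joint and trunk angles in degrees.

    * trunk: signed angle between the vertical and the line from L5 to the
      midpoint of the two acromion markers (forward lean positive);
    * knee: interior angle between thigh (knee -> trochanter) and shank
      (knee -> lateral malleolus), 180 deg = fully extended;
    * ankle: interior angle between the shank vector (knee -> lateral
      malleolus) and the foot vector (lateral malleolus -> toe).

    With ``handstand=True`` the arm substitutes for the leg: elbow for
    knee and wrist for ankle (upper arm / forearm / hand chain).
    """
    needed = {"L5", "R_acromion", "L_acromion"}
    if handstand:
        hip, knee, ankle, toe = (f"{side}_acromion", f"{side}_elbow",
                                 f"{side}_wrist", f"{side}_finger")
    else:
        hip, knee, ankle, toe = (f"{side}_trochanter", f"{side}_knee",
                                 f"{side}_lat_malleolus", f"{side}_toe")
    needed |= {hip, knee, ankle, toe}
    _resolve(markers, needed)
    mid_acromion = 0.5 * (markers["R_acromion"] + markers["L_acromion"])
    trunk_vec = mid_acromion - markers["L5"]
    trunk = np.degrees(np.arctan2(trunk_vec[:, 0], trunk_vec[:, -1]))
    trunk[np.linalg.norm(trunk_vec, axis=1) < 1e-12] = np.nan
    thigh = markers[hip] - markers[knee]
    shank_up = markers[knee] - markers[ankle]
    foot = markers[toe] - markers[ankle]
    return {
        "trunk": trunk,
        "knee": _interior_angle(thigh, -shank_up),
        "ankle": _interior_angle(-shank_up, foot),
    }
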