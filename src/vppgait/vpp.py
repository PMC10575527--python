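"""Virtual pivot point (VPP) estimation from ground-reaction-force lines.

During the single support phase of walking, ground reaction forces (GRFs)
plotted in a CoM-centred sagittal frame tend to converge toward a single
point above the centre of mass — the virtual pivot point.  This module
implements the two quantities that operationalise that observation:

* the VPP position, defined as the point minimising the sum of squared
  perpendicular distances to the GRF lines of the single support phase
  (a linear least-squares problem with a closed-form solution), and
* an angle-based coefficient of determination

      R^2 = 1 - sum_ij (theta_exp_ij - theta_vpp_ij)^2
              / sum_ij (theta_exp_ij - theta_bar)^2

  where ``theta_exp`` is the angle between the ground and the measured
  GRF, ``theta_vpp`` the angle between the ground and the line connecting
  the centre of pressure (CoP) to the fitted VPP, and ``theta_bar`` the
  grand mean of ``theta_exp`` over all trials and instants of one
  participant-condition.  R^2 ranges over (-inf, 1]; the VPP is declared
  a point iff R^2 > 0.6 (strict), the conventional cutoff.

Angles are measured counterclockwise from the +x (travel-direction)
ground axis in the sagittal plane, so an exactly vertical force has
theta = pi/2.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import (
    AnalysisConfig,
    DataError,
    DegenerateGeometryError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "ForceLineSet",
    "VPPFit",
    "build_force_lines",
    "fit_vpp",
    "compute_r_squared",
    "classify_vpp",
    "aggregate",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ForceLineSet:
    """GRF lines of one or more trials in the CoM-centred sagittal frame.

    ``origins[k]`` is the CoM-relative CoP position (x, z) of line *k* in
    metres (z is negative: the CoP lies on the ground, below the CoM),
    ``directions[k]`` the unit GRF direction (x, z) and ``magnitudes[k]``
    the GRF magnitude in BW.  ``trial_ids[k]`` indexes the source trial so
    that several trials can be pooled in one set.
    """

    origins: np.ndarray      # (n, 2)
    directions: np.ndarray   # (n, 2), unit vectors
    magnitudes: np.ndarray   # (n,)
    trial_ids: np.ndarray    # (n,) int

    def __post_init__(self) -> None:
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        n = len(self.origins)
        if not (len(self.directions) == len(self.magnitudes) == len(self.trial_ids) == n):
            raise ValidationError("ForceLineSet arrays must share their length")
        norms = np.linalg.norm(self.directions, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("ForceLineSet directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def theta_exp(self) -> np.ndarray:
        """Angle between ground and GRF, radians in (0, pi) for upward forces."""
        return np.arctan2(self.directions[:, 1], self.directions[:, 0])

    @property
    def n_trials(self) -> int:
        return len(np.unique(self.trial_ids))

    @staticmethod
    def concatenate(sets: Sequence["ForceLineSet"]) -> "ForceLineSet":
        """Pool several line sets, re-tagging trials 0..len(sets)-1."""
        if not sets:
            raise ValidationError("cannot concatenate an empty collection")
        return ForceLineSet(
            origins=np.concatenate([s.origins for s in sets]),
            directions=np.concatenate([s.directions for s in sets]),
            magnitudes=np.concatenate([s.magnitudes for s in sets]),
            trial_ids=np.concatenate(
                [np.full(len(s), i, dtype=int) for i, s in enumerate(sets)]
            ),
        )


@dataclasses.dataclass
class VPPFit:
    """Result of a least-squares VPP fit.

    ``x``/``z`` are CoM-relative coordinates in metres (``z`` is the VPP
    height above the CoM).  ``residual`` is the minimised sum of squared
    perpendicular distances (m^2).  ``r_squared`` and ``is_point`` are
    populated once the angle statistic has been evaluated.
    """

    x: float
    z: float
    residual: float
    n_lines: int
    r_squared: float | None = None
    is_point: bool | None = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.z])


# ---------------------------------------------------------------------------
# Line construction
# ---------------------------------------------------------------------------

def build_force_lines(trial, events, com, *, config: AnalysisConfig | None = None,
                      plate: int = 1) -> ForceLineSet:
    """Build CoM-centred GRF lines for the single-support window of a trial.

    Parameters
    ----------
    trial:
        A fused :class:`~vppgait.io.TrialRecording` whose force streams
        live on the marker timeline (see ``preprocessing.synchronize``)
        and are normalised to BW.
    events:
        :class:`~vppgait.preprocessing.GaitEvents` for the trial.
    com:
        ``(n, >=2)`` CoM trajectory on the marker timeline; column 0 is x
        and the last column is the height above the ground, metres.
    plate:
        Index of the plate carrying the analysed contact (default: the
        middle plate of a three-plate walkway).

    Instants whose total GRF magnitude falls below the event threshold are
    excluded, so near-zero forces cannot contribute ill-defined directions.
    """
    config = config or AnalysisConfig()
    t0, t1 = events.single_support
    stream = trial.forces[plate]
    t = stream.time
    mask = (t >= t0) & (t <= t1)
    if not mask.any():
        raise DataError("empty single-support window: no force samples in "
                        f"[{t0:.4f}, {t1:.4f}] s")
    com = np.asarray(com, dtype=float)
    fx = stream.force[mask, 0]
    fz = stream.force[mask, 2]
    copx = stream.cop[mask, 0]
    comx = com[mask, 0]
    comz = com[mask, -1]
    if np.any(~np.isfinite(comx)) or np.any(~np.isfinite(comz)):
        raise DataError("CoM undefined inside the single-support window")
    mag = np.hypot(fx, fz)
    keep = np.isfinite(copx) & (mag >= config.event_threshold_bw)
    if not keep.any():
        raise DataError("no usable force samples in the single-support window")
    d = np.column_stack([fx[keep], fz[keep]]) / mag[keep, None]
    p = np.column_stack([copx[keep] - comx[keep], -comz[keep]])
    return ForceLineSet(
        origins=p,
        directions=d,
        magnitudes=mag[keep],
        trial_ids=np.zeros(int(keep.sum()), dtype=int),
    )


# ---------------------------------------------------------------------------
# Least-squares fit
# ---------------------------------------------------------------------------

def fit_vpp(lines: ForceLineSet, *, weight_by_force: bool = False) -> VPPFit:
    """Fit the VPP as the least-squares intersection point of GRF lines.

    The squared perpendicular distance of a point ``v`` to the line through
    ``p`` with unit direction ``d`` is ``|(I - d d^T)(v - p)|^2``.  Summing
    over lines gives a convex quadratic whose unique minimiser solves the
    normal equations ``A v = b`` with ``A = sum (I - d d^T)`` and
    ``b = sum (I - d d^T) p``.  The fit is unweighted over instants and
    trials unless ``weight_by_force`` is set.

    Raises
    ------
    DegenerateGeometryError
        If fewer than two lines are given or all lines are (numerically)
        parallel, in which case no unique intersection exists.
    """
    n = len(lines)
    if n < 2:
        raise DegenerateGeometryError("need at least two lines to intersect")
    d = lines.directions
    p = lines.origins
    w = lines.magnitudes if weight_by_force else np.ones(n)
    # projector onto each line's normal space: P_k = I - d_k d_k^T
    eye = np.eye(2)
    proj = eye[None, :, :] - d[:, :, None] * d[:, None, :]
    A = np.einsum("k,kij->ij", w, proj)
    b = np.einsum("k,kij,kj->i", w, proj, p)
    # all-parallel bundles make A rank-1
    if np.linalg.cond(A) > 1e12:
        raise DegenerateGeometryError("all force lines are parallel; the VPP "
                                      "is not identifiable")
    v = np.linalg.solve(A, b)
    r = p - v[None, :]
    resid = float(np.sum(w * (np.einsum("kij,kj->ki", proj, r) ** 2).sum(axis=1)))
    return VPPFit(x=float(v[0]), z=float(v[1]), residual=resid, n_lines=n)


def _theta_vpp(lines: ForceLineSet, vpp_xz: np.ndarray) -> np.ndarray:
    """Angle between ground and the CoP-to-VPP connections, radians."""
    delta = vpp_xz[None, :] - lines.origins
    return np.arctan2(delta[:, 1], delta[:, 0])


def compute_r_squared(lines: ForceLineSet,
                      vpp: VPPFit | Mapping[int, VPPFit]) -> float:
    """Angle-based R^2 of a VPP fit, pooled over all lines in ``lines``.

    ``vpp`` is either a single fit applied to every line (pooled-position
    mode) or a mapping ``trial_id -> VPPFit`` so each trial's lines are
    predicted by that trial's own VPP while the grand-mean angle pools all
    trials of the participant-condition.

    Raises
    ------
    UndefinedStatisticError
        If all experimental angles are equal, i.e. the denominator of the
        statistic vanishes.
    """
    if len(lines) == 0:
        raise UndefinedStatisticError("empty line set")
    theta_exp = lines.theta_exp
    theta_bar = theta_exp.mean()
    denom = float(np.sum((theta_exp - theta_bar) ** 2))
    if denom <= 0.0:
        raise UndefinedStatisticError(
            "all experimental force angles are equal; R^2 is undefined")
    if isinstance(vpp, Mapping):
        theta_pred = np.empty_like(theta_exp)
        for tid in np.unique(lines.trial_ids):
            if int(tid) not in vpp:
                raise ValidationError(f"no VPP fit supplied for trial {tid}")
            sel = lines.trial_ids == tid
            sub = ForceLineSet(lines.origins[sel], lines.directions[sel],
                               lines.magnitudes[sel], lines.trial_ids[sel])
            theta_pred[sel] = _theta_vpp(sub, vpp[int(tid)].position)
    else:
        theta_pred = _theta_vpp(lines, vpp.position)
    num = float(np.sum((theta_exp - theta_pred) ** 2))
    return 1.0 - num / denom


def classify_vpp(r2: float, threshold: float = 0.6) -> bool:
    """Existence rule: the VPP is a point iff ``r2 > threshold`` (strict)."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return bool(r2 > threshold)


# ---------------------------------------------------------------------------
# Participant/condition evaluation and aggregation
# ---------------------------------------------------------------------------

def evaluate_participant_condition(line_sets: Sequence[ForceLineSet],
                                   config: AnalysisConfig | None = None) -> dict:
    """Fit VPPs for all trials of one participant-condition and pool R^2.

    Returns a dict with the pooled R^2, the existence flag, per-trial fits
    and — when the VPP qualifies as a point — the mean VPP position over
    the accepted trials.  In per-trial mode (default) the position of each
    trial comes from that trial's own fit; in pooled mode a single fit to
    all lines is used.
    """
    config = config or AnalysisConfig()
    if not line_sets:
        raise ValidationError("need at least one trial")
    pooled = ForceLineSet.concatenate(line_sets)
    per_trial = {i: fit_vpp(s, weight_by_force=config.weight_by_force)
                 for i, s in enumerate(line_sets)}
    if config.pooled_position:
        fit = fit_vpp(pooled, weight_by_force=config.weight_by_force)
        r2 = compute_r_squared(pooled, fit)
        positions = np.array([[fit.x, fit.z]])
    else:
        r2 = compute_r_squared(pooled, per_trial)
        positions = np.array([[f.x, f.z] for f in per_trial.values()])
    is_point = classify_vpp(r2, config.r2_threshold)
    vpp_mean = positions.mean(axis=0) if is_point else np.array([np.nan, np.nan])
    return {
        "r_squared": r2,
        "is_point": is_point,
        "vpp_x": float(vpp_mean[0]),
        "vpp_z": float(vpp_mean[1]),
        "per_trial_fits": per_trial,
        "n_trials": len(line_sets),
        "n_lines": len(pooled),
    }


def median_mad(values: Iterable[float]) -> tuple[float, float]:
    """Median and (unscaled) median absolute deviation, NaNs dropped."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


def aggregate(per_participant: Mapping[str, Mapping[str, float]],
              vpp_variables: Sequence[str] = ("r_squared", "vpp_x", "vpp_z"),
              ) -> dict[str, dict[str, float]]:
    """Aggregate per-participant values of one condition across participants.

    VPP variables are summarised as median +/- median absolute deviation
    (robust to the occasional non-VPP outlier); every other variable as
    mean +/- sample standard deviation.  Participants with a missing value
    (e.g. no accepted trial) are dropped from that variable only.
    """
    if not per_participant:
        raise ValidationError("no participants to aggregate")
    variables: set[str] = set()
    for rec in per_participant.values():
        variables.update(rec)
    out: dict[str, dict[str, float]] = {}
    for var in sorted(variables):
        vals = np.array([rec[var] for rec in per_participant.values()
                         if var in rec], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[var] = {"center": float("nan"), "spread": float("nan"), "n": 0}
            continue
        if var in vpp_variables:
            med, mad = median_mad(vals)
            out[var] = {"center": med, "spread": mad, "n": int(vals.size)}
        else:
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[var] = {"center": float(vals.mean()), "spread": sd,
                        "n": int(vals.size)}
    return out
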