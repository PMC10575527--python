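"""Spatio-temporal gait parameters and condition-level statistics.

Condition comparisons follow the standard within-subject design of gait
studies: per participant, trial values are averaged; across participants,
one-way repeated-measures ANOVA (with classical eta-squared as effect
size) compares conditions, post-hoc pairwise paired t-tests use the
Sidak-corrected significance level, and one-sample t-tests against zero
ask whether the VPP lies above (z) or anterior/posterior (x) to the CoM.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .config import DataError, UndefinedStatisticError, ValidationError

__all__ = [
    "SpatioTemporal",
    "TestReport",
    "spatiotemporal",
    "rm_anova",
    "sidak",
    "t_vs_zero",
]


@dataclasses.dataclass
class SpatioTemporal:
    """Per-trial spatio-temporal parameters.

    speed: mean CoM forward velocity over the contact (m/s);
    contact/ssp/dsp times in seconds (dsp = mean of the two double-support
    intervals); rel_ssp as % of contact; step length/width from the
    lateral malleoli at the second touchdown (m); cadence in steps/min.
    """

    speed: float
    contact_time: float
    ssp_time: float
    dsp_time: float
    rel_ssp: float
    step_length: float
    step_width: float
    cadence: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def spatiotemporal(trial, events, com) -> SpatioTemporal:
    """Spatio-temporal parameters of one (direction-normalised) trial."""
    td2, to2 = events.contact
    to1, td3 = events.single_support
    contact = to2 - td2
    ssp = td3 - to1
    dsp = 0.5 * ((to1 - td2) + (to2 - td3))
    tm = trial.markers.time
    com = np.asarray(com, float)
    in_contact = (tm >= td2) & (tm <= to2)
    if in_contact.sum() < 2:
        raise DataError("contact interval contains fewer than two marker "
                        "samples")
    tc = tm[in_contact]
    speed = float((com[in_contact, 0][-1] - com[in_contact, 0][0])
                  / (tc[-1] - tc[0]))
    # step metrics: lateral malleoli of both feet at the second touchdown
    step_length = step_width = float("nan")
    names = trial.markers.positions
    if "R_lat_malleolus" in names and "L_lat_malleolus" in names:
        idx = int(np.argmin(np.abs(tm - td3)))
        right = trial.markers["R_lat_malleolus"][idx]
        left = trial.markers["L_lat_malleolus"][idx]
        step_length = float(abs(left[0] - right[0]))
        step_width = float(abs(left[1] - right[1]))
    return SpatioTemporal(
        speed=speed,
        contact_time=float(contact),
        ssp_time=float(ssp),
        dsp_time=float(dsp),
        rel_ssp=float(100.0 * ssp / contact),
        step_length=step_length,
        step_width=step_width,
        cadence=float(60.0 / (td3 - td2)),
    )


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TestReport:
    """Omnibus + post-hoc results of one condition comparison."""

    f_value: float | None
    p_value: float
    eta_squared: float | None
    df: tuple[int, int] | None
    alpha: float
    pairwise: pd.DataFrame | None = None
    statistic: float | None = None  # t for one-sample tests

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def sidak(alpha: float, m: int) -> float:
    """Sidak-corrected per-comparison level: 1 - (1 - alpha)^(1/m)."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be at least 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def rm_anova(values: np.ndarray | pd.DataFrame, alpha: float = 0.05,
             condition_names: Sequence[str] | None = None,
             posthoc: bool = True) -> TestReport:
    """One-way repeated-measures ANOVA over a participant x condition matrix.

    Rows are participants, columns conditions; rows with any missing cell
    are dropped listwise.  The classical sums-of-squares decomposition is
    used: SS_total = SS_conditions + SS_subjects + SS_error with
    F = MS_conditions / MS_error on (k-1, (n-1)(k-1)) degrees of freedom,
    and eta^2 = SS_conditions / SS_total (classical, not partial).  No
    sphericity correction is applied.  Post-hoc: all pairwise paired
    t-tests, with Sidak-adjusted p-values and significance flags.
    """
    if isinstance(values, pd.DataFrame):
        condition_names = condition_names or list(values.columns)
        values = values.to_numpy(float)
    y = np.asarray(values, float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 conditions")
    y = y[np.all(np.isfinite(y), axis=1)]
    n, k = y.shape
    if n < 3:
        raise ValidationError("need at least 3 complete participants")
    names = list(condition_names) if condition_names else [
        f"c{j}" for j in range(k)]
    grand = y.mean()
    ss_cond = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    if ss_err <= 0 or ss_tot <= 0:
        # identical columns (or constant matrix): no condition effect
        f = 0.0 if ss_cond <= 1e-300 else float("inf")
        p = 1.0 if f == 0.0 else 0.0
        eta2 = 0.0 if ss_tot <= 0 else ss_cond / ss_tot
    else:
        f = (ss_cond / df_cond) / (ss_err / df_err)
        p = float(_stats.f.sf(f, df_cond, df_err))
        eta2 = ss_cond / ss_tot
    report = TestReport(f_value=float(f), p_value=p, eta_squared=float(eta2),
                        df=(df_cond, df_err), alpha=alpha)
    if posthoc:
        m = k * (k - 1) // 2
        alpha_corr = sidak(alpha, m)
        rows = []
        for a, b in itertools.combinations(range(k), 2):
            diff = y[:, a] - y[:, b]
            if np.allclose(diff.std(ddof=1), 0.0):
                t_ab, p_ab = 0.0, 1.0
            else:
                t_ab, p_ab = _stats.ttest_rel(y[:, a], y[:, b])
            p_adj = min(1.0, 1.0 - (1.0 - p_ab) ** m)
            rows.append({"a": names[a], "b": names[b],
                         "t": float(t_ab), "p_raw": float(p_ab),
                         "p_sidak": float(p_adj),
                         "significant": bool(p_ab < alpha_corr)})
        report.pairwise = pd.DataFrame(rows)
    return report


def t_vs_zero(values: Sequence[float], m: int = 1,
              alpha: float = 0.05) -> TestReport:
    """Two-sided one-sample t-test of per-participant means against zero.

    ``m`` is the number of simultaneous tests in the family (one per
    condition, typically), used for the Sidak-corrected significance
    level.  Raises if the sample is degenerate (all values identical).
    """
    v = np.asarray(list(values), float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValidationError("need at least 2 values")
    if np.allclose(v.std(ddof=1), 0.0):
        raise UndefinedStatisticError("zero variance: one-sample t-test is "
                                      "degenerate")
    t, p = _stats.ttest_1samp(v, 0.0)
    alpha_corr = sidak(alpha, m)
    rep = TestReport(f_value=None, p_value=float(p), eta_squared=None,
                     df=(1, v.size - 1), alpha=alpha_corr,
                     statistic=float(t))
    return rep
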