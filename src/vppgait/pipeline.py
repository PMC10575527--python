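"""End-to-end analysis chain: trial recordings to condition summaries.

This module wires the stages together in the order a lab analysis runs:
direction normalisation -> event detection -> marker filtering -> CoM
reconstruction -> force-line construction -> VPP fit and R^2 -> existence
classification -> aggregation and condition statistics.  The command-line
interface is a thin wrapper around these functions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .body_model import SegmentParameterTable, compute_com, default_segment_table
from .config import AnalysisConfig, VppGaitError
from .io import MarkerStream, TrialRecording
from .preprocessing import (
    detect_events,
    lowpass_filter,
    normalize_bw,
    normalize_direction,
    synchronize,
)
from .stats import rm_anova, spatiotemporal, t_vs_zero
from .vpp import ForceLineSet, build_force_lines, evaluate_participant_condition

logger = logging.getLogger("vppgait")

VPP_VARIABLES = ("r_squared", "vpp_x", "vpp_z")
SPATIOTEMPORAL_VARIABLES = ("speed", "contact_time", "ssp_time", "dsp_time",
                            "rel_ssp", "step_length", "step_width", "cadence")


def analyze_trial(trial: TrialRecording,
                  config: AnalysisConfig | None = None,
                  table: SegmentParameterTable | None = None) -> dict:
    """Run the single-trial chain and return its intermediate products.

    Returns a dict with the detected ``events``, the filtered-marker CoM
    trajectory ``com`` (marker timeline), the single-support
    ``lines`` (:class:`ForceLineSet`), and the trial's ``spatiotemporal``
    parameters.  Forces are BW-normalised; the trial is mirrored into the
    travel-direction frame first.
    """
    config = config or AnalysisConfig()
    table = table or default_segment_table()
    trial = normalize_direction(trial)
    events = detect_events(trial, config)
    fs_m = trial.marker_rate
    filtered = MarkerStream(
        time=trial.markers.time,
        positions={name: lowpass_filter(xyz, fs_m, config.filter_cutoff_hz,
                                        config.filter_order)
                   for name, xyz in trial.markers.positions.items()},
    )
    trial = TrialRecording(forces=trial.forces, markers=filtered,
                           meta=trial.meta)
    com = compute_com(filtered, table, trial.meta.mass)
    fused = synchronize(trial)
    for s in fused.forces:
        if not s.in_bw:
            s.force = normalize_bw(s.force, trial.meta.mass, config.gravity)
            s.in_bw = True
        if config.filter_forces:
            s.force = lowpass_filter(s.force, fs_m, config.filter_cutoff_hz,
                                     config.filter_order)
    lines = build_force_lines(fused, events, com[:, [0, 2]], config=config)
    st = spatiotemporal(trial, events, com)
    return {"trial": trial, "events": events, "com": com, "lines": lines,
            "spatiotemporal": st}


def analyze_cohort(trials: Iterable[TrialRecording],
                   config: AnalysisConfig | None = None,
                   table: SegmentParameterTable | None = None,
                   ) -> tuple[list[dict], list[dict]]:
    """Analyse a collection of trials and summarise per (participant,
    condition).

    Per-trial failures are logged and skipped, mirroring the practice of
    excluding trials with missing or incorrect data; the run fails only
    if no trial succeeds.  Returns ``(rows, exclusions)`` where each row
    carries the pooled R^2, the existence flag, the accepted mean VPP and
    the mean spatio-temporal parameters of one participant-condition.
    """
    config = config or AnalysisConfig()
    table = table or default_segment_table()
    groups: dict[tuple[str, str], list[dict]] = {}
    exclusions: list[dict] = []
    n_seen = 0
    for trial in trials:
        n_seen += 1
        key = (trial.meta.participant_id, trial.meta.condition)
        try:
            result = analyze_trial(trial, config, table)
        except VppGaitError as exc:
            record = {"participant_id": key[0], "condition": key[1],
                      "trial_id": trial.meta.trial_id, "reason": str(exc)}
            exclusions.append(record)
            logger.warning("excluded trial %s/%s/%s: %s", *key,
                           trial.meta.trial_id, exc)
            continue
        groups.setdefault(key, []).append(result)
    if n_seen and not groups:
        raise VppGaitError("no trial could be analysed; see exclusion log")
    rows: list[dict] = []
    for (pid, cond), results in sorted(groups.items()):
        line_sets: list[ForceLineSet] = [r["lines"] for r in results]
        summary = evaluate_participant_condition(line_sets, config)
        st = pd.DataFrame([r["spatiotemporal"].as_dict() for r in results])
        row = {
            "participant_id": pid,
            "condition": cond,
            "n_trials": summary["n_trials"],
            "n_lines": summary["n_lines"],
            "r_squared": summary["r_squared"],
            "vpp_is_point": summary["is_point"],
            "vpp_x": summary["vpp_x"],
            "vpp_z": summary["vpp_z"],
        }
        row.update({k: float(v) for k, v in st.mean().items()})
        rows.append(row)
    return rows, exclusions


def condition_statistics(rows: Sequence[dict],
                         config: AnalysisConfig | None = None) -> dict:
    """Condition-level summary table and statistical tests.

    Builds, per variable, the participant x condition matrix of
    per-participant means; runs the repeated-measures ANOVA with Sidak
    post-hoc across conditions, one-sample t-tests of VPPx/VPPz against
    zero per condition (Sidak-corrected over conditions), and aggregates
    each condition as median +/- MAD (VPP variables) or mean +/- s.d.
    (spatio-temporal variables).
    """
    config = config or AnalysisConfig()
    frame = pd.DataFrame(list(rows))
    if frame.empty:
        raise VppGaitError("no analysis rows to summarise")
    conditions = sorted(frame["condition"].unique())
    out: dict = {"conditions": conditions, "anova": {}, "t_vs_zero": {},
                 "summary": {}}
    for var in VPP_VARIABLES + SPATIOTEMPORAL_VARIABLES:
        if var not in frame.columns:
            continue
        wide = frame.pivot_table(index="participant_id", columns="condition",
                                 values=var, dropna=False)
        wide = wide.reindex(columns=conditions)
        robust = var in VPP_VARIABLES
        per_cond = {}
        for cond in conditions:
            vals = wide[cond].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                per_cond[cond] = {"center": np.nan, "spread": np.nan, "n": 0}
            elif robust:
                med = float(np.median(vals))
                mad = float(np.median(np.abs(vals - med)))
                per_cond[cond] = {"center": med, "spread": mad,
                                  "n": int(vals.size)}
            else:
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                per_cond[cond] = {"center": float(vals.mean()), "spread": sd,
                                  "n": int(vals.size)}
        out["summary"][var] = per_cond
        if len(conditions) >= 2:
            try:
                out["anova"][var] = rm_anova(wide, alpha=config.alpha,
                                             condition_names=conditions)
            except VppGaitError as exc:
                logger.warning("rmANOVA skipped for %s: %s", var, exc)
    for var in ("vpp_x", "vpp_z"):
        if var not in frame.columns:
            continue
        for cond in conditions:
            vals = frame.loc[frame["condition"] == cond, var].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            try:
                out["t_vs_zero"][(var, cond)] = t_vs_zero(
                    vals, m=len(conditions), alpha=config.alpha)
            except VppGaitError as exc:
                logger.warning("t-test skipped for %s/%s: %s", var, cond, exc)
    return out


def statistics_table(stats: dict) -> pd.DataFrame:
    """Flatten :func:`condition_statistics` into a conditions-as-columns
    report (one row per variable, 'center+/-spread' cells, omnibus P and
    F/eta^2 columns)."""
    conditions = stats["conditions"]
    rows = []
    for var, per_cond in stats["summary"].items():
        row: dict = {"variable": var}
        for cond in conditions:
            c = per_cond[cond]
            row[cond] = (f"{c['center']:.2f}±{c['spread']:.2f}"
                         if np.isfinite(c["center"]) else "—")
        rep = stats["anova"].get(var)
        if rep is not None:
            row["P"] = f"{rep.p_value:.3f}"
            row["F/eta2"] = f"{rep.f_value:.2f}/{rep.eta_squared:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
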