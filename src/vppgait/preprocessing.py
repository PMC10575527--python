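"""Filtering, normalisation, event detection and frame normalisation.

The preprocessing chain turns a raw three-plate walking trial into the
phase structure the VPP computation needs:

1. kinematic (marker) streams are low-passed with a zero-phase
   fourth-order Butterworth filter (50 Hz cutoff by default);
2. forces are normalised to body weight (BW = mass * g);
3. touchdown (TD) and take-off (TO) are detected per plate with a 0.05 BW
   threshold on the vertical GRF, and combined into the walking phase
   intervals (contact, single support, the two double supports);
4. the force streams are resampled onto the marker timeline;
5. the trial is mirrored into a common analysis frame in which +x always
   points in the direction of travel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _signal

from .config import (
    AnalysisConfig,
    ConfigurationError,
    DataError,
    InvalidGaitError,
    NoContactError,
    ValidationError,
)

__all__ = [
    "GaitEvents",
    "lowpass_filter",
    "normalize_bw",
    "detect_plate_contact",
    "detect_events",
    "synchronize",
    "normalize_direction",
]


@dataclasses.dataclass
class GaitEvents:
    """Touchdown/take-off instants (s) per plate and derived intervals.

    A valid trial covers one full contact on the middle plate (index 1),
    bracketed by the contralateral take-off on plate 0 and the
    contralateral touchdown on plate 2, so that

        contact        = [TD2, TO2]
        double_support = [TD2, TO1]  then  [TD3, TO2]
        single_support = [TO1, TD3]

    with the ordering TD2 < TO1 < TD3 < TO2 (numbering plates 1..3 as on
    the walkway).
    """

    td: tuple[float, float, float]
    to: tuple[float, float, float]

    def __post_init__(self) -> None:
        td2, to1, td3, to2 = self.td[1], self.to[0], self.td[2], self.to[1]
        if not (td2 < to1 < td3 < to2):
            raise InvalidGaitError(
                "event ordering TD2 < TO1 < TD3 < TO2 violated: "
                f"TD2={td2:.4f}, TO1={to1:.4f}, TD3={td3:.4f}, TO2={to2:.4f}")

    @property
    def contact(self) -> tuple[float, float]:
        return (self.td[1], self.to[1])

    @property
    def single_support(self) -> tuple[float, float]:
        return (self.to[0], self.td[2])

    @property
    def double_support_1(self) -> tuple[float, float]:
        return (self.td[1], self.to[0])

    @property
    def double_support_2(self) -> tuple[float, float]:
        return (self.td[2], self.to[1])


def lowpass_filter(series: np.ndarray, fs: float, fc: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The bidirectional pass squares the magnitude response, so the -3 dB
    point of the one-way design becomes a -6 dB point (gain 1/2) at
    ``fc``.  Operates along the first axis; NaNs are not handled.
    """
    if fc <= 0:
        raise ValidationError("cutoff frequency must be positive")
    if fc >= fs / 2:
        raise ValidationError(f"cutoff {fc} Hz must be below Nyquist {fs / 2} Hz")
    series = np.asarray(series, dtype=float)
    sos = _signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, series, axis=0)


def normalize_bw(force: np.ndarray, mass: float,
                 gravity: float = 9.81) -> np.ndarray:
    """Normalise forces in newtons to units of body weight (mass * g)."""
    if mass <= 0:
        raise ValidationError("mass must be positive")
    return np.asarray(force, dtype=float) / (mass * gravity)


def detect_plate_contact(time: np.ndarray, fz_bw: np.ndarray,
                         threshold: float = 0.05,
                         min_contact_s: float = 0.05) -> tuple[float, float]:
    """TD and TO of the longest supra-threshold run of one plate.

    TD is the time of the first sample strictly above ``threshold`` of the
    longest supra-threshold run; TO is the time of the first sample at or
    below the threshold after that run (the last sample's time if the run
    reaches the end of the record).  Runs shorter than ``min_contact_s``
    are discarded as plate noise.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1) BW")
    time = np.asarray(time, dtype=float)
    fz_bw = np.asarray(fz_bw, dtype=float)
    above = fz_bw > threshold
    if not above.any():
        raise NoContactError("no samples above threshold")
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, above.size - 1]
    runs = [(s, e) for s, e in zip(starts, ends) if above[s]]
    dt = float(np.median(np.diff(time)))
    runs = [(s, e) for s, e in runs if (e - s + 1) * dt >= min_contact_s]
    if not runs:
        raise NoContactError("no supra-threshold run longer than "
                             f"{min_contact_s * 1e3:.0f} ms")
    s, e = max(runs, key=lambda r: r[1] - r[0])
    td = float(time[s])
    to = float(time[e + 1]) if e + 1 < time.size else float(time[e])
    return td, to


def detect_events(trial, config: AnalysisConfig | None = None) -> GaitEvents:
    """Detect TD/TO on all three plates of a trial and derive the phases.

    Expects a :class:`~vppgait.io.TrialRecording`; forces may be in
    newtons (converted to BW using the trial's mass) or already in BW.
    """
    config = config or AnalysisConfig()
    tds, tos = [], []
    for i, stream in enumerate(trial.forces):
        fz = stream.force[:, 2]
        if not stream.in_bw:
            fz = normalize_bw(fz, trial.meta.mass, config.gravity)
        try:
            td, to = detect_plate_contact(stream.time, fz,
                                          config.event_threshold_bw,
                                          config.min_contact_s)
        except NoContactError as exc:
            raise NoContactError(f"plate {i + 1}: {exc}") from exc
        tds.append(td)
        tos.append(to)
    return GaitEvents(td=tuple(tds), to=tuple(tos))


def synchronize(trial):
    """Resample force/CoP streams onto the marker timeline.

    Linear interpolation is used; samples outside a plate's recorded range
    keep their edge values.  CoP samples that are NaN (unloaded plate) stay
    NaN wherever either neighbour is NaN.  Event times keep force-rate
    resolution because they are detected on the raw force streams.
    """
    from .io import PlateStream, TrialRecording  # local import: io uses us too

    tm = trial.markers.time
    tf0 = min(s.time[0] for s in trial.forces)
    tf1 = max(s.time[-1] for s in trial.forces)
    if tm[0] > tf1 or tm[-1] < tf0:
        raise DataError("marker and force time ranges do not overlap")
    new_forces = []
    for stream in trial.forces:
        t = stream.time
        force = np.column_stack([np.interp(tm, t, stream.force[:, j])
                                 for j in range(3)])
        cop = np.column_stack([_interp_nan(tm, t, stream.cop[:, j])
                               for j in range(stream.cop.shape[1])])
        new_forces.append(PlateStream(time=tm, force=force, cop=cop,
                                      in_bw=stream.in_bw))
    return TrialRecording(forces=new_forces, markers=trial.markers,
                          meta=trial.meta)


def _interp_nan(tq: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear interpolation that propagates NaN gaps instead of bridging."""
    finite = np.isfinite(y)
    if not finite.any():
        return np.full_like(tq, np.nan, dtype=float)
    out = np.interp(tq, t[finite], y[finite])
    # mask query points whose nearest source sample is NaN
    idx = np.searchsorted(t, tq).clip(1, t.size - 1)
    bad = ~finite[idx] | ~finite[idx - 1]
    out[bad] = np.nan
    return out


def normalize_direction(trial):
    """Mirror a trial so that +x is the direction of travel.

    For ``walking_direction == +1`` this is the identity.  For ``-1`` all
    x-coordinates (markers, CoP) and x-force components are negated and
    the direction flag is reset to +1, making the map an involution.
    """
    from .io import MarkerStream, PlateStream, TrialRecording

    direction = trial.meta.walking_direction
    if direction is None:
        raise ConfigurationError("trial metadata lacks walking_direction")
    if direction == 1:
        return trial
    if direction != -1:
        raise ConfigurationError(f"walking_direction must be +1 or -1, "
                                 f"got {direction}")
    forces = []
    for s in trial.forces:
        force = s.force.copy()
        force[:, 0] *= -1
        cop = s.cop.copy()
        cop[:, 0] *= -1
        forces.append(PlateStream(time=s.time, force=force, cop=cop,
                                  in_bw=s.in_bw))
    pos = {name: xyz.copy() for name, xyz in trial.markers.positions.items()}
    for xyz in pos.values():
        xyz[:, 0] *= -1
    markers = MarkerStream(time=trial.markers.time, positions=pos)
    meta = dataclasses.replace(trial.meta, walking_direction=1)
    return TrialRecording(forces=forces, markers=markers, meta=meta)
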