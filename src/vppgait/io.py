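"""Trial, results and configuration I/O.

Canonical trial format
----------------------
One CSV per trial: a metadata header of ``# key: value`` lines followed by
a wide table keyed by time.  Columns are namespaced: ``plate1.Fx`` ...
``plate3.CoPy`` for the three force plates (newtons / metres, lab frame)
and ``marker.<name>.x|y|z`` for marker trajectories (metres).  Rows run on
the force timeline; marker cells are populated only on marker timestamps
(the force rate must be an integer multiple of the marker rate), so a
single file carries both streams without resampling either.

Lab frame: x = walkway axis, y = mediolateral, z = up, ground at z = 0.
``walking_direction`` (+1/-1) records the direction of travel along x.

A ground-truth "sidecar" JSON (written by the synthetic generator) holds
the planted events, CoM trajectory and VPP of a simulated trial under the
same stem with suffix ``.truth.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import DataError, FormatError, ValidationError

__all__ = [
    "MARKER_NAMES",
    "PlateStream",
    "MarkerStream",
    "TrialMeta",
    "TrialRecording",
    "read_trial",
    "write_trial",
    "write_truth",
    "read_truth",
    "write_results",
    "read_c3d",
]

#: Reflective-marker set: bilateral anatomical landmarks plus two spine
#: markers.  "knee" = lateral femoral epicondyle, "elbow" = lateral humeral
#: epicondyle, "wrist" = ulnar styloid, "finger" = third-finger tip,
#: "toe" = first-toe tip.
MARKER_NAMES: tuple[str, ...] = tuple(
    f"{side}_{name}"
    for side in ("R", "L")
    for name in ("acromion", "elbow", "wrist", "finger", "trochanter",
                 "knee", "lat_malleolus", "med_malleolus", "toe")
) + ("L5", "C7")

_META_FIELDS = ("participant_id", "mass_kg", "height_m", "condition",
                "walking_direction", "trial_id")


@dataclasses.dataclass
class PlateStream:
    """One force plate: time (s), force (n,3) and CoP (n,2) arrays.

    ``in_bw`` marks whether forces are already body-weight normalised
    (newtons otherwise).  CoP is NaN while the plate is unloaded.
    """

    time: np.ndarray
    force: np.ndarray
    cop: np.ndarray
    in_bw: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise DataError("plate time stamps must be strictly increasing")


@dataclasses.dataclass
class MarkerStream:
    """Marker trajectories: shared time base and name -> (n,3) positions."""

    time: np.ndarray
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise DataError("marker time stamps must be strictly increasing")
        self.positions = {k: np.asarray(v, dtype=float)
                          for k, v in self.positions.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    @property
    def names(self) -> list[str]:
        return list(self.positions)


@dataclasses.dataclass
class TrialMeta:
    participant_id: str
    mass: float
    height: float
    condition: str
    walking_direction: int
    trial_id: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValidationError("participant mass must be positive")


@dataclasses.dataclass
class TrialRecording:
    """Synchronised force-plate and marker streams of one walking trial."""

    forces: list[PlateStream]
    markers: MarkerStream
    meta: TrialMeta

    @property
    def force_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.forces[0].time)))

    @property
    def marker_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.markers.time)))


# ---------------------------------------------------------------------------
# Trial CSV
# ---------------------------------------------------------------------------

def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Write a trial to the canonical single-file CSV layout."""
    path = Path(path)
    tf = trial.forces[0].time
    n = tf.size
    cols: dict[str, np.ndarray] = {"time": tf}
    for i, s in enumerate(trial.forces, start=1):
        if s.time.shape != tf.shape or not np.allclose(s.time, tf):
            raise DataError("all plates must share one force timeline for "
                            "the canonical CSV")
        for j, comp in enumerate(("Fx", "Fy", "Fz")):
            cols[f"plate{i}.{comp}"] = s.force[:, j]
        for j, comp in enumerate(("CoPx", "CoPy")):
            cols[f"plate{i}.{comp}"] = s.cop[:, j]
    # marker samples go on the matching force rows
    idx = np.searchsorted(tf, trial.markers.time)
    idx = idx.clip(0, n - 1)
    if not np.allclose(tf[idx], trial.markers.time, atol=1e-9):
        raise DataError("marker timestamps must coincide with force "
                        "timestamps (force rate = k * marker rate)")
    for name in trial.markers.names:
        xyz = trial.markers[name]
        for j, comp in enumerate("xyz"):
            col = np.full(n, np.nan)
            col[idx] = xyz[:, j]
            cols[f"marker.{name}.{comp}"] = col
    frame = pd.DataFrame(cols)
    m = trial.meta
    header = [
        "# vppgait-trial v1",
        f"# participant_id: {m.participant_id}",
        f"# mass_kg: {m.mass!r}",
        f"# height_m: {m.height!r}",
        f"# condition: {m.condition}",
        f"# walking_direction: {m.walking_direction}",
        f"# trial_id: {m.trial_id}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")
    return path


def read_trial(path: str | Path) -> TrialRecording:
    """Read a canonical trial CSV back into a :class:`TrialRecording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta_raw[key.strip()] = val.strip()
    missing = [k for k in _META_FIELDS if k not in meta_raw]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    try:
        meta = TrialMeta(
            participant_id=meta_raw["participant_id"],
            mass=float(meta_raw["mass_kg"]),
            height=float(meta_raw["height_m"]),
            condition=meta_raw["condition"],
            walking_direction=int(meta_raw["walking_direction"]),
            trial_id=meta_raw["trial_id"],
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed metadata value ({exc})") from exc
    frame = pd.read_csv(path, comment="#")
    if "time" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'time'")
    t = frame["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: non-monotone time stamps")
    forces = []
    for i in (1, 2, 3):
        for comp in ("Fx", "Fy", "Fz", "CoPx", "CoPy"):
            if f"plate{i}.{comp}" not in frame.columns:
                raise FormatError(f"{path}: missing required column "
                                  f"'plate{i}.{comp}'")
        force = frame[[f"plate{i}.Fx", f"plate{i}.Fy",
                       f"plate{i}.Fz"]].to_numpy(float)
        cop = frame[[f"plate{i}.CoPx", f"plate{i}.CoPy"]].to_numpy(float)
        forces.append(PlateStream(time=t, force=force, cop=cop))
    marker_cols = [c for c in frame.columns if c.startswith("marker.")]
    names = sorted({c.split(".")[1] for c in marker_cols})
    if not names:
        raise FormatError(f"{path}: no marker columns found")
    first = frame[f"marker.{names[0]}.x"].to_numpy(float)
    sel = np.isfinite(first)
    positions = {}
    for name in names:
        try:
            xyz = frame[[f"marker.{name}.x", f"marker.{name}.y",
                         f"marker.{name}.z"]].to_numpy(float)
        except KeyError as exc:
            raise FormatError(f"{path}: incomplete marker column triple for "
                              f"'{name}'") from exc
        positions[name] = xyz[sel]
    markers = MarkerStream(time=t[sel], positions=positions)
    return TrialRecording(forces=forces, markers=markers, meta=meta)


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> Path:
    """Write a generator ground-truth record as the trial's JSON sidecar."""
    path = Path(path)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, default=_default, indent=1, sort_keys=True)
    return path


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def truth_path_for(trial_path: str | Path) -> Path:
    p = Path(trial_path)
    return p.with_suffix("").with_suffix(".truth.json") if p.suffix else p


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "participant_id", "condition", "n_trials", "n_lines",
    "r_squared", "vpp_is_point", "vpp_x", "vpp_z",
    "speed", "contact_time", "ssp_time", "dsp_time", "rel_ssp",
    "step_length", "step_width", "cadence",
]


def write_results(rows: Sequence[dict], out_dir: str | Path,
                  config=None, seed: int | None = None,
                  stem: str = "results") -> tuple[Path, Path]:
    """Write per-(participant, condition) results plus run metadata.

    Produces ``<stem>.csv`` with a deterministic column order and row sort,
    and ``<stem>.meta.json`` holding the configuration digest, seed and
    software version, so a run is fully identified by its outputs.
    Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(list(rows))
    for col in RESULTS_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    extra = [c for c in frame.columns if c not in RESULTS_COLUMNS]
    frame = frame[RESULTS_COLUMNS + sorted(extra)]
    if len(frame):
        frame = frame.sort_values(["participant_id", "condition"],
                                  kind="mergesort").reset_index(drop=True)
        # VPP coordinates are only reported when the VPP qualifies as a point
        not_point = frame["vpp_is_point"] == False  # noqa: E712 (NaN-safe)
        frame.loc[not_point, ["vpp_x", "vpp_z"]] = np.nan
    csv_path = out_dir / f"{stem}.csv"
    try:
        frame.to_csv(csv_path, index=False, float_format="%.9g",
                     lineterminator="\n")
    except OSError as exc:
        raise DataError(f"could not write results to {csv_path}: {exc}") from exc
    meta = {
        "software": f"vppgait {_pkg_version}",
        "config_digest": config.digest() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "n_rows": int(len(frame)),
    }
    meta_path = out_dir / f"{stem}.meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return csv_path, meta_path


# ---------------------------------------------------------------------------
# Optional C3D adapter
# ---------------------------------------------------------------------------

def read_c3d(path: str | Path, meta: TrialMeta) -> TrialRecording:
    """Import a trial from a C3D motion-capture container (optional).

    Requires the third-party ``ezc3d`` reader; the canonical CSV remains
    the supported interchange format and nothing in the package depends on
    this adapter.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package; "
            "install vppgait[c3d] or convert the trial to the canonical CSV"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover - optional dependency
    raise NotImplementedError(
        "C3D import is an adapter stub: map your lab's plate/marker layout "
        "onto PlateStream/MarkerStream and construct a TrialRecording"
    )  # pragma: no cover
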