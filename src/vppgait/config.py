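"""Run-time configuration and the package's exception hierarchy.

All tunable analysis parameters live in :class:`AnalysisConfig` so that a
whole pipeline run is reproducible from one record.  Defaults follow common
gait-lab practice: kinematics low-passed at 50 Hz with a zero-phase
fourth-order Butterworth filter, gait events from a 0.05 body-weight (BW)
threshold on the vertical ground reaction force, and a virtual-pivot-point
(VPP) existence threshold of R^2 > 0.6.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

GRAVITY = 9.81  # m/s^2, conventional value


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class VppGaitError(Exception):
    """Base class for all errors raised by vppgait."""


class ValidationError(VppGaitError, ValueError):
    """A specification or parameter violates its invariants."""


class ConfigurationError(VppGaitError):
    """Missing or inconsistent configuration/metadata."""


class FormatError(VppGaitError):
    """A file does not conform to the expected layout."""


class DataError(VppGaitError):
    """Data are structurally valid but unusable (non-monotone time, ...)."""


class NoContactError(DataError):
    """No supra-threshold contact found on a required force plate."""


class InvalidGaitError(DataError):
    """Detected events violate the touchdown/take-off ordering of walking."""


class DegenerateGeometryError(DataError):
    """Force-line geometry admits no unique least-squares intersection."""


class UndefinedStatisticError(DataError):
    """A statistic's defining denominator is zero (e.g. all angles equal)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalysisConfig:
    """Parameters of the trial-to-summary pipeline.

    Attributes
    ----------
    filter_cutoff_hz:
        Low-pass cutoff for kinematic (marker) data, Hz.
    filter_order:
        Butterworth order before the forward-backward pass.
    filter_forces:
        Whether to low-pass the force streams as well.  Off by default:
        only kinematics are filtered.
    event_threshold_bw:
        Vertical-force threshold for touchdown/take-off detection, in BW.
    min_contact_s:
        Supra-threshold runs shorter than this are treated as plate noise.
    r2_threshold:
        The VPP counts as a point iff R^2 is strictly greater than this.
    pooled_position:
        If True, one VPP is fitted to all pooled lines of a
        participant-condition; if False (default) the VPP is fitted per
        trial and R^2 pools the per-trial predictions.
    weight_by_force:
        Weight the least-squares fit by GRF magnitude (sensitivity
        analysis; the standard definition is unweighted).
    cop_trim:
        Fraction of contact time trimmed at each edge when *reporting*
        centre-of-pressure trajectories (the CoP is noisy at the load
        edges).  Not applied to the single-support fitting window.
    gravity:
        Gravitational acceleration used for BW normalisation, m/s^2.
    """

    filter_cutoff_hz: float = 50.0
    filter_order: int = 4
    filter_forces: bool = False
    event_threshold_bw: float = 0.05
    min_contact_s: float = 0.05
    r2_threshold: float = 0.6
    pooled_position: bool = False
    weight_by_force: bool = False
    cop_trim: float = 0.05
    gravity: float = GRAVITY
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_cutoff_hz <= 0:
            raise ValidationError("filter_cutoff_hz must be positive")
        if not 0 < self.event_threshold_bw < 1:
            raise ValidationError("event_threshold_bw must lie in (0, 1)")
        if self.min_contact_s < 0:
            raise ValidationError("min_contact_s must be non-negative")
        if not 0 <= self.cop_trim < 0.5:
            raise ValidationError("cop_trim must lie in [0, 0.5)")
        if self.gravity <= 0:
            raise ValidationError("gravity must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run-metadata records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
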