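"""Uniformly sampled time-series containers.

All times are in milliseconds. Membrane potentials are in mV; Ca++ currents
are in normalized units (open probability x driving force, inward negative).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoltageTrace",
    "CurrentTrace",
    "PairedRecording",
    "ConfigurationError",
    "FitFailureError",
    "UndefinedRatioError",
    "UndefinedCorrelationError",
]


class ConfigurationError(ValueError):
    """Inconsistent settings (e.g. sampling mismatch between trace and params)."""


class FitFailureError(RuntimeError):
    """A numerical calibration or fit could not be bracketed/solved."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio requested against a zero-amplitude control."""


class UndefinedCorrelationError(ValueError):
    """Cross-correlation of a constant (zero-variance) trace."""


def _as_samples(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} must be a 1-D array with at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite samples")
    return arr


@dataclass(frozen=True)
class VoltageTrace:
    """Membrane-potential command or recording, sampled every ``dt`` ms."""

    t0: float
    dt: float
    V: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "V", _as_samples(self.V, "V"))

    def __len__(self) -> int:
        return self.V.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.V.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.V.size - 1)

    def index_at(self, t_ms: float) -> int:
        """Sample index closest to absolute time ``t_ms``."""
        return int(round((t_ms - self.t0) / self.dt))


@dataclass(frozen=True)
class CurrentTrace:
    """Normalized Ca++ current (inward negative), sampled every ``dt`` ms."""

    t0: float
    dt: float
    I: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "I", _as_samples(self.I, "I"))

    def __len__(self) -> int:
        return self.I.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.I.size)

    def index_at(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0) / self.dt))


@dataclass(frozen=True)
class PairedRecording:
    """Simultaneous somatic and bouton voltage traces plus the axonal path
    distance (soma center to varicosity, micrometres)."""

    soma: VoltageTrace
    bouton: VoltageTrace
    distance_um: float

    def __post_init__(self):
        if self.distance_um <= 0:
            raise ValueError("distance_um must be positive")
        if abs(self.soma.dt - self.bouton.dt) > 1e-12 or len(self.soma) != len(self.bouton):
            raise ConfigurationError("soma and bouton traces must share dt and length")
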