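"""Shared in-memory containers for instrument-like signals.

All analysis and simulation functions exchange data through three small
array-backed containers: :class:`TimeSeries` for anything sampled in time
(flash-fluorescence decays, OJIP transients, oxygen-evolution time courses,
SOSG fluorescence, OD730 growth curves), :class:`Spectrum` for wavelength
scans (77 K emission), and :class:`GlowCurve` for thermoluminescence
intensity recorded along a linear temperature ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "Spectrum", "GlowCurve"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class TimeSeries:
    """A signal sampled in time.

    Parameters
    ----------
    time
        Sample times, strictly increasing. Unit given by ``time_unit``
        (seconds for flash/OJIP/O2 data, minutes for SOSG, hours for OD730).
    values
        Signal values, same length as ``time``.
    kind
        Free-form tag (``flash``, ``ojip``, ``o2``, ``sosg``, ``od`` ...).
    """

    time: np.ndarray
    values: np.ndarray
    kind: str = "generic"
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.values = _as_float_array(self.values, "values")
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def scaled(self, c: float) -> "TimeSeries":
        """Return a copy with values multiplied by ``c``."""
        return TimeSeries(self.time.copy(), self.values * c, self.kind,
                          self.time_unit, dict(self.meta))


@dataclass
class Spectrum:
    """Intensity versus wavelength (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have the same length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity at ``wavelength``."""
        w = self.wavelengths
        if not (w[0] <= wavelength <= w[-1]):
            raise ValueError(f"wavelength {wavelength} nm outside spectrum range")
        return float(np.interp(wavelength, w, self.intensities))


@dataclass
class GlowCurve:
    """Thermoluminescence intensity along a linear heating ramp.

    Temperatures are kept in kelvin internally; ``temperatures_c`` converts
    for reporting. ``beta`` is the heating rate (K/s) and ``T0`` the ramp
    start, so sample i was recorded at time (T_i - T0)/beta.
    """

    temperatures: np.ndarray
    intensities: np.ndarray
    beta: float
    T0: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_float_array(self.temperatures, "temperatures")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.temperatures.shape != self.intensities.shape:
            raise ValueError("temperatures and intensities must have the same length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.beta <= 0:
            raise ValueError("heating rate beta must be positive")

    @property
    def temperatures_c(self) -> np.ndarray:
        return self.temperatures - 273.15

    @property
    def times(self) -> np.ndarray:
        """Time (s) since the start of the ramp for each sample."""
        return (self.temperatures - self.T0) / self.beta

    def __len__(self) -> int:
        return self.temperatures.size
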