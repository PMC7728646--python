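"""Feature extraction from fluorescence measurements.

Covers the three fluorescence-based probes of PSII status used when
characterising light acclimation:

* single-flash decay traces (double normalization to the pre-flash zero
  level and the post-flash maximum),
* OJIP induction transients (F0, FM, Fv/Fm, time of the fluorescence
  maximum, J- and I-step levels), and
* 77 K emission spectra (normalization to 713 nm and the PSII/PSI
  emission ratio, a stoichiometry proxy for the two photosystems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import Spectrum, TimeSeries

__all__ = [
    "InductionFeatures",
    "SpectrumFeatures",
    "double_normalize_decay",
    "induction_features",
    "normalize_spectrum_713",
    "psii_psi_ratio",
    "PSII_BAND",
    "PSI_BAND",
    "J_TIME_S",
    "I_TIME_S",
]

#: Search windows (nm) for the PSII and PSI 77 K emission maxima. They
#: bracket the classic ~686 nm (PSII core) and ~713-720 nm (PSI) bands.
PSII_BAND = (675.0, 700.0)
PSI_BAND = (705.0, 725.0)

#: Conventional OJIP step read-out times.
J_TIME_S = 2e-3
I_TIME_S = 30e-3


@dataclass
class InductionFeatures:
    """Landmarks of a chlorophyll fluorescence induction (OJIP) transient."""

    F0: float
    Fm: float
    t_Fm_ms: float
    step_values: dict = field(default_factory=dict)
    truncated: bool = False

    @property
    def FvFm(self) -> float:
        """Maximum quantum yield of PSII photochemistry, (Fm - F0)/Fm."""
        return (self.Fm - self.F0) / self.Fm


@dataclass
class SpectrumFeatures:
    """PSII and PSI emission maxima of a 77 K spectrum and their ratio."""

    psii_peak_nm: float
    psii_value: float
    psi_peak_nm: float
    psi_value: float

    @property
    def ratio(self) -> float:
        return self.psii_value / self.psi_value


def double_normalize_decay(raw: TimeSeries, F0_pre: float, Fmax: float) -> TimeSeries:
    """Double-normalize a flash decay trace.

    First to the zero fluorescence level measured before the flash
    (``F0_pre``), then to the maximum fluorescence after the single
    turnover flash (``Fmax``): v'(t) = (v(t) - F0_pre)/(Fmax - F0_pre).
    """
    if Fmax <= F0_pre:
        raise ValueError("Fmax must exceed the pre-flash zero level F0_pre")
    scale = Fmax - F0_pre
    return TimeSeries(raw.time.copy(), (raw.values - F0_pre) / scale,
                      kind=raw.kind, time_unit=raw.time_unit,
                      meta={**raw.meta, "F0_pre": F0_pre, "Fmax": Fmax})


def induction_features(trace: TimeSeries) -> InductionFeatures:
    """Extract F0, FM, Fv/Fm and step levels from an induction transient.

    F0 is read at the earliest recorded sample, FM is the global maximum
    and t_Fm its time. The J (2 ms) and I (30 ms) step levels are read by
    linear interpolation on a logarithmic time axis, matching the
    log-spaced sampling of induction fluorometers. A trace that is still
    rising at its last sample is flagged as truncated.
    """
    t, v = trace.time, trace.values
    if t[0] > 1e-4 or t[-1] < 1.0:
        raise ValueError("induction trace must cover 1e-4 s to 1 s")
    F0 = float(v[0])
    if F0 <= 0:
        raise ValueError("non-positive F0: earliest sample must be > 0")
    i_max = int(np.argmax(v))
    Fm = float(v[i_max])
    truncated = i_max == len(v) - 1 and np.all(np.diff(v) >= 0)
    if truncated:
        warnings.warn("truncated induction: trace still rising at the last sample")
    log_t = np.log10(t)
    steps = {
        "J": float(np.interp(np.log10(J_TIME_S), log_t, v)),
        "I": float(np.interp(np.log10(I_TIME_S), log_t, v)),
    }
    return InductionFeatures(F0=F0, Fm=Fm, t_Fm_ms=float(t[i_max] * 1e3),
                             step_values=steps, truncated=truncated)


def normalize_spectrum_713(spec: Spectrum) -> Spectrum:
    """Normalize a 77 K emission spectrum to its value at 713 nm."""
    ref = spec.value_at(713.0)
    if ref <= 0:
        raise ValueError("intensity at 713 nm must be positive to normalize")
    return Spectrum(spec.wavelengths.copy(), spec.intensities / ref,
                    meta={**spec.meta, "normalized_at_nm": 713.0, "norm_value": ref})


def _band_max(spec: Spectrum, band: tuple[float, float]) -> tuple[float, float]:
    mask = (spec.wavelengths >= band[0]) & (spec.wavelengths <= band[1])
    if not np.any(mask):
        raise ValueError(f"spectrum has no samples in the {band} nm band")
    w, v = spec.wavelengths[mask], spec.intensities[mask]
    i = int(np.argmax(v))
    return float(w[i]), float(v[i])


def psii_psi_ratio(spec: Spectrum) -> SpectrumFeatures:
    """PSII-to-PSI emission ratio of a 77 K spectrum.

    The PSII value is the maximum intensity in the 675-700 nm window, the
    PSI value the maximum in 705-725 nm. The ratio is scale invariant, so
    it is identical before and after 713 nm normalization.
    """
    psii_nm, psii_v = _band_max(spec, PSII_BAND)
    psi_nm, psi_v = _band_max(spec, PSI_BAND)
    if psi_v <= 0:
        raise ValueError("PSI band maximum must be positive")
    return SpectrumFeatures(psii_peak_nm=psii_nm, psii_value=psii_v,
                            psi_peak_nm=psi_nm, psi_value=psi_v)
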