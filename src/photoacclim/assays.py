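"""Pigment, singlet-oxygen, oxygen-evolution and growth statistics.

* Pigment quantification from methanol-extract absorbances via the
  Wellburn equations (spectrophotometer resolution 1-4 nm set).
* The SOSG slope statistic: the mean rate of increase of Singlet Oxygen
  Sensor Green fluorescence over three consecutive 10 min illumination
  periods, a relative rate of singlet-oxygen production.
* Normalization of oxygen-evolution rates per chlorophyll and per OD730.
* Threshold-crossing summaries of OD730 growth curves (the fraction of
  cultures that acclimated to extreme light by 24/48/96 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .containers import TimeSeries

__all__ = [
    "AbsorbanceTriplet",
    "PigmentResult",
    "OxygenRates",
    "AcclimationTable",
    "WELLBURN_CHL_A",
    "WELLBURN_CHL_B",
    "WELLBURN_CAR",
    "pigments_wellburn",
    "sosg_rate",
    "oxygen_rate_normalize",
    "photoinhibition_relative",
    "acclimation_table",
]

# Wellburn (1994) methanol coefficients, 1-4 nm resolution set:
#   chl_a = 16.72 A665.2 - 9.16 A652.4
#   chl_b = 34.09 A652.4 - 15.28 A665.2
#   car   = (1000 A470 - 1.63 chl_a - 104.96 chl_b) / 221
WELLBURN_CHL_A = (16.72, -9.16)      # (A665.2, A652.4)
WELLBURN_CHL_B = (-15.28, 34.09)
WELLBURN_CAR = (1000.0, -1.63, -104.96, 221.0)


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """Absorbances of a methanol pigment extract at 470, 652.4, 665.2 nm."""

    A470: float
    A652_4: float
    A665_2: float

    def __post_init__(self) -> None:
        if min(self.A470, self.A652_4, self.A665_2) < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass
class PigmentResult:
    """Pigment concentrations (µg/ml) and derived ratios."""

    chl_a: float
    chl_b: float
    carotenoids: float

    @property
    def chl_total(self) -> float:
        return self.chl_a + self.chl_b

    @property
    def chl_ab_ratio(self) -> Optional[float]:
        return self.chl_a / self.chl_b if self.chl_b > 0 else None

    @property
    def car_chl_ratio(self) -> Optional[float]:
        return self.carotenoids / self.chl_total if self.chl_total > 0 else None


@dataclass(frozen=True)
class OxygenRates:
    """Oxygen evolution normalized per chlorophyll and per OD730."""

    per_chl: float
    per_od: float


@dataclass(frozen=True)
class AcclimationTable:
    """Percentage of cultures whose OD730 reached the threshold by each horizon."""

    n_cultures: int
    pct_24h: float
    pct_48h: float
    pct_96h: float
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.pct_24h <= self.pct_48h <= self.pct_96h <= 100:
            raise ValueError("percentages must be non-decreasing in the horizon "
                             "and lie in [0, 100]")


def wellburn_matrix() -> np.ndarray:
    """Linear map from (A470, A652.4, A665.2) to (chl_a, chl_b, carotenoids)."""
    a665, a652 = WELLBURN_CHL_A
    b665, b652 = WELLBURN_CHL_B
    c470, c_a, c_b, denom = WELLBURN_CAR
    row_a = np.array([0.0, a652, a665])
    row_b = np.array([0.0, b652, b665])
    row_c = (np.array([c470, 0.0, 0.0]) + c_a * row_a + c_b * row_b) / denom
    return np.vstack([row_a, row_b, row_c])


def pigments_wellburn(absorbances: AbsorbanceTriplet,
                      dilution_factor: float = 1.0) -> PigmentResult:
    """Chlorophyll a, b and total carotenoid concentrations (µg/ml).

    Applies the Wellburn methanol equations to the absorbance triplet and
    multiplies by ``dilution_factor``. Slightly negative results (possible
    for noisy absorbances near zero pigment) are clipped to 0 with a
    warning; the map is otherwise linear through the origin.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    vec = np.array([absorbances.A470, absorbances.A652_4, absorbances.A665_2])
    chl_a, chl_b, car = wellburn_matrix() @ vec * dilution_factor
    # warn on genuinely negative results; round-off noise is clipped silently
    clipped = [n for n, v in (("chl_a", chl_a), ("chl_b", chl_b),
                              ("carotenoids", car)) if v < -1e-9]
    if clipped:
        warnings.warn(f"negative pigment value(s) clipped to 0: {clipped}")
    return PigmentResult(chl_a=max(chl_a, 0.0), chl_b=max(chl_b, 0.0),
                         carotenoids=max(car, 0.0))


def sosg_rate(series: TimeSeries, period_min: float = 10.0,
              n_periods: int = 3) -> float:
    """Mean SOSG fluorescence slope (a.u./min) over consecutive periods.

    The probe signal is sampled once per illumination period boundary, so
    each period's slope is the endpoint difference quotient
    (v(end) - v(start)) / period, and the statistic is the mean over the
    ``n_periods`` periods. Invariant to adding a constant to the signal.

    ``series.time`` must be in minutes and contain every period boundary
    0, P, 2P, ..., n*P (to within 1e-9 min).
    """
    if n_periods < 1:
        raise ValueError("need at least one period")
    boundaries = period_min * np.arange(n_periods + 1)
    values = []
    for b in boundaries:
        hits = np.flatnonzero(np.abs(series.time - b) < 1e-9)
        if hits.size == 0:
            raise ValueError(f"missing sample at period boundary t={b} min")
        values.append(series.values[hits[0]])
    slopes = np.diff(values) / period_min
    return float(np.mean(slopes))


def oxygen_rate_normalize(raw_rate: float, chl: float, od: float) -> OxygenRates:
    """Normalize a raw oxygen-evolution rate per chlorophyll and per OD730."""
    if chl <= 0 or od <= 0:
        raise ValueError("chlorophyll and OD must be positive")
    return OxygenRates(per_chl=raw_rate / chl, per_od=raw_rate / od)


def photoinhibition_relative(rates: TimeSeries, chl: float) -> TimeSeries:
    """Relative PSII activity: per-chlorophyll rates divided by the t=0 value.

    The measured oxygen evolution rates are first divided by the
    chlorophyll concentration and then by the pre-illumination (control)
    value of the same sample, so the output starts at exactly 1.
    """
    if chl <= 0:
        raise ValueError("chlorophyll concentration must be positive")
    per_chl = rates.values / chl
    if per_chl[0] <= 0:
        raise ValueError("initial rate must be positive for normalization")
    return TimeSeries(rates.time.copy(), per_chl / per_chl[0], kind=rates.kind,
                      time_unit=rates.time_unit,
                      meta={**rates.meta, "normalized": "relative"})


def acclimation_table(curves: Sequence[TimeSeries],
                      threshold: float = 0.05) -> AcclimationTable:
    """Threshold-crossing percentages of a set of OD730 growth curves.

    A culture counts towards horizon h (24/48/96 h) if its OD730 reached
    ``threshold`` at any sampled time up to and including h — horizons are
    cumulative, matching daily optical-density monitoring.
    """
    if len(curves) == 0:
        raise ValueError("need at least one growth curve")
    pct = {}
    for horizon in (24.0, 48.0, 96.0):
        n_crossed = sum(
            bool(np.any(c.values[c.time <= horizon + 1e-9] >= threshold))
            for c in curves)
        pct[horizon] = 100.0 * n_crossed / len(curves)
    return AcclimationTable(n_cultures=len(curves), pct_24h=pct[24.0],
                            pct_48h=pct[48.0], pct_96h=pct[96.0],
                            threshold=threshold)
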