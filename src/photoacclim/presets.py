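"""Phenotype presets for the synthetic instrument-data generators.

A :class:`FixturePreset` bundles the measurable phenotype of one culture
condition of *Chlamydomonas reinhardtii*: the rate constant of S2QA-
charge recombination, the rate constant of the damaging reaction of
photoinhibition (k_PI), chlorophyll-fluorescence induction landmarks,
the 77 K PSII/PSI emission ratio, thermoluminescence band positions,
the relative singlet-oxygen (SOSG) production rate, the equilibrium
oxygen-evolution rate under photoinhibitory light, chlorophyll content
at standard optical density, and the fraction of cultures that acclimate
to extreme light within 96 h.

Two presets ship with the package: ``control`` (cells grown at moderate
light, PPFD 100 µmol m-2 s-1) and ``EL`` (cells acclimated to extreme
light, PPFD 3000 µmol m-2 s-1, roughly 1.5x full sunlight).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["FixturePreset", "NoiseSpec", "PRESETS", "CONTROL", "EL", "get_preset"]


@dataclass(frozen=True)
class FixturePreset:
    """Named parameter set from which every synthetic fixture is generated.

    Attributes
    ----------
    k_recomb
        Rate constant of S2QA- recombination (s-1), measured from the
        DCMU-supplemented single-flash fluorescence decay.
    k_PI
        Rate constant of the damaging reaction of photoinhibition (s-1),
        measured with the repair inhibitor lincomycin present.
    F0_rel
        Minimal fluorescence F0 as a fraction of FM, so Fv/Fm = 1 - F0_rel.
    t_Fm_ms
        Time of maximal fluorescence in the induction transient (ms).
    psii_psi_ratio
        Ratio of the PSII (≈686 nm) to PSI (≈713 nm) 77 K emission maxima.
    tl_peak_Q, tl_peak_B
        Thermoluminescence Q- and B-band peak temperatures (°C).
    sosg_slope
        SOSG fluorescence increase per minute of red illumination (a.u./min,
        arbitrary absolute scale; only the EL/control ratio is meaningful).
    o2_eq_rate
        Equilibrium oxygen-evolution rate under photoinhibitory light
        without lincomycin (µmol O2 µg Chl-1 h-1).
    chl_per_od
        Chlorophyll concentration (µg/ml) of a culture diluted to OD730 0.5.
    acclim_fraction_96h
        Fraction of cultures whose OD730 reaches 0.05 within 96 h of
        transfer to extreme light.
    """

    name: str
    k_recomb: float
    k_PI: float
    F0_rel: float
    t_Fm_ms: float
    psii_psi_ratio: float
    tl_peak_Q: float
    tl_peak_B: float
    sosg_slope: float
    o2_eq_rate: float
    chl_per_od: float
    acclim_fraction_96h: float

    def __post_init__(self) -> None:
        for attr in ("k_recomb", "k_PI", "t_Fm_ms", "psii_psi_ratio",
                     "sosg_slope", "o2_eq_rate", "chl_per_od"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        if not 0.0 < self.F0_rel < 1.0:
            raise ValueError("F0_rel must lie in (0, 1)")
        if not 0.0 <= self.acclim_fraction_96h <= 1.0:
            raise ValueError("acclim_fraction_96h must lie in [0, 1]")

    @property
    def fv_fm(self) -> float:
        """Fv/Fm implied by the F0/FM fraction."""
        return 1.0 - self.F0_rel


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian measurement noise.

    A seed is mandatory whenever noise is enabled so that every fixture is
    reproducible; the same (seed, parameters) always yields the same draw.
    """

    enabled: bool = False
    sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.enabled and self.sd > 0 and self.seed is None:
            raise ValueError("a seed is required when noise is enabled")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if not self.enabled or self.sd == 0:
            return values
        rng = np.random.default_rng(self.seed)
        return values + rng.normal(0.0, self.sd, size=values.shape)


NO_NOISE = NoiseSpec()

CONTROL = FixturePreset(
    name="control",
    k_recomb=0.24,
    k_PI=1.47e-3,
    F0_rel=0.24,
    t_Fm_ms=161.0,
    psii_psi_ratio=1.5,
    tl_peak_Q=15.5,
    tl_peak_B=20.0,
    sosg_slope=1.0,
    o2_eq_rate=21.57,
    chl_per_od=11.08,
    acclim_fraction_96h=0.80,
)

EL = FixturePreset(
    name="EL",
    k_recomb=0.08,
    k_PI=1.38e-3,
    F0_rel=0.70,
    t_Fm_ms=161.0,
    psii_psi_ratio=0.95,
    tl_peak_Q=13.6,
    tl_peak_B=21.6,
    sosg_slope=0.102,
    o2_eq_rate=22.29,
    chl_per_od=3.89,
    acclim_fraction_96h=0.567,
)

PRESETS = {"control": CONTROL, "EL": EL}


def get_preset(name: str) -> FixturePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
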