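"""Synthetic instrument-data generators.

Every signal the analysis stages consume can be generated here from a
:class:`~photoacclim.presets.FixturePreset`, so the full pipeline —
simulate, analyze, fit — runs without any external dataset. The
generators are deterministic given (preset, arguments, seed) and are
built so that feeding their output back through the corresponding
analyzer recovers the preset parameter (exactly with noise off, within a
stated Monte-Carlo tolerance with noise on).

Shapes the presets do not pin down (OJIP sigmoid steepness, 77 K band
widths, the fast phase of the -DCMU flash decay) are phenomenological
choices that reproduce the qualitative control/EL contrasts; they are
documented as module constants below.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import assays, fluorescence
from .containers import GlowCurve, Spectrum, TimeSeries
from .kinetics import DamageRepairModel, simulate_damage_repair
from .presets import NO_NOISE, FixturePreset, NoiseSpec
from .thermoluminescence import ArrheniusModel, s_from_peak, simulate_glow

__all__ = [
    "gen_flash_decay",
    "gen_ojip",
    "gen_glow_curve",
    "gen_photoinhibition_series",
    "gen_77k_spectrum",
    "gen_sosg_series",
    "gen_growth_curves",
    "gen_pigment_absorbances",
]

#: First recorded point after the single turnover flash (s) and record length.
FLASH_T_FIRST = 3e-4
FLASH_DURATION = 120.0

#: Fast phase of the -DCMU flash decay (QA- -> QB electron transfer):
#: rate (s-1) and preset-dependent fraction. The fast phase is larger in
#: EL than in control cells; the slow tail decays at the preset's
#: recombination rate.
FAST_PHASE_RATE = 300.0
FAST_PHASE_FRACTION = {"control": 0.55, "EL": 0.75}

#: OJIP time base (s).
OJIP_T_MIN = 5e-5
OJIP_T_MAX = 2.0

#: 77 K emission band centres and Gaussian widths (nm).
PSII_CENTER_NM, PSII_SIGMA_NM = 686.0, 8.0
PSI_CENTER_NM, PSI_SIGMA_NM = 713.0, 12.0

#: Default initial activity for photoinhibition fixtures
#: (µmol O2 µg Chl-1 h-1); only the equilibrium level is phenotype-pinned.
PHOTOINHIBITION_A0 = 50.0


def _log_times(t_min: float, t_max: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(t_min), np.log10(t_max), n)


def gen_flash_decay(preset: FixturePreset, with_dcmu: bool = True,
                    duration: float = FLASH_DURATION,
                    noise: NoiseSpec = NO_NOISE,
                    n_points: int = 200) -> TimeSeries:
    """Single-turnover-flash fluorescence decay, log-sampled 0.3 ms-duration.

    With DCMU the QA- to QB electron transfer is blocked and the trace is a
    single exponential at the preset's S2QA- recombination rate (amplitude
    1, baseline 0). Without DCMU a fast reoxidation phase (rate
    ``FAST_PHASE_RATE``) precedes the recombination tail; its fractional
    amplitude is larger for the EL preset.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = _log_times(FLASH_T_FIRST, duration, n_points)
    if with_dcmu:
        v = np.exp(-preset.k_recomb * t)
    else:
        f = FAST_PHASE_FRACTION.get(preset.name, 0.6)
        v = f * np.exp(-FAST_PHASE_RATE * t) + (1 - f) * np.exp(-preset.k_recomb * t)
    return TimeSeries(t, noise.apply(v), kind="flash",
                      meta={"preset": preset.name, "with_dcmu": with_dcmu,
                            "seed": noise.seed})


def _sigmoid(u: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(u - center) / width))


def gen_ojip(preset: FixturePreset, with_dcmu: bool = False,
             n_points: int = 256) -> TimeSeries:
    """OJIP fluorescence induction transient on a logarithmic time base.

    The trace rises from F0 = F0_rel * FM at the first sample to FM = 1
    exactly at the preset's t_Fm (161 ms, inserted into the grid), then
    declines. The control (-DCMU) curve is a sum of O-J, J-I and I-P
    sigmoids in log time; the EL curve is dominated by a single O-J rise
    with no resolvable J-I transition and shows a pronounced post-peak
    decline. With DCMU a single sigmoidal O-J rise is produced.
    """
    t_fm = preset.t_Fm_ms * 1e-3
    t = np.unique(np.concatenate([
        _log_times(OJIP_T_MIN, OJIP_T_MAX, n_points),
        [fluorescence.J_TIME_S, fluorescence.I_TIME_S, t_fm],
    ]))
    u = np.log10(t)
    u_min, u_fm = u[0], np.log10(t_fm)

    if with_dcmu or preset.name == "EL":
        # single sigmoidal rise: the O-J transition carries the whole rise
        comps = [(1.0, np.log10(2e-3), 0.40)]
        decline = 0.8 if preset.name == "EL" else 0.1
    else:
        comps = [(0.50, np.log10(2e-3), 0.30),
                 (0.25, np.log10(3e-2), 0.25),
                 (0.25, np.log10(9e-2), 0.18)]
        decline = 0.05
    raw = sum(w * _sigmoid(u, c, s) for w, c, s in comps)
    raw_min = sum(w * _sigmoid(np.array([u_min]), c, s) for w, c, s in comps)[0]
    raw_fm = sum(w * _sigmoid(np.array([u_fm]), c, s) for w, c, s in comps)[0]
    rise = np.minimum((raw - raw_min) / (raw_fm - raw_min), 1.0)
    post = np.where(u > u_fm, np.exp(-decline * (u - u_fm)), 1.0)

    fm = 1.0
    f0 = preset.F0_rel * fm
    v = f0 + (fm - f0) * rise * post
    return TimeSeries(t, v, kind="ojip",
                      meta={"preset": preset.name, "with_dcmu": with_dcmu})


def gen_glow_curve(peak_T_c: float, Ea: float = 0.501, beta: float = 0.66,
                   T0: float = 274.0, Tend: float = 340.0,
                   noise: NoiseSpec = NO_NOISE, dT: float = 0.01) -> GlowCurve:
    """Randall–Wilkins glow band peaking at ``peak_T_c`` (°C).

    The pre-exponential factor is obtained by closed-form inversion of the
    first-order peak condition, so the simulated band peaks at the
    requested temperature to within the grid resolution. Additive noise is
    clipped at zero (luminescence counts cannot be negative).
    """
    T_m = peak_T_c + 273.15
    if not T0 < T_m < Tend:
        raise ValueError(f"peak_T {peak_T_c} °C outside the heating ramp")
    s = s_from_peak(T_m, Ea=Ea, beta=beta, T0=T0, Tend=Tend)
    curve = simulate_glow(ArrheniusModel(s=s, Ea=Ea, T0=T0, beta=beta, Tend=Tend),
                          dT=dT)
    intensities = np.clip(noise.apply(curve.intensities), 0.0, None)
    return GlowCurve(curve.temperatures, intensities, beta=beta, T0=T0,
                     meta={**curve.meta, "peak_T_c": peak_T_c, "seed": noise.seed})


def gen_photoinhibition_series(preset: FixturePreset, lincomycin: bool,
                               duration: float = 3600.0, interval: float = 600.0,
                               A0: float = PHOTOINHIBITION_A0,
                               noise: NoiseSpec = NO_NOISE) -> TimeSeries:
    """Oxygen-evolution time course under photoinhibitory light.

    With lincomycin, repair is blocked and activity decays as a pure first
    order at the preset's k_PI. Without lincomycin, the damage-repair
    closed form is used with the repair rate constant chosen so that the
    equilibrium activity equals the preset's printed plateau rate.
    Sampled every ``interval`` s (default 10 min) from 0 to ``duration``.
    """
    if A0 <= 0:
        raise ValueError("initial activity A0 must be positive")
    if interval <= 0 or duration < interval:
        raise ValueError("need interval > 0 and duration >= interval")
    t = np.arange(0.0, duration + interval / 2, interval)
    if lincomycin:
        v = A0 * np.exp(-preset.k_PI * t)
        meta = {"preset": preset.name, "lincomycin": True, "A0": A0}
    else:
        a_eq = preset.o2_eq_rate
        if a_eq >= A0:
            raise ValueError("equilibrium rate must be below A0")
        k_rec = preset.k_PI * a_eq / (A0 - a_eq)
        series = simulate_damage_repair(
            DamageRepairModel(k_PI=preset.k_PI, k_rec=k_rec, A0=A0), t)
        v = series.values
        meta = {"preset": preset.name, "lincomycin": False, **series.meta}
    return TimeSeries(t, noise.apply(v), kind="o2",
                      meta={**meta, "seed": noise.seed})


def _gaussian(w: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / sigma) ** 2)


def gen_77k_spectrum(preset: FixturePreset,
                     wl_min: float = 650.0, wl_max: float = 780.0,
                     step: float = 0.5) -> Spectrum:
    """77 K fluorescence emission spectrum with a preset PSII/PSI ratio.

    The spectrum is the sum of two Gaussian bands (PSII near 686 nm, PSI
    near 713 nm). The PSII amplitude is solved numerically so that the
    band-maximum ratio measured by
    :func:`photoacclim.fluorescence.psii_psi_ratio` equals the preset value
    — the enforcement is on the measured statistic, not on the raw
    amplitudes, because the bands overlap.
    """
    w = np.arange(wl_min, wl_max + step / 2, step)
    g_psii = _gaussian(w, PSII_CENTER_NM, PSII_SIGMA_NM)
    g_psi = _gaussian(w, PSI_CENTER_NM, PSI_SIGMA_NM)

    def measured_ratio(a_psii: float) -> float:
        spec = Spectrum(w, a_psii * g_psii + g_psi)
        return fluorescence.psii_psi_ratio(spec).ratio

    target = preset.psii_psi_ratio
    a = brentq(lambda x: measured_ratio(x) - target, 1e-9, 100.0, xtol=1e-12)
    return Spectrum(w, a * g_psii + g_psi,
                    meta={"preset": preset.name, "psii_amplitude": a})


def gen_sosg_series(preset: FixturePreset, n_periods: int = 3,
                    period_min: float = 10.0, noise: NoiseSpec = NO_NOISE,
                    dark_control: bool = False) -> TimeSeries:
    """SOSG fluorescence sampled at every illumination-period boundary.

    The signal increases linearly at the preset's slope (a.u./min); the
    dark-control variant has slope 0. Time axis is in minutes.
    """
    if n_periods < 3:
        raise ValueError("need at least 3 illumination periods")
    t = period_min * np.arange(n_periods + 1)
    slope = 0.0 if dark_control else preset.sosg_slope
    v = slope * t
    return TimeSeries(t, noise.apply(v), kind="sosg", time_unit="min",
                      meta={"preset": preset.name, "dark_control": dark_control,
                            "seed": noise.seed})


#: OD730 sampling times of the extreme-light growth experiment (h).
GROWTH_TIMES_H = np.array([0.0, 24.0, 48.0, 96.0])
GROWTH_OD_START = 0.01
GROWTH_THRESHOLD = 0.05


def gen_growth_curves(preset: FixturePreset, n_cultures: int = 30,
                      seed: int = 0) -> list[TimeSeries]:
    """OD730 growth curves of cultures transferred to extreme light.

    All cultures start at OD730 0.01 and dip during the first 24 h (death
    of part of the population). A seeded draw marks
    round(acclim_fraction_96h * n_cultures) cultures as acclimating: these
    resume exponential growth and cross OD730 0.05 between 48 h and 96 h.
    The rest stay below the threshold for the whole experiment.
    """
    if n_cultures < 1:
        raise ValueError("need at least one culture")
    rng = np.random.default_rng(seed)
    n_acc = int(round(preset.acclim_fraction_96h * n_cultures))
    acclimating = np.zeros(n_cultures, dtype=bool)
    acclimating[rng.permutation(n_cultures)[:n_acc]] = True

    curves = []
    for i in range(n_cultures):
        u = rng.uniform(-1.0, 1.0, size=3)
        if acclimating[i]:
            od = [GROWTH_OD_START,
                  0.006 + 0.002 * u[0],   # initial die-off
                  0.025 + 0.010 * u[1],   # regrowth, still below threshold
                  0.110 + 0.040 * u[2]]   # crossed 0.05 well before 96 h
        else:
            od = [GROWTH_OD_START,
                  0.006 + 0.002 * u[0],
                  0.008 + 0.003 * u[1],
                  0.015 + 0.010 * u[2]]   # never reaches 0.05
        curves.append(TimeSeries(GROWTH_TIMES_H, np.array(od), kind="od",
                                 time_unit="h",
                                 meta={"preset": preset.name, "seed": seed,
                                       "acclimating": bool(acclimating[i])}))
    return curves


def gen_pigment_absorbances(chl_a: float, chl_b: float,
                            car: float) -> assays.AbsorbanceTriplet:
    """Absorbance triplet whose Wellburn inversion yields the given pigments.

    Solves the 3x3 linear Wellburn system for (A470, A652.4, A665.2), so
    :func:`photoacclim.assays.pigments_wellburn` applied to the result
    returns the input concentrations (µg/ml). Used for roundtrip testing
    of the pigment equations.
    """
    if min(chl_a, chl_b, car) < 0:
        raise ValueError("pigment concentrations must be non-negative")
    vec = np.linalg.solve(assays.wellburn_matrix(),
                          np.array([chl_a, chl_b, car]))
    # the inverse map preserves non-negativity; clip round-off only
    a470, a652, a665 = np.where(np.abs(vec) < 1e-15, 0.0, vec)
    return assays.AbsorbanceTriplet(A470=float(a470), A652_4=float(a652),
                                    A665_2=float(a665))
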