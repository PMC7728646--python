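"""End-to-end simulate → analyze → fit roundtrips.

`roundtrip_report` regenerates every synthetic fixture from its preset,
pushes it through the corresponding analysis operator and collects the
recovered value next to the preset (expected) value. This is the
package's main self-check: the generators are parameterized by the
phenotype constants and the analyzers must recover them through
realistic instrument-shaped data.
"""

from __future__ import annotations

import logging

from . import assays, fluorescence, kinetics, synthetic
from .presets import PRESETS, get_preset
from .thermoluminescence import band_features

__all__ = ["roundtrip_report", "format_report"]

log = logging.getLogger(__name__)


def _flash_k(preset, seed: int) -> tuple[float, int]:
    series = synthetic.gen_flash_decay(preset, with_dcmu=True)
    norm = fluorescence.double_normalize_decay(series, F0_pre=0.0,
                                               Fmax=float(series.values.max()))
    fit = kinetics.fit_first_order(norm, fit_baseline=False, role="recombination")
    return fit.k, fit.n_points


def _kpi(preset, seed: int) -> tuple[float, int]:
    series = synthetic.gen_photoinhibition_series(preset, lincomycin=True,
                                                  duration=3600.0, interval=600.0)
    rel = assays.photoinhibition_relative(series, chl=preset.chl_per_od)
    fit = kinetics.kpi_from_oxygen(rel)
    return fit.k, fit.n_points


def _fvfm(preset, seed: int) -> tuple[float, int]:
    feats = fluorescence.induction_features(synthetic.gen_ojip(preset))
    return feats.FvFm, 0


def _ratio77k(preset, seed: int) -> tuple[float, int]:
    spec = fluorescence.normalize_spectrum_713(synthetic.gen_77k_spectrum(preset))
    return fluorescence.psii_psi_ratio(spec).ratio, len(spec)


def _tl_peak(preset, band: str, seed: int) -> tuple[float, int]:
    peak = preset.tl_peak_B if band == "B" else preset.tl_peak_Q
    curve = synthetic.gen_glow_curve(peak)
    return band_features(curve).T_peak_c, len(curve)


def _o2_equilibrium(preset, seed: int) -> tuple[float, int]:
    series = synthetic.gen_photoinhibition_series(preset, lincomycin=False,
                                                  duration=3600.0, interval=600.0)
    model = kinetics.fit_damage_repair(series, k_PI_fixed=preset.k_PI)
    return model.A_eq, len(series)


def _sosg_ratio(seed: int) -> tuple[float, int]:
    rates = {name: assays.sosg_rate(synthetic.gen_sosg_series(p))
             for name, p in PRESETS.items()}
    return 100.0 * rates["EL"] / rates["control"], 4


def _acclim_pct(preset, n_cultures: int, seed: int) -> tuple[float, int]:
    curves = synthetic.gen_growth_curves(preset, n_cultures=n_cultures, seed=seed)
    return assays.acclimation_table(curves).pct_96h, n_cultures


def roundtrip_report(seed: int = 0) -> dict:
    """Run every fixture → analysis roundtrip and return a nested report.

    Each entry maps a quantity to ``{"expected": preset value,
    "recovered": analyzed value, "n": problem size}``. ``seed`` drives the
    only stochastic fixture (the growth curves); all other fixtures are
    generated noise-free and analyzed deterministically.
    """
    report: dict = {}
    for name, preset in PRESETS.items():
        entries = {}
        k, n = _flash_k(preset, seed)
        entries["k_recomb_s-1"] = {"expected": preset.k_recomb,
                                   "recovered": k, "n": n}
        k, n = _kpi(preset, seed)
        entries["k_PI_s-1"] = {"expected": preset.k_PI, "recovered": k, "n": n}
        v, n = _fvfm(preset, seed)
        entries["Fv_over_Fm"] = {"expected": preset.fv_fm, "recovered": v, "n": n}
        v, n = _ratio77k(preset, seed)
        entries["psii_psi_ratio_77K"] = {"expected": preset.psii_psi_ratio,
                                         "recovered": v, "n": n}
        for band in ("Q", "B"):
            v, n = _tl_peak(preset, band, seed)
            expected = preset.tl_peak_Q if band == "Q" else preset.tl_peak_B
            entries[f"tl_peak_{band}_C"] = {"expected": expected,
                                            "recovered": v, "n": n}
        v, n = _o2_equilibrium(preset, seed)
        entries["o2_equilibrium_rate"] = {"expected": preset.o2_eq_rate,
                                          "recovered": v, "n": n}
        v, n = _acclim_pct(preset, 30, seed)
        entries["acclimated_pct_96h"] = {
            "expected": 100.0 * preset.acclim_fraction_96h, "recovered": v, "n": n}
        report[name] = entries
        log.info("roundtrips for preset %s done (seed=%d)", name, seed)

    v, n = _sosg_ratio(seed)
    report["sosg_ratio_EL_over_control_pct"] = {"expected": 10.2,
                                                "recovered": v, "n": n}
    return report


def format_report(report: dict) -> str:
    """Human-readable table of expected vs recovered values."""
    lines = [f"{'quantity':<38} {'expected':>12} {'recovered':>12}"]
    lines.append("-" * 64)

    def _emit(prefix: str, entry: dict) -> None:
        lines.append(f"{prefix:<38} {entry['expected']:>12.6g} "
                     f"{entry['recovered']:>12.6g}")

    for key, val in report.items():
        if "recovered" in val:
            _emit(key, val)
        else:
            for sub, entry in val.items():
                _emit(f"{key}.{sub}", entry)
    return "\n".join(lines)
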