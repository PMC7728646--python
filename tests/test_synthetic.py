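"""Determinism and analysis roundtrips of the synthetic-data generators."""

import numpy as np
import pytest

from photoacclim.fluorescence import double_normalize_decay
from photoacclim.kinetics import fit_first_order
from photoacclim.presets import CONTROL, EL, FixturePreset, NoiseSpec
from photoacclim.synthetic import (gen_flash_decay, gen_glow_curve,
                                   gen_growth_curves, gen_ojip,
                                   gen_photoinhibition_series, gen_sosg_series)
from photoacclim.thermoluminescence import band_features


class TestFlashDecay:
    def test_value_at_inverse_rate_is_e_minus_one(self):
        """Definition of exponential decay: v(1/k) = e^-1 * amplitude."""
        series = gen_flash_decay(CONTROL, with_dcmu=True)
        v = np.interp(1.0 / CONTROL.k_recomb, series.time, series.values)
        assert v == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_dcmu_fixture_roundtrips_recombination_rate(self, preset):
        series = gen_flash_decay(preset, with_dcmu=True)
        fit = fit_first_order(series)
        assert fit.k == pytest.approx(preset.k_recomb, rel=1e-8)

    def test_noisy_el_fixture_fit_bias_below_5pct(self):
        """Monte-Carlo over 50 seeds: mean fitted k within 5% of 0.08 s^-1."""
        ks = []
        for seed in range(50):
            noise = NoiseSpec(enabled=True, sd=0.01, seed=seed)
            series = gen_flash_decay(EL, with_dcmu=True, noise=noise)
            ks.append(fit_first_order(series).k)
        assert np.mean(ks) == pytest.approx(EL.k_recomb, rel=0.05)

    def test_fast_phase_larger_in_el(self):
        """-DCMU decay: early loss of fluorescence larger for EL cells."""
        t_probe = 5e-3  # after the fast phase, before recombination matters
        ctrl = gen_flash_decay(CONTROL, with_dcmu=False)
        el = gen_flash_decay(EL, with_dcmu=False)
        assert np.interp(t_probe, el.time, el.values) < \
            np.interp(t_probe, ctrl.time, ctrl.values)

    def test_deterministic_given_seed(self):
        noise = NoiseSpec(enabled=True, sd=0.02, seed=7)
        a = gen_flash_decay(CONTROL, noise=noise)
        b = gen_flash_decay(CONTROL, noise=noise)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            gen_flash_decay(CONTROL, duration=0.0)

    def test_seed_required_when_noise_enabled(self):
        with pytest.raises(ValueError, match="seed"):
            NoiseSpec(enabled=True, sd=0.01, seed=None)


class TestOjip:
    def test_trace_rises_from_f0_to_fm_at_t_fm(self, preset):
        trace = gen_ojip(preset)
        assert trace.values[0] == pytest.approx(preset.F0_rel, rel=1e-12)
        i_max = np.argmax(trace.values)
        assert trace.time[i_max] == pytest.approx(preset.t_Fm_ms * 1e-3)
        assert trace.values[i_max] == pytest.approx(1.0)

    def test_el_declines_after_peak_more_than_control(self):
        ctrl, el = gen_ojip(CONTROL), gen_ojip(EL)
        drop = lambda tr: 1.0 - tr.values[-1] / tr.values.max()
        assert drop(el) > drop(ctrl) > 0.0

    def test_dcmu_trace_is_single_rise(self):
        trace = gen_ojip(CONTROL, with_dcmu=True)
        rising = trace.values[trace.time <= 0.161]
        assert np.all(np.diff(rising) >= -1e-12)


class TestGlowCurveFixture:
    @pytest.mark.parametrize("peak_c", [13.6, 15.5, 20.0, 21.6])
    def test_peak_roundtrip_within_grid_resolution(self, peak_c):
        curve = gen_glow_curve(peak_c, dT=0.01)
        feats = band_features(curve)
        assert feats.T_peak_c == pytest.approx(peak_c, abs=0.01)

    def test_noise_free_curves_identical(self):
        a, b = gen_glow_curve(20.0), gen_glow_curve(20.0)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_peak_outside_ramp_rejected(self):
        with pytest.raises(ValueError, match="ramp"):
            gen_glow_curve(80.0)


class TestPhotoinhibitionSeries:
    def test_lincomycin_series_decays_toward_zero(self):
        series = gen_photoinhibition_series(CONTROL, lincomycin=True,
                                            duration=36000.0, interval=3600.0)
        assert series.values[-1] < 1e-4 * series.values[0]

    def test_no_lincomycin_plateau_is_preset_equilibrium(self, preset):
        series = gen_photoinhibition_series(preset, lincomycin=False,
                                            duration=7200.0, interval=600.0)
        assert series.values[-1] == pytest.approx(preset.o2_eq_rate, rel=1e-6)

    def test_nonpositive_a0_rejected(self):
        with pytest.raises(ValueError, match="A0"):
            gen_photoinhibition_series(CONTROL, lincomycin=True, A0=0.0)


class TestGrowthCurves:
    def test_all_curves_start_at_od_0_01(self):
        for curve in gen_growth_curves(CONTROL, n_cultures=10, seed=3):
            assert curve.values[0] == 0.01

    def test_acclimating_count_matches_preset_fraction(self):
        curves = gen_growth_curves(CONTROL, n_cultures=30, seed=5)
        n_acc = sum(c.meta["acclimating"] for c in curves)
        assert n_acc == round(0.80 * 30)

    def test_zero_fraction_never_crosses_threshold(self):
        preset = FixturePreset(name="dead", k_recomb=0.1, k_PI=1e-3,
                               F0_rel=0.5, t_Fm_ms=161.0, psii_psi_ratio=1.0,
                               tl_peak_Q=15.0, tl_peak_B=20.0, sosg_slope=1.0,
                               o2_eq_rate=20.0, chl_per_od=10.0,
                               acclim_fraction_96h=0.0)
        curves = gen_growth_curves(preset, n_cultures=12, seed=1)
        assert all(c.values.max() < 0.05 for c in curves)

    def test_same_seed_reproduces_curves(self):
        a = gen_growth_curves(EL, n_cultures=8, seed=9)
        b = gen_growth_curves(EL, n_cultures=8, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.values, cb.values)


class TestNormalizationChain:
    def test_double_normalized_fixture_still_fits_preset_rate(self, preset):
        """Full chain: generate, double-normalize, fit."""
        series = gen_flash_decay(preset, with_dcmu=True)
        norm = double_normalize_decay(series, F0_pre=0.0,
                                      Fmax=float(series.values.max()))
        assert fit_first_order(norm).k == pytest.approx(preset.k_recomb,
                                                        rel=1e-6)
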