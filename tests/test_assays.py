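"""Pigment equations, SOSG slope statistic, O2 normalization, growth table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoacclim.assays import (AbsorbanceTriplet, acclimation_table,
                                oxygen_rate_normalize,
                                photoinhibition_relative, pigments_wellburn,
                                sosg_rate, wellburn_matrix)
from photoacclim.containers import TimeSeries
from photoacclim.presets import CONTROL, EL
from photoacclim.synthetic import (gen_growth_curves, gen_pigment_absorbances,
                                   gen_sosg_series)

nonneg = st.floats(0.0, 100.0, allow_nan=False)


class TestPigments:
    def test_zero_absorbances_give_zero_pigments(self):
        res = pigments_wellburn(AbsorbanceTriplet(0.0, 0.0, 0.0))
        assert res.chl_a == res.chl_b == res.carotenoids == res.chl_total == 0.0

    def test_direct_evaluation_of_chl_a_equation(self):
        # chl_a = 16.72*0.1 - 9.16*0.05 = 1.214 µg/ml
        res = pigments_wellburn(AbsorbanceTriplet(A470=0.2, A652_4=0.05,
                                                  A665_2=0.1))
        assert res.chl_a == pytest.approx(1.214, abs=1e-12)
        assert res.chl_b == pytest.approx(34.09 * 0.05 - 15.28 * 0.1, abs=1e-12)
        expected_car = (1000 * 0.2 - 1.63 * res.chl_a - 104.96 * res.chl_b) / 221
        assert res.carotenoids == pytest.approx(expected_car, abs=1e-12)

    def test_dilution_factor_scales_linearly(self):
        triplet = AbsorbanceTriplet(0.2, 0.05, 0.1)
        assert pigments_wellburn(triplet, 4.0).chl_a == pytest.approx(
            4.0 * pigments_wellburn(triplet).chl_a)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(chl_a=nonneg, chl_b=nonneg, car=nonneg)
    def test_absorbance_roundtrip_recovers_concentrations(self, chl_a, chl_b, car):
        """Linear-solve inversion then Wellburn equations is the identity."""
        triplet = gen_pigment_absorbances(chl_a, chl_b, car)
        res = pigments_wellburn(triplet)
        assert res.chl_a == pytest.approx(chl_a, abs=1e-9)
        assert res.chl_b == pytest.approx(chl_b, abs=1e-9)
        assert res.carotenoids == pytest.approx(car, abs=1e-9)

    def test_map_is_linear_in_absorbances(self):
        m = wellburn_matrix()
        v1, v2 = np.array([0.1, 0.2, 0.3]), np.array([0.05, 0.0, 0.4])
        np.testing.assert_allclose(m @ (2 * v1 + v2), 2 * (m @ v1) + m @ v2,
                                   rtol=1e-13)

    def test_negative_result_clipped_with_warning(self):
        # high A652.4 alone drives chl_a negative
        with pytest.warns(UserWarning, match="clipped"):
            res = pigments_wellburn(AbsorbanceTriplet(0.0, 1.0, 0.0))
        assert res.chl_a == 0.0


class TestSosgRate:
    def test_constant_signal_has_zero_slope(self):
        t = np.arange(0.0, 31.0, 10.0)
        assert sosg_rate(TimeSeries(t, np.full(4, 7.0), time_unit="min")) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m=st.floats(-5.0, 5.0), offset=st.floats(-10.0, 10.0))
    def test_linear_signal_returns_its_slope(self, m, offset):
        """Exactly linear series of slope m -> m, invariant to offsets."""
        t = np.arange(0.0, 31.0, 10.0)
        series = TimeSeries(t, offset + m * t, time_unit="min")
        assert sosg_rate(series) == pytest.approx(m, abs=1e-9)

    def test_el_to_control_ratio_is_10_2_percent(self):
        rates = {p.name: sosg_rate(gen_sosg_series(p)) for p in (CONTROL, EL)}
        assert 100.0 * rates["EL"] / rates["control"] == pytest.approx(10.2,
                                                                       abs=1e-9)

    def test_dark_control_is_flat(self):
        series = gen_sosg_series(CONTROL, dark_control=True)
        assert sosg_rate(series) == 0.0

    def test_slopes_constant_across_periods(self):
        series = gen_sosg_series(CONTROL)
        slopes = np.diff(series.values) / np.diff(series.time)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_missing_boundary_rejected(self):
        series = TimeSeries([0.0, 10.0, 20.0, 25.0], [0, 1, 2, 3],
                            time_unit="min")
        with pytest.raises(ValueError, match="boundary"):
            sosg_rate(series)


class TestOxygenNormalization:
    def test_unit_denominators_are_identity(self):
        rates = oxygen_rate_normalize(12.5, chl=1.0, od=1.0)
        assert rates.per_chl == rates.per_od == 12.5

    def test_doubling_chl_halves_per_chl_rate(self):
        assert oxygen_rate_normalize(10.0, chl=2.0, od=0.5).per_chl == \
            pytest.approx(oxygen_rate_normalize(10.0, 1.0, 0.5).per_chl / 2)

    def test_chl_presets_imply_per_chl_contrast(self):
        """Equal per-OD rates imply EL per-Chl rate ~2.85x the control."""
        raw = 100.0
        ctrl = oxygen_rate_normalize(raw, CONTROL.chl_per_od, 0.5)
        el = oxygen_rate_normalize(raw, EL.chl_per_od, 0.5)
        assert el.per_od == ctrl.per_od
        assert el.per_chl / ctrl.per_chl == pytest.approx(11.08 / 3.89, rel=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            oxygen_rate_normalize(1.0, chl=0.0, od=1.0)


class TestPhotoinhibitionRelative:
    def test_first_point_is_one(self):
        t = np.arange(0.0, 3000.0, 600.0)
        rel = photoinhibition_relative(TimeSeries(t, 50.0 * np.exp(-1e-3 * t)),
                                       chl=8.93)
        assert rel.values[0] == 1.0

    def test_exponential_input_independent_of_chl(self):
        t = np.arange(0.0, 3000.0, 600.0)
        raw = TimeSeries(t, 50.0 * np.exp(-1.47e-3 * t))
        a = photoinhibition_relative(raw, chl=8.93).values
        b = photoinhibition_relative(raw, chl=4.87).values
        np.testing.assert_allclose(a, b, rtol=1e-14)
        np.testing.assert_allclose(a, np.exp(-1.47e-3 * t), rtol=1e-12)

    def test_zero_initial_rate_rejected(self):
        with pytest.raises(ValueError, match="initial rate"):
            photoinhibition_relative(TimeSeries([0.0, 1.0, 2.0], [0.0, 1, 2]),
                                     chl=1.0)


class TestAcclimationTable:
    def test_table_percentages_for_both_inoculum_types(self):
        """n=30 fixtures reproduce the 96 h acclimation percentages."""
        for preset, expected in ((CONTROL, 80.0), (EL, 56.7)):
            curves = gen_growth_curves(preset, n_cultures=30, seed=11)
            table = acclimation_table(curves)
            assert round(table.pct_96h, 1) == expected
            assert table.pct_24h == 0.0

    def test_no_crossings_gives_zero_row(self):
        t = [0.0, 24.0, 48.0, 96.0]
        curves = [TimeSeries(t, [0.01, 0.008, 0.01, 0.02], time_unit="h")
                  for _ in range(5)]
        table = acclimation_table(curves)
        assert (table.pct_24h, table.pct_48h, table.pct_96h) == (0.0, 0.0, 0.0)

    def test_percentages_cumulative_in_horizon(self):
        for seed in range(5):
            curves = gen_growth_curves(CONTROL, n_cultures=20, seed=seed)
            table = acclimation_table(curves)
            assert table.pct_24h <= table.pct_48h <= table.pct_96h

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            acclimation_table([])
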