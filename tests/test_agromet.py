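"""Reference ET, Kc curves, crop ET arithmetic and salinity leaching."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquafoot.agromet import (
    KcProfile,
    MeteoRecord,
    build_kc_curve,
    crop_et_series,
    effective_rainfall,
    gross_irrigation,
    leaching_depth,
    leaching_fraction,
    penman_monteith_eto,
    water_requirement_q,
)
from aquafoot.fixtures import kc_profile_for


def _record(**kw):
    defaults = dict(
        date=date(2016, 6, 1), tmean_c=25.0, u2_ms=2.0, rn_mj=15.0,
        es_kpa=3.17, ea_kpa=1.5, rain_mm=0.0,
    )
    defaults.update(kw)
    return MeteoRecord(**defaults)


class TestPenmanMonteith:
    def test_zero_forcing_gives_zero_eto(self):
        rec = _record(rn_mj=0.0, g_mj=0.0, u2_ms=0.0)
        assert penman_monteith_eto(rec) == 0.0

    def test_radiative_term_hand_value(self):
        # u2 = 0 leaves only the radiation term: 0.408*Delta*(Rn-G)/(Delta+gamma)
        # with Delta(25 C) = 0.1887 kPa/C and sea-level gamma = 0.0674 kPa/C.
        rec = _record(u2_ms=0.0, rn_mj=10.0, g_mj=0.0)
        assert penman_monteith_eto(rec, elevation_m=0.0) == pytest.approx(3.01, abs=0.02)

    def test_eto_strictly_increases_with_wind_under_vpd(self):
        etos = [
            penman_monteith_eto(_record(u2_ms=u)) for u in (0.0, 1.0, 2.0, 5.0, 8.0)
        ]
        assert all(b > a for a, b in zip(etos, etos[1:]))

    def test_missing_forcing_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient forcing"):
            penman_monteith_eto(_record(rn_mj=None))

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            _record(u2_ms=-1.0)
        with pytest.raises(ValueError):
            _record(ea_kpa=5.0)  # exceeds es
        with pytest.raises(ValueError):
            MeteoRecord(date=date(2016, 1, 1), tmean_c=30.0, tmin_c=10.0, tmax_c=20.0)


class TestEffectiveRainfall:
    @pytest.mark.parametrize(
        "p_tot, expected",
        [(0.0, 0.0), (13.6, 13.30), (8.9, 8.77)],
    )
    def test_hand_values(self, p_tot, expected):
        assert effective_rainfall(p_tot) == pytest.approx(expected, abs=0.005)

    @given(st.floats(min_value=0.0, max_value=312.5))
    @settings(max_examples=60, derandomize=True)
    def test_bounded_by_total(self, p):
        assert 0.0 <= effective_rainfall(p) <= p

    @given(st.floats(min_value=0.0, max_value=312.4))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_on_physical_range(self, p):
        assert effective_rainfall(p + 0.1) >= effective_rainfall(p)


class TestKcCurve:
    @pytest.fixture()
    def maize_spring(self):
        return kc_profile_for("maize", "spring")

    def test_stage_values_match_tabulation(self, maize_spring):
        curve = build_kc_curve(maize_spring)  # native 120-day profile
        assert curve[0] == pytest.approx(0.45)
        assert curve[24] == pytest.approx(0.45)        # last initial-stage day
        assert curve[70] == pytest.approx(1.15)        # mid-season plateau
        assert curve[-1] == pytest.approx(1.00)        # end of late decline

    def test_development_ramp_midpoint(self, maize_spring):
        # dev stage spans days 26..65; its midpoint carries the tabulated
        # developmental coefficient (0.45 + 1.15)/2 = 0.80
        curve = build_kc_curve(maize_spring)
        assert curve[25 + 19] == pytest.approx(0.80)

    def test_rescaled_length_and_bounds(self, maize_spring):
        for lgp in (4, 37, 80, 90, 200):
            curve = build_kc_curve(maize_spring, lgp)
            assert curve.size == lgp
            assert curve.min() >= 0.45 - 1e-12
            assert curve.max() <= 1.15 + 1e-12

    def test_too_short_season_rejected(self, maize_spring):
        with pytest.raises(ValueError):
            build_kc_curve(maize_spring, 3)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            KcProfile("x", "s", 10, 0, 10, 10, 0.4, 0.8, 1.1, 0.9)
        with pytest.raises(ValueError):
            KcProfile("x", "s", 10, 10, 10, 10, 0.4, 0.8, 1.7, 0.9)


class TestCropEtSeries:
    def _dates(self, n):
        return [date(2016, 4, 1) + timedelta(days=i) for i in range(n)]

    def test_identity_and_zero_coefficients(self):
        eto = np.full(30, 7.0)
        s1 = crop_et_series(self._dates(30), eto, np.ones(30))
        assert s1.cwr_mm == pytest.approx(eto.sum())
        s0 = crop_et_series(self._dates(30), eto, np.zeros(30) + 1e-9)
        assert s0.cwr_mm == pytest.approx(0.0, abs=1e-6)

    def test_against_day_loop_oracle(self):
        rng = np.random.default_rng(42)
        n = 80
        eto = rng.uniform(2.0, 18.0, n)
        kc = rng.uniform(0.3, 1.3, n)
        rain = np.where(rng.random(n) < 0.05, rng.uniform(0, 12, n), 0.0)
        series = crop_et_series(self._dates(n), eto, kc, rain)

        cwr = green = blue = 0.0
        for i in range(n):
            etc = eto[i] * kc[i]
            p_eff = rain[i] * (125 - 0.2 * rain[i]) / 125
            cwr += etc
            green += min(etc, p_eff)
            blue += max(0.0, etc - p_eff)
        assert series.cwr_mm == pytest.approx(cwr, abs=1e-9)
        assert series.et_green.sum() == pytest.approx(green, abs=1e-9)
        assert series.et_blue.sum() == pytest.approx(blue, abs=1e-9)
        # per-day conservation whenever rain does not exceed demand
        ok = series.p_eff <= series.etc
        np.testing.assert_allclose(
            (series.et_green + series.et_blue)[ok], series.etc[ok], atol=1e-12
        )

    def test_uniform_eto_closed_form(self):
        n, eto_day = 80, 11.2
        kc = np.full(n, 1.02)
        series = crop_et_series(self._dates(n), np.full(n, eto_day), kc)
        assert series.cwr_mm == pytest.approx(eto_day * 1.02 * n)  # ~914 mm
        assert series.cwr_mm == pytest.approx(914, abs=1)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            crop_et_series(self._dates(5), np.ones(5), np.ones(4))


class TestLeaching:
    @pytest.mark.parametrize(
        "ecw, ece, expected_f",
        [(0.0, 2.0, 0.0), (1.86, 2.27, 0.1960), (2.04, 2.34, 0.2112)],
    )
    def test_fraction_hand_values(self, ecw, ece, expected_f):
        assert leaching_fraction(ecw, ece) == pytest.approx(expected_f, abs=5e-5)

    def test_salinity_out_of_range(self):
        with pytest.raises(ValueError, match="salinity out of range"):
            leaching_fraction(10.0, 1.9)

    @pytest.mark.parametrize(
        "cwr, ecw, ece, expected_mm",
        [(1304, 1.86, 2.27, 318), (1072, 2.04, 2.34, 287)],
    )
    def test_depth_reproduces_field_records(self, cwr, ecw, ece, expected_mm):
        lr = leaching_depth(cwr, leaching_fraction(ecw, ece))
        assert round(lr) == expected_mm

    @given(
        st.floats(min_value=1.0, max_value=3000.0),
        st.floats(min_value=0.0, max_value=0.95),
    )
    @settings(max_examples=60, derandomize=True)
    def test_gross_application_identity(self, cwr, f):
        # the leaching depth is the fraction f of the gross application
        lr = leaching_depth(cwr, f)
        assert lr / (cwr + lr) == pytest.approx(f, abs=1e-9)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            leaching_depth(1000.0, 1.0)


class TestFieldWaterArithmetic:
    def test_q_hand_value_and_additivity(self):
        assert water_requirement_q([50.0], [11.0], [0.0]) == pytest.approx(5500.0)
        one = water_requirement_q([50.0], [11.0], [2.0])
        two = water_requirement_q([50.0, 50.0], [11.0, 11.0], [2.0, 2.0])
        assert two == pytest.approx(2 * one)

    def test_q_floors_negative_fields(self):
        assert water_requirement_q([10.0], [3.0], [8.0]) == 0.0
        mixed = water_requirement_q([10.0, 10.0], [3.0, 9.0], [8.0, 1.0])
        assert mixed == pytest.approx(10.0 * 8.0 * 10.0)

    @pytest.mark.parametrize(
        "net, eff, expected", [(700.0, 0.70, 1000.0), (5.0, 1.0, 5.0), (1140.0, 0.70, 1628.6)]
    )
    def test_gross_irrigation(self, net, eff, expected):
        assert gross_irrigation(net, eff) == pytest.approx(expected, abs=0.05)

    def test_gross_irrigation_rejects_bad_efficiency(self):
        with pytest.raises(ValueError):
            gross_irrigation(100.0, 0.0)
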