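"""WBGT energy-balance model: identities, monotonicity, stability classes."""

import numpy as np
import pytest

from heatstack.psychro import AirState
from heatstack.wbgt import (
    LAPSE_C,
    WbgtInput,
    classify_urban,
    globe_temperature,
    natural_wet_bulb,
    stability_class,
    wbgt,
    wind_to_2m,
)

A, B, C, D, E, F = 1, 2, 3, 4, 5, 6


def make_input(t_air=30.0, t_dew=20.0, p=1000.0, speed=3.0, solar=600.0,
               cza=0.8, urban=0, n=None):
    def arr(x):
        return np.full(n, float(x)) if n else np.asarray(float(x))
    return WbgtInput(
        air=AirState(t_air=arr(t_air), t_dew=arr(t_dew), p_air=arr(p)),
        speed10=arr(speed), solar=arr(solar), cza_daytime_mean=arr(cza),
        urban=np.zeros(n, dtype=int) + urban if n else np.asarray(urban),
    )


class TestClassifyUrban:
    @pytest.mark.parametrize("frac, expected", [(0.33, 1), (0.329, 0), (0.0, 0), (1.0, 1)])
    def test_threshold_boundary(self, frac, expected):
        assert classify_urban(frac) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            classify_urban(1.2)


class TestStabilityClass:
    def test_corrected_night_classes_between_2_and_2p5(self):
        assert stability_class(2.2, 0.0, 0.0, lapse=-0.052) == E
        assert stability_class(2.2, 0.0, 0.0, lapse=+0.052) == D

    def test_original_night_classes_between_2_and_2p5(self):
        assert stability_class(2.2, 0.0, 0.0, lapse=-0.052, variant="original") == F
        assert stability_class(2.2, 0.0, 0.0, lapse=+0.052, variant="original") == E

    def test_bright_calm_day_is_class_a(self):
        assert stability_class(1.0, 950.0, 0.9) == A

    @pytest.mark.parametrize("speed, solar, expected", [
        # spot checks of the EPA SRDT daytime lookup
        (1.0, 700.0, A), (2.5, 400.0, C), (4.0, 950.0, B),
        (5.5, 700.0, C), (7.0, 100.0, D), (1.0, 100.0, D),
    ])
    def test_daytime_table(self, speed, solar, expected):
        assert stability_class(speed, solar, 0.7) == expected

    def test_night_boundaries(self):
        # <2.0 → E/F; ≥2.5 → D/E (half-open [2.0, 2.5) for the middle row)
        assert stability_class(1.5, 0.0, 0.0, lapse=-0.052) == F
        assert stability_class(1.5, 0.0, 0.0, lapse=+0.052) == E
        assert stability_class(2.5, 0.0, 0.0, lapse=-0.052) == E
        assert stability_class(2.5, 0.0, 0.0, lapse=+0.052) == D


class TestWindTo2m:
    def test_rural_class_d_hand_value(self):
        assert wind_to_2m(5.0, D, 0) == pytest.approx(5.0 * 0.2**0.15, rel=1e-12)

    def test_post_conversion_floor(self):
        # rural F exponent 0.55: 0.6·0.2^0.55 ≈ 0.25 → floored to 0.5
        assert wind_to_2m(0.6, F, 0) == 0.5

    def test_original_variant_floor_is_0p13(self):
        assert wind_to_2m(0.6, F, 0, variant="original") == pytest.approx(
            0.6 * 0.2**0.55, rel=1e-12)
        assert wind_to_2m(0.1, F, 0, variant="original") == 0.13

    def test_urban_exponent_differs(self):
        assert wind_to_2m(5.0, E, 1) != wind_to_2m(5.0, E, 0)


class TestSolvers:
    def test_globe_isothermal_enclosure(self):
        # no sun, sky emissivity pinned to 1: the globe must sit at t_air
        inp = make_input(solar=0.0, cza=0.0)
        tg = globe_temperature(inp, speed2=2.0, emis_atm_override=1.0)
        assert tg == pytest.approx(30.0, abs=0.05)

    def test_globe_heats_under_sun(self):
        inp = make_input(solar=800.0, cza=0.9, speed=1.0)
        assert globe_temperature(inp, speed2=1.0) > 30.0

    def test_wind_couples_globe_to_air(self):
        inp = make_input(solar=800.0, cza=0.9)
        t_slow = globe_temperature(inp, speed2=1.0)
        t_fast = globe_temperature(inp, speed2=2.0)
        assert abs(t_fast - 30.0) < abs(t_slow - 30.0)

    def test_wet_bulb_saturated_no_sun_equals_air(self):
        inp = make_input(t_dew=30.0, solar=0.0, cza=0.0)
        tw = natural_wet_bulb(inp, speed2=2.0, emis_atm_override=1.0)
        assert tw == pytest.approx(30.0, abs=0.1)

    def test_wet_bulb_depressed_when_dry(self):
        inp = make_input(t_dew=18.4, solar=0.0, cza=0.0)  # ~50% RH
        assert natural_wet_bulb(inp, speed2=2.0) < 30.0

    def test_wet_bulb_monotone_in_humidity(self):
        tws = [natural_wet_bulb(make_input(t_dew=td, solar=0.0, cza=0.0), speed2=2.0)
               for td in (10.0, 18.0, 25.0, 29.0)]
        assert np.all(np.diff(tws) > 0)


class TestWbgt:
    def test_combination_weights(self):
        res = wbgt(make_input())
        assert res.wbgt == pytest.approx(
            0.70 * res.t_w + 0.20 * res.t_g + 0.10 * res.t_a, abs=1e-12)
        # arithmetic identity of the weights themselves
        assert 0.70 * 25 + 0.20 * 35 + 0.10 * 30 == pytest.approx(27.5)

    def test_bounded_by_components(self):
        res = wbgt(make_input())
        lo = min(res.t_w, res.t_g, res.t_a)
        hi = max(res.t_w, res.t_g, res.t_a)
        assert lo <= res.wbgt <= hi

    def test_equal_components_identity(self):
        # saturated, dark, pinned enclosure: all three components → t_air,
        # so the convex combination returns t_air
        inp = make_input(t_dew=30.0, solar=0.0, cza=0.0, speed=2.0)
        tw = natural_wet_bulb(inp, speed2=2.0, emis_atm_override=1.0)
        tg = globe_temperature(inp, speed2=2.0, emis_atm_override=1.0)
        combined = 0.7 * tw + 0.2 * tg + 0.1 * 30.0
        assert combined == pytest.approx(30.0, abs=0.1)

    def test_deterministic(self):
        r1 = wbgt(make_input(n=20))
        r2 = wbgt(make_input(n=20))
        assert np.array_equal(r1.wbgt, r2.wbgt)

    def test_missing_input_propagates(self):
        inp = make_input()
        inp.air.t_dew = np.asarray(np.nan)
        assert np.isnan(wbgt(inp).wbgt)

    def test_monotonicity_sweep(self, rng):
        """Randomized 200-state sweep: WBGT responds with the right sign to
        solar load, humidity, and wind (within solver tolerance)."""
        n = 200
        t_air = rng.uniform(15, 40, n)
        depression = rng.uniform(2, 15, n)
        base = WbgtInput(
            air=AirState(t_air=t_air, t_dew=t_air - depression,
                         p_air=rng.uniform(800, 1020, n)),
            speed10=rng.uniform(0.5, 8, n),
            solar=rng.uniform(100, 700, n),
            cza_daytime_mean=rng.uniform(0.3, 1.0, n),
            urban=rng.integers(0, 2, n),
        )
        ref = wbgt(base).wbgt
        tol = 0.05

        more_sun = wbgt(WbgtInput(air=base.air, speed10=base.speed10,
                                  solar=base.solar + 150,
                                  cza_daytime_mean=base.cza_daytime_mean,
                                  urban=base.urban)).wbgt
        assert np.all(more_sun - ref > -tol)

        moister = wbgt(WbgtInput(
            air=AirState(t_air=t_air, t_dew=t_air - depression * 0.5,
                         p_air=base.air.p_air),
            speed10=base.speed10, solar=base.solar,
            cza_daytime_mean=base.cza_daytime_mean, urban=base.urban)).wbgt
        assert np.all(moister - ref > -tol)

        windier = wbgt(WbgtInput(air=base.air, speed10=base.speed10 + 3,
                                 solar=base.solar,
                                 cza_daytime_mean=base.cza_daytime_mean,
                                 urban=base.urban)).wbgt
        assert np.all(windier - ref < tol)

    def test_variant_switch_changes_little_but_changes(self, rng):
        n = 50
        t_air = rng.uniform(18, 38, n)
        inp = WbgtInput(
            air=AirState(t_air=t_air, t_dew=t_air - rng.uniform(2, 12, n),
                         p_air=rng.uniform(800, 1020, n)),
            speed10=rng.uniform(0.5, 6, n), solar=rng.uniform(0, 700, n),
            cza_daytime_mean=rng.uniform(0.0, 1.0, n),
            urban=rng.integers(0, 2, n),
        )
        mod = wbgt(inp, variant="modified").wbgt
        orig = wbgt(inp, variant="original").wbgt
        diff = np.abs(mod - orig)
        assert np.nanmax(diff) < 1.0          # modifications are small
        assert np.nanmean(diff) < 0.25
        assert np.any(diff > 0)               # but the switch is live

    def test_lapse_constant_matches_lapse_rate(self):
        assert LAPSE_C == pytest.approx(-6.5e-3 * 8.0)
        assert LAPSE_C == pytest.approx(-0.052)
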