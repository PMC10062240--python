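import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldrisk import (
    Environment,
    SEGMENTS,
    ValidationError,
    air_layer_insulation,
    bundled_ensemble,
    clo_to_rct,
    ret_from_im,
    total_segment_resistance,
)
from coldrisk.clothing import (
    AIR_LAYER_IM,
    LEWIS_RELATION,
    im_from_resistances,
    saturation_vapour_pressure,
)


class TestDryResistance:
    @pytest.mark.parametrize("clo,expected", [(1.0, 0.155), (0.0, 0.0), (6.26, 0.9703)])
    def test_clo_definition(self, clo, expected):
        assert clo_to_rct(clo) == pytest.approx(expected, rel=1e-9)

    def test_negative_clo_rejected(self):
        with pytest.raises(ValidationError):
            clo_to_rct(-0.1)


class TestEvaporativeResistance:
    def test_lewis_identity_case(self):
        assert ret_from_im(0.165, 1.0) == pytest.approx(0.01, rel=1e-9)

    def test_low_protection_feet(self):
        # clo 0.74, im 0.15 -> rct 0.1147 m2K/W, ret 0.04634 m2kPa/W
        rct = clo_to_rct(0.74)
        assert rct == pytest.approx(0.1147, abs=1e-4)
        assert ret_from_im(rct, 0.15) == pytest.approx(0.04634, rel=1e-3)

    def test_inverse_proportional_in_im(self):
        assert ret_from_im(0.3, 0.2) == pytest.approx(2 * ret_from_im(0.3, 0.4))

    @pytest.mark.parametrize("im", [0.0, -0.5, 1.5])
    def test_invalid_im_rejected(self, im):
        with pytest.raises(ValidationError):
            ret_from_im(0.2, im)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 2.0), st.floats(0.01, 1.0))
    def test_im_round_trip(self, rct, im):
        assert im_from_resistances(rct, ret_from_im(rct, im)) == pytest.approx(
            im, abs=1e-9
        )


class TestAirLayer:
    def test_still_air_anchor(self):
        assert air_layer_insulation(0.0) == pytest.approx(0.70)

    def test_reference_wind_speed(self):
        # 0.70 * (0.25 + 0.75 * exp(-0.05 * 17))
        expected = 0.70 * (0.25 + 0.75 * math.exp(-0.85))
        assert air_layer_insulation(17.0) == pytest.approx(expected, rel=1e-12)
        assert air_layer_insulation(17.0) == pytest.approx(0.3994, abs=1e-4)

    def test_high_wind_asymptote(self):
        assert air_layer_insulation(1e6) == pytest.approx(0.175, rel=1e-6)
        assert air_layer_insulation(500.0) > 0.25 * 0.70

    def test_strictly_decreasing(self):
        winds = np.linspace(0.6, 60.0, 40)
        vals = [air_layer_insulation(w) for w in winds]
        assert np.all(np.diff(vals) < 0)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValidationError):
            air_layer_insulation(-1.0)


class TestTotalResistance:
    def test_exposed_skin_is_air_layer_only(self):
        env = Environment(ta=-20.0, rh=0.6, wind=17.0)
        res = total_segment_resistance(1.44, 0.14, env, exposed=True)
        assert res.rct == pytest.approx(clo_to_rct(air_layer_insulation(17.0)))
        assert res.ret == pytest.approx(res.rct / (AIR_LAYER_IM * LEWIS_RELATION))

    def test_zero_clo_equals_exposed(self):
        env = Environment(ta=-8.0, rh=0.6, wind=5.0)
        bare = total_segment_resistance(0.0, 0.5, env, exposed=False)
        exposed = total_segment_resistance(1.44, 0.14, env, exposed=True)
        assert bare.rct == pytest.approx(exposed.rct)
        assert bare.ret == pytest.approx(exposed.ret)

    def test_wind_reduces_total_dry_resistance(self):
        calm = Environment(ta=-20.0, rh=0.6, wind=1.0)
        windy = Environment(ta=-20.0, rh=0.6, wind=17.0)
        r_calm = total_segment_resistance(1.44, 0.14, calm)
        r_windy = total_segment_resistance(1.44, 0.14, windy)
        assert r_calm.rct > r_windy.rct

    def test_protection_ordering_hands_feet(self, low_protection, high_protection):
        env = Environment(ta=-20.0, rh=0.6, wind=1.0)
        for seg in ("hands", "feet"):
            lo_clo, lo_im = low_protection.segment(seg)
            hi_clo, hi_im = high_protection.segment(seg)
            lo = total_segment_resistance(lo_clo, lo_im, env)
            hi = total_segment_resistance(hi_clo, hi_im, env)
            assert hi.rct > lo.rct
            assert lo.ret > 0 and hi.ret > 0


class TestBundledEnsembles:
    def test_reference_values(self, low_protection, high_protection):
        assert low_protection.clo_array == pytest.approx(
            [1.80, 6.26, 4.37, 0.77, 4.49, 0.74]
        )
        assert low_protection.im_array == pytest.approx(
            [0.37, 0.32, 0.41, 0.30, 0.39, 0.15]
        )
        assert high_protection.clo_array == pytest.approx(
            [1.80, 6.26, 4.45, 2.41, 4.49, 1.44]
        )
        assert high_protection.im_array == pytest.approx(
            [0.37, 0.32, 0.42, 0.94, 0.39, 0.14]
        )

    def test_csv_round_trip(self, tmp_path, low_protection):
        path = tmp_path / "ens.csv"
        low_protection.to_frame().to_csv(path, index=False)
        from coldrisk import EnsembleSpec

        loaded = EnsembleSpec.from_csv(path, name=low_protection.name)
        assert loaded.clo_array == pytest.approx(low_protection.clo_array)
        assert loaded.im_array == pytest.approx(low_protection.im_array)

    def test_unknown_ensemble_rejected(self):
        with pytest.raises(ValidationError, match="unknown ensemble"):
            bundled_ensemble("arctic_parka")


class TestEnvironment:
    def test_validation(self):
        with pytest.raises(ValidationError, match="ta"):
            Environment(ta=-80.0, rh=0.5, wind=1.0)
        with pytest.raises(ValidationError, match="rh"):
            Environment(ta=-8.0, rh=1.5, wind=1.0)
        with pytest.raises(ValidationError, match="wind"):
            Environment(ta=-8.0, rh=0.5, wind=-1.0)

    def test_saturation_pressure_supercooled(self):
        # Buck curve over water at -20 °C
        assert saturation_vapour_pressure(-20.0) == pytest.approx(0.1256, abs=2e-4)
        t = np.linspace(-40, 40, 50)
        assert np.all(np.diff(saturation_vapour_pressure(t)) > 0)

    def test_vapour_pressure(self):
        env = Environment(ta=-20.0, rh=0.6, wind=1.0)
        assert env.vapour_pressure == pytest.approx(0.6 * 0.1256, abs=2e-4)
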