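import math

import numpy as np
import pytest

from coldrisk import (
    ControllerParams,
    Environment,
    EnsembleSpec,
    FractionTable,
    IntegrationError,
    PhysioState,
    Scenario,
    ValidationError,
    simulate,
)
from coldrisk.anthropometry import SEGMENTS
from coldrisk.model import (
    GROUPS,
    _Packed,
    dry_heat_flux,
    evaporative_heat_flux,
    respiratory_heat_loss,
    shivering_thermogenesis,
    skin_blood_flow,
)

UNIFORM_ENSEMBLE = EnsembleSpec("uniform", clo=(1.0,) * 6, im=(0.5,) * 6)


def _state(core=37.0, skin=33.5, blood=37.0, face=33.5):
    return PhysioState(
        core=np.full(6, core), skin=np.full(6, skin), blood=blood, face=face
    )


class TestFluxes:
    def test_dry_flux_zero_gradient(self):
        assert dry_heat_flux(25.0, 25.0, 0.2) == 0.0

    def test_dry_flux_reference_value(self):
        # feet at 30 °C skin against -20 °C through 0.1147 m2K/W
        assert dry_heat_flux(30.0, -20.0, 0.1147) == pytest.approx(435.9, abs=0.1)

    def test_dry_flux_inverse_in_resistance(self):
        assert dry_heat_flux(30.0, -20.0, 0.2) == pytest.approx(
            0.5 * dry_heat_flux(30.0, -20.0, 0.1)
        )

    def test_dry_flux_invalid_resistance(self):
        with pytest.raises(ValidationError):
            dry_heat_flux(30.0, -20.0, 0.0)

    def test_evaporative_zero_gradient_floored(self):
        env = Environment(ta=30.0, rh=1.0, wind=1.0)
        assert evaporative_heat_flux(30.0, env, 0.05) == 0.0
        # skin colder than dew point would give negative gradient -> floored
        assert evaporative_heat_flux(10.0, env, 0.05) == 0.0

    def test_evaporative_reference_value(self):
        # 30 °C skin, -20 °C / 60% RH air, low-protection feet ret
        env = Environment(ta=-20.0, rh=0.6, wind=1.0)
        assert evaporative_heat_flux(30.0, env, 0.04634, wetness=0.06) == pytest.approx(
            5.40, rel=2e-3
        )

    def test_evaporative_linear_in_inverse_ret(self):
        env = Environment(ta=-20.0, rh=0.6, wind=1.0)
        assert evaporative_heat_flux(30.0, env, 0.02) == pytest.approx(
            2 * evaporative_heat_flux(30.0, env, 0.04)
        )

    def test_respiratory_reference_value(self):
        env = Environment(ta=-20.0, rh=0.6, wind=1.0)
        assert respiratory_heat_loss(116.0, env) == pytest.approx(20.4, abs=0.1)

    def test_respiratory_vanishes_in_warm_saturated_air(self):
        # above 34 °C and with ambient vapour pressure above 5.87 kPa both
        # terms are non-positive -> floored at 0
        env = Environment(ta=36.0, rh=1.0, wind=1.0)
        assert respiratory_heat_loss(300.0, env) == 0.0

    def test_respiratory_linear_in_met(self):
        env = Environment(ta=-8.0, rh=0.5, wind=1.0)
        assert respiratory_heat_loss(274.0, env) == pytest.approx(
            2 * respiratory_heat_loss(137.0, env)
        )


class TestControllers:
    PARAMS = ControllerParams(
        core_setpoint=36.8, skin_setpoint=33.7, shiver_gain=40.0, shiver_cap=350.0
    )

    def test_shivering_null_at_setpoints(self):
        assert shivering_thermogenesis(_state(blood=36.8, skin=33.7), self.PARAMS) == 0.0
        assert shivering_thermogenesis(_state(blood=37.5, skin=35.0), self.PARAMS) == 0.0

    def test_shivering_product_formula(self):
        # gain * (36.8 - 36.3) * (33.7 - 28.0) = 40 * 0.5 * 5.7
        got = shivering_thermogenesis(_state(blood=36.3, skin=28.0), self.PARAMS)
        assert got == pytest.approx(40.0 * 0.5 * 5.7)

    def test_shivering_cap(self):
        assert shivering_thermogenesis(_state(blood=30.0, skin=5.0), self.PARAMS) == 350.0

    def test_skin_blood_flow_baseline_at_thermoneutral(self, body_model):
        flows = skin_blood_flow(_state(blood=36.9, skin=33.8), self.PARAMS, body_model)
        from coldrisk.model import SEGMENT_GROUP

        expected = [
            self.PARAMS.skin_blood[g] * body_model.area[i]
            for i, g in enumerate(SEGMENT_GROUP)
        ]
        assert flows == pytest.approx(expected)

    def test_skin_blood_flow_floor_in_deep_cold(self, body_model):
        flows = skin_blood_flow(_state(blood=33.0, skin=5.0), self.PARAMS, body_model)
        from coldrisk.model import SEGMENT_GROUP

        expected = [
            self.PARAMS.min_flow[g] * self.PARAMS.skin_blood[g] * body_model.area[i]
            for i, g in enumerate(SEGMENT_GROUP)
        ]
        assert flows == pytest.approx(expected)

    def test_skin_blood_flow_monotone_in_mean_skin(self, body_model):
        warm = skin_blood_flow(_state(skin=32.0), self.PARAMS, body_model)
        cold = skin_blood_flow(_state(skin=25.0), self.PARAMS, body_model)
        assert np.all(cold <= warm + 1e-12)


def _scenario(**kw):
    defaults = dict(
        label="test",
        environment=Environment(ta=-10.0, rh=0.6, wind=5.0),
        ensemble=UNIFORM_ENSEMBLE,
        metabolic_rate=116.0,
        duration_min=30.0,
        exposed_face=True,
    )
    defaults.update(kw)
    return Scenario(**defaults)


class TestSimulate:
    def test_dt_out_of_range(self):
        with pytest.raises(ValidationError, match="dt"):
            simulate(_scenario(), ControllerParams.off(), dt=0.1)

    def test_trajectory_grid(self):
        traj = simulate(_scenario(duration_min=10.0), ControllerParams.off(), dt=2.0)
        assert len(traj.time) == 10 * 60 // 2 + 1
        assert np.all(np.diff(traj.time) > 0)

    def test_equilibrium_fixed_point(self):
        # no metabolism, all nodes at air temperature, saturated air:
        # every derivative must vanish identically
        sc = _scenario(environment=Environment(ta=20.0, rh=1.0, wind=1.0))
        packed = _Packed([sc], [ControllerParams.off()])
        packed.met[:] = 0.0
        state = np.full((1, 14), 20.0)
        assert np.allclose(packed.rhs(state), 0.0, atol=1e-12)

    def test_passive_skin_matches_exponential_relaxation(self):
        # conduction and perfusion off -> each skin node relaxes toward Ta
        # with time constant C*R/A; RK4 must track the closed form to <1%
        params = ControllerParams.off().replace(
            tissue_conductance=0.0,
            skin_blood={g: 0.0 for g in GROUPS},
        )
        env = Environment(ta=45.0, rh=1.0, wind=2.0)
        sc = _scenario(environment=env, duration_min=430.0, exposed_face=False)
        traj = simulate(sc, params, dt=2.0, record_every=15)

        from coldrisk.clothing import air_layer_insulation, clo_to_rct
        from coldrisk.anthropometry import REFERENCE_BODY, build_body_model

        body = build_body_model(REFERENCE_BODY, tissue_conductance=0.0)
        r_tot = clo_to_rct(1.0) + clo_to_rct(air_layer_insulation(2.0))
        for i, seg in enumerate(SEGMENTS):
            tau = body.skin_heat_capacity[i] * r_tot / body.area[i]
            closed = 45.0 + (33.5 - 45.0) * np.exp(-traj.time / tau)
            dev = np.max(np.abs(traj.skin[:, i] - closed)) / (45.0 - 33.5)
            assert dev < 0.01, f"{seg}: relative deviation {dev:.2%}"

    def test_symmetric_segments_stay_identical(self):
        # identical per-segment geometry, clothing, heat allocation and
        # perfusion, controllers off, no respiratory loss -> the six segment
        # trajectories must coincide
        uniform = (1.0 / 6.0,) * 6
        params = ControllerParams.off().replace(
            met_fraction=uniform,
            shiver_fraction=uniform,
            skin_blood={g: 6.0 for g in GROUPS},
            core_blood_distal={"hands": 35.0 / 6.0, "feet": 35.0 / 6.0},
        )
        sc = _scenario(
            environment=Environment(ta=40.0, rh=0.9, wind=5.0),
            fractions=FractionTable(area=uniform, mass=uniform),
            exposed_face=False,
            duration_min=60.0,
        )
        traj = simulate(sc, params, dt=2.0, record_every=30)
        assert np.allclose(traj.skin, traj.skin[:, [0]], atol=1e-9)
        assert np.allclose(traj.core, traj.core[:, [0]], atol=1e-9)

    def test_unstable_step_raises_with_step_index(self):
        # a deliberately tiny face heat capacity makes dt=60 s unstable
        params = ControllerParams.off().replace(face_sheath_capacity=100.0)
        sc = _scenario(
            environment=Environment(ta=-40.0, rh=0.2, wind=40.0),
            duration_min=250.0,
        )
        with pytest.raises(IntegrationError, match="step"):
            simulate(sc, params, dt=60.0)

    def test_energy_audit_closes(self):
        traj = simulate(_scenario(duration_min=30.0), ControllerParams.defaults(), dt=2.0)
        audit = traj.energy_audit()
        assert abs(audit["residual_j"]) < 5e-3 * audit["metabolic_energy_j"]

    def test_node_series_lookup(self):
        traj = simulate(_scenario(duration_min=10.0), ControllerParams.off(), dt=2.0)
        assert np.array_equal(traj.series("feet"), traj.skin[:, SEGMENTS.index("feet")])
        assert np.array_equal(traj.series("exposed_skin"), traj.face)
        assert np.array_equal(traj.series("core:torso"), traj.core[:, 1])
        with pytest.raises(ValidationError):
            traj.series("tail")
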