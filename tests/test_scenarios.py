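import numpy as np
import pytest
import yaml
from importlib import resources

from coldrisk import (
    Environment,
    Scenario,
    ThresholdSet,
    ValidationError,
    load_scenario,
    paper_scenarios,
    run_scenario,
    save_scenario,
)
from coldrisk.model import ControllerParams
from coldrisk.scenarios import SCENARIO_SET_DIGEST, scenario_set_digest


def _bundled_config(name):
    return resources.files("coldrisk.data").joinpath(f"scenarios/{name}.yaml")


class TestConfigIO:
    def test_load_bundled_vehicle_scenario(self, tmp_path):
        cfg = _bundled_config("vehicle_m20_low")
        path = tmp_path / "sc.yaml"
        path.write_text(cfg.read_text())
        sc = load_scenario(path)
        assert sc.environment.ta == -20.0
        assert sc.environment.wind == 1.0
        assert sc.metabolic_rate == 116.0
        assert sc == paper_scenarios()[2]

    def test_round_trip(self, tmp_path, low_protection):
        sc = Scenario(
            label="custom",
            environment=Environment(ta=-12.0, rh=0.55, wind=9.0),
            ensemble=low_protection,
            metabolic_rate=150.0,
            duration_min=120.0,
            exposed_face=False,
        )
        path = tmp_path / "sc.yaml"
        save_scenario(sc, path)
        assert load_scenario(path) == sc

    def test_unknown_keys_rejected(self, tmp_path):
        data = yaml.safe_load(_bundled_config("vehicle_m8_low").read_text())
        data["windchill"] = True
        path = tmp_path / "sc.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ValidationError, match="windchill"):
            load_scenario(path)

    def test_missing_ensemble_rejected(self, tmp_path):
        data = yaml.safe_load(_bundled_config("vehicle_m8_low").read_text())
        del data["ensemble"]
        path = tmp_path / "sc.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ValidationError, match="ensemble"):
            load_scenario(path)

    def test_metabolic_rate_range(self, tmp_path):
        data = yaml.safe_load(_bundled_config("vehicle_m8_low").read_text())
        data["metabolic_rate"] = 5.0
        path = tmp_path / "sc.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ValidationError, match="metabolic_rate"):
            load_scenario(path)

    def test_named_bundled_ensemble_reference(self, tmp_path):
        path = tmp_path / "sc.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "label": "by_name",
                    "environment": {"ta": -5.0, "rh": 0.6, "wind": 3.0},
                    "ensemble": "high_protection",
                    "metabolic_rate": 137.0,
                }
            )
        )
        sc = load_scenario(path)
        assert sc.ensemble.segment("hands")[0] == 2.41


class TestPaperScenarioSet:
    def test_exactly_ten(self):
        assert len(paper_scenarios()) == 10

    def test_parameters(self):
        scs = {sc.label: sc for sc in paper_scenarios()}
        veh = scs["vehicle_m20_high"]
        assert (veh.environment.ta, veh.environment.rh, veh.environment.wind) == (
            -20.0, 0.6, 1.0,
        )
        assert veh.metabolic_rate == 116.0
        out = scs["outside_5_low"]
        assert (out.environment.ta, out.environment.wind) == (5.0, 17.0)
        assert out.metabolic_rate == 137.0
        assert all(sc.duration_min == 250.0 for sc in scs.values())
        assert all(sc.body.height == 1.75 for sc in scs.values())

    def test_frozen_manifest_digest(self):
        assert scenario_set_digest() == SCENARIO_SET_DIGEST

    def test_bundled_configs_match_code(self, tmp_path):
        for sc in paper_scenarios():
            cfg = _bundled_config(sc.label)
            path = tmp_path / "sc.yaml"
            path.write_text(cfg.read_text())
            assert load_scenario(path) == sc


class TestRunScenario:
    THRESHOLDS = ThresholdSet(horizon=30.0, floor=5.0, grid=5.0)

    def _fast_scenario(self):
        sc = paper_scenarios()[2]
        return Scenario(
            label=sc.label, environment=sc.environment, ensemble=sc.ensemble,
            body=sc.body, metabolic_rate=sc.metabolic_rate, duration_min=30.0,
            exposed_face=True,
        )

    def test_deterministic_repeat(self, calibrated):
        sc = self._fast_scenario()
        t1, r1 = run_scenario(sc, calibrated, dt=10.0, thresholds=self.THRESHOLDS)
        t2, r2 = run_scenario(sc, calibrated, dt=10.0, thresholds=self.THRESHOLDS)
        assert np.array_equal(t1.skin, t2.skin)
        assert np.array_equal(t1.face, t2.face)
        assert r1.cells == r2.cells

    def test_thermoneutral_scenario_has_no_crossings(self, high_protection):
        sc = Scenario(
            label="thermoneutral",
            environment=Environment(ta=36.9, rh=0.5, wind=1.0),
            ensemble=high_protection,
            metabolic_rate=116.0,
            duration_min=40.0,
        )
        _, report = run_scenario(
            sc, ControllerParams.defaults(), dt=10.0, thresholds=self.THRESHOLDS
        )
        assert all(tok == "-" for tok in report.cells.values())
        assert report.hypothermia is False

    def test_trajectory_csv_export(self, tmp_path, calibrated):
        traj, _ = run_scenario(
            self._fast_scenario(), calibrated, dt=10.0, thresholds=self.THRESHOLDS
        )
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == len(traj.time)
        assert "skin_feet" in df.columns
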