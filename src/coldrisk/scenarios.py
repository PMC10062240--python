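"""Scenario definition, config I/O, and the bundled reference scenario set.

A :class:`Scenario` bundles the four modelling inputs — environment, human,
activity and clothing — plus the exposure duration.  Ten reference
scenarios are bundled: four "in vehicle" cases (−8 / −20 °C × low / high
extremity protection; 60% RH, 1 km/h wind, 116 W sitting) and six
"outside" cases (5 / −8 / −20 °C × low / high protection; 60% RH, 17 km/h
wind, 137 W slow movement).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import yaml

from .anthropometry import REFERENCE_BODY, BodyInput, FractionTable, ValidationError
from .clothing import Environment, EnsembleSpec, bundled_ensemble
from .injury import (
    BODY_PARTS,
    THRESHOLD_LABELS,
    RiskReport,
    ThresholdSet,
    assess_scenario,
)
from .model import ControllerParams, Trajectory, simulate_batch

__all__ = [
    "Scenario",
    "load_scenario",
    "save_scenario",
    "paper_scenarios",
    "scenario_set_digest",
    "SCENARIO_SET_DIGEST",
    "run_scenario",
    "run_paper_tables",
    "PaperTables",
]

log = logging.getLogger("coldrisk")


@dataclass(frozen=True)
class Scenario:
    """One simulation case: environment + human + activity + clothing."""

    label: str
    environment: Environment
    ensemble: EnsembleSpec
    body: BodyInput = REFERENCE_BODY
    metabolic_rate: float = 116.0
    duration_min: float = 250.0
    exposed_face: bool = True
    fractions: FractionTable = FractionTable()

    def __post_init__(self) -> None:
        if not (80.0 <= self.metabolic_rate <= 800.0):
            raise ValidationError(
                f"metabolic_rate={self.metabolic_rate!r} outside [80, 800] W"
            )
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be > 0")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "environment": {
                "ta": self.environment.ta,
                "rh": self.environment.rh,
                "wind": self.environment.wind,
            },
            "ensemble": {
                "name": self.ensemble.name,
                "clo": [float(v) for v in self.ensemble.clo_array],
                "im": [float(v) for v in self.ensemble.im_array],
            },
            "body": {
                "height": self.body.height,
                "mass": self.body.mass,
                "body_fat": self.body.body_fat,
            },
            "metabolic_rate": self.metabolic_rate,
            "duration_min": self.duration_min,
            "exposed_face": self.exposed_face,
            **(
                {
                    "fractions": {
                        "area": [float(v) for v in self.fractions.area],
                        "mass": [float(v) for v in self.fractions.mass],
                    }
                }
                if self.fractions != FractionTable()
                else {}
            ),
        }


_TOP_KEYS = {
    "label", "environment", "ensemble", "body",
    "metabolic_rate", "duration_min", "exposed_face", "fractions",
}


def _scenario_from_dict(d: dict) -> Scenario:
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown scenario keys {sorted(unknown)}")
    if "ensemble" not in d:
        raise ValidationError("scenario config is missing the ensemble reference")
    ens = d["ensemble"]
    if isinstance(ens, str):
        ensemble = bundled_ensemble(ens)
    else:
        ensemble = EnsembleSpec(
            name=ens.get("name", "custom"),
            clo=tuple(ens["clo"]),
            im=tuple(ens["im"]),
        )
    env = d.get("environment", {})
    body = d.get("body", {})
    fractions = FractionTable()
    if "fractions" in d:
        fr = d["fractions"]
        fractions = FractionTable(area=tuple(fr["area"]), mass=tuple(fr["mass"]))
    return Scenario(
        label=d.get("label", "scenario"),
        environment=Environment(
            ta=env.get("ta", 0.0), rh=env.get("rh", 0.6), wind=env.get("wind", 1.0)
        ),
        ensemble=ensemble,
        body=BodyInput(
            height=body.get("height", REFERENCE_BODY.height),
            mass=body.get("mass", REFERENCE_BODY.mass),
            body_fat=body.get("body_fat", REFERENCE_BODY.body_fat),
        ),
        metabolic_rate=d.get("metabolic_rate", 116.0),
        duration_min=d.get("duration_min", 250.0),
        exposed_face=bool(d.get("exposed_face", True)),
        fractions=fractions,
    )


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML or JSON config file."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return _scenario_from_dict(data)


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario config (YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Bundled reference scenario set
# ---------------------------------------------------------------------------

def paper_scenarios() -> list:
    """The ten bundled reference scenarios, in table order."""
    out = []
    for ta in (-8.0, -20.0):
        for prot in ("low", "high"):
            out.append(
                Scenario(
                    label=f"vehicle_m{int(-ta)}_{prot}",
                    environment=Environment(ta=ta, rh=0.6, wind=1.0),
                    ensemble=bundled_ensemble(f"{prot}_protection"),
                    metabolic_rate=116.0,
                )
            )
    for ta in (5.0, -8.0, -20.0):
        for prot in ("low", "high"):
            tag = f"m{int(-ta)}" if ta < 0 else f"{int(ta)}"
            out.append(
                Scenario(
                    label=f"outside_{tag}_{prot}",
                    environment=Environment(ta=ta, rh=0.6, wind=17.0),
                    ensemble=bundled_ensemble(f"{prot}_protection"),
                    metabolic_rate=137.0,
                )
            )
    return out


def scenario_set_digest(scenarios=None) -> str:
    """SHA-256 digest of the scenario set's canonical JSON."""
    scenarios = scenarios if scenarios is not None else paper_scenarios()
    blob = json.dumps([s.to_dict() for s in scenarios], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


#: Frozen digest of the bundled ten-scenario set.
SCENARIO_SET_DIGEST = (
    "6e9269caa293fb43a16faa8138b94457abbbf921f77481a8ef1b4e13050022bf"
)


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

def run_scenario(
    scenario: Scenario,
    params: ControllerParams | None = None,
    dt: float = 1.0,
    thresholds: ThresholdSet = ThresholdSet(),
    record_every: int = 5,
):
    """Simulate one scenario and assess it. Returns (Trajectory, RiskReport)."""
    params = params or ControllerParams.defaults()
    log.info(
        "running scenario %s (dt=%.2g s, calibration %s)",
        scenario.label, dt, params.digest,
    )
    traj = simulate_batch([scenario], [params], dt=dt, record_every=record_every)[0]
    return traj, assess_scenario(traj, thresholds)


@dataclass
class PaperTables:
    """The two rendered threshold-time tables plus underlying reports."""

    vehicle: list      # RiskReports, 4 scenarios
    outside: list      # RiskReports, 6 scenarios
    trajectories: dict  # label -> Trajectory

    def report(self, label: str) -> RiskReport:
        for rep in self.vehicle + self.outside:
            if rep.scenario == label:
                return rep
        raise KeyError(label)

    @staticmethod
    def _render(title: str, reports) -> str:
        header = (
            f"{'Temperature (Ta)':<17}{'Condition':<17}{'Body Part':<15}"
            f"{'Numbness/Dexterity loss (8°C)':<31}{'Pain (5°C)':<12}"
            f"{'Frostbite (<1°C)':<17}"
        )
        lines = [title, header, "-" * len(header)]
        for rep in reports:
            parts = rep.scenario.split("_")
            ta = parts[1].replace("m", "-") + "°C"
            cond = f"{parts[2].capitalize()} protection"
            first = True
            for row in rep.rows():
                lines.append(
                    f"{ta if first else '':<17}{cond if first else '':<17}"
                    f"{row[0]:<15}{row[1]:<31}{row[2]:<12}{row[3]:<17}"
                )
                first = False
        return "\n".join(lines)

    def render_vehicle(self) -> str:
        return self._render(
            "Predicted times to reach thresholds within 250 minutes of exposure "
            "while in the vehicle.",
            self.vehicle,
        )

    def render_outside(self) -> str:
        return self._render(
            "Predicted times to reach thresholds within 250 minutes of exposure "
            "while outside.",
            self.outside,
        )

    def to_dataframe(self):
        import pandas as pd

        frames = [rep.to_dataframe() for rep in self.vehicle + self.outside]
        return pd.concat(frames, ignore_index=True)


def run_paper_tables(
    params: ControllerParams | None = None,
    dt: float = 1.0,
    thresholds: ThresholdSet = ThresholdSet(),
) -> PaperTables:
    """Run all ten bundled scenarios and assemble the two tables."""
    params = params or ControllerParams.defaults()
    scenarios = paper_scenarios()
    trajs = simulate_batch(scenarios, params, dt=dt, record_every=5)
    reports, trajectories = [], {}
    for sc, traj in zip(scenarios, trajs):
        try:
            reports.append(assess_scenario(traj, thresholds))
        except Exception as exc:  # attach the scenario label to any failure
            raise type(exc)(f"{sc.label}: {exc}") from exc
        trajectories[sc.label] = traj
    return PaperTables(
        vehicle=reports[:4], outside=reports[4:], trajectories=trajectories
    )
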