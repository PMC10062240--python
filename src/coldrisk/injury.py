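"""Cold-injury assessment: threshold-crossing times and risk reports.

Skin-temperature thresholds follow the cold-weather modelling convention:
loss of dexterity / numbness at 8 °C, onset of pain at 5 °C, and frostbite
at 1 °C (observed skin freezing points range −0.6 to −4.8 °C; the 1 °C
modelling threshold is deliberately conservative).  Hypothermia is flagged
when the central core temperature falls below 35 °C.

Times are reported the way cold-exposure planning tables print them: a
"<10 min" floor, a 5-minute grid (ties round down), and "-" for crossings
censored at the 250-minute horizon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import ValidationError
from .model import HYPOTHERMIA_CORE, Trajectory

__all__ = [
    "ThresholdSet",
    "RiskReport",
    "BODY_PARTS",
    "THRESHOLD_LABELS",
    "time_to_threshold",
    "format_report_time",
    "parse_report_time",
    "assess_scenario",
]

#: Reported body part -> trajectory node.
BODY_PARTS = {
    "Exposed skin": "exposed_skin",
    "Hands/Fingers": "hands",
    "Feet/Toes": "feet",
}

THRESHOLD_LABELS = ("numbness", "pain", "frostbite")


@dataclass(frozen=True)
class ThresholdSet:
    """Injury thresholds (°C) and reporting conventions (minutes)."""

    numbness: float = 8.0
    pain: float = 5.0
    frostbite: float = 1.0
    hypothermia: float = HYPOTHERMIA_CORE
    horizon: float = 250.0
    floor: float = 10.0
    grid: float = 5.0

    def __post_init__(self) -> None:
        if not (self.numbness > self.pain > self.frostbite):
            raise ValidationError("thresholds must satisfy numbness > pain > frostbite")
        if not (self.horizon > self.floor > 0):
            raise ValidationError("horizon > floor > 0 required")

    @property
    def skin_thresholds(self) -> dict:
        return {"numbness": self.numbness, "pain": self.pain, "frostbite": self.frostbite}


def time_to_threshold(trajectory: Trajectory, node: str, threshold: float):
    """First time (minutes) the node falls to/below the threshold, or None.

    Linearly interpolated between recorded steps; None if the trajectory
    never crosses within its recorded span.
    """
    temps = trajectory.series(node)  # raises ValidationError for unknown node
    if temps.size == 0:
        raise ValidationError("trajectory is empty")
    t_min = trajectory.minutes
    below = temps <= threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return 0.0
    t0, t1 = t_min[i - 1], t_min[i]
    y0, y1 = temps[i - 1], temps[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - threshold) / (y0 - y1) * (t1 - t0))


def format_report_time(t, thresholds: ThresholdSet = ThresholdSet()) -> str:
    """Render a crossing time the way planning tables print it.

    ``t < floor`` → "<10 min"; absent or beyond the horizon → "-";
    otherwise snapped to the nearest grid point (ties round down).
    """
    if t is None:
        return "-"
    if t < 0:
        raise ValidationError(f"negative crossing time {t!r}")
    if t < thresholds.floor:
        return f"<{thresholds.floor:.0f} min"
    if t > thresholds.horizon:
        return "-"
    snapped = thresholds.grid * math.ceil(t / thresholds.grid - 0.5)
    return f"{snapped:.0f} min"


def parse_report_time(token: str, thresholds: ThresholdSet = ThresholdSet()):
    """Inverse of :func:`format_report_time` up to grid resolution."""
    token = token.strip()
    if token == "-":
        return None
    if token.startswith("<"):
        return float(token[1:].split()[0]) / 2.0  # representative sub-floor time
    return float(token.split()[0])


@dataclass
class RiskReport:
    """Per-body-part threshold-crossing report for one scenario."""

    scenario: str
    cells: dict = field(default_factory=dict)   # (part, threshold_label) -> token
    times: dict = field(default_factory=dict)   # (part, threshold_label) -> float|None
    hypothermia: bool = False
    min_core: float = float("nan")

    def token(self, part: str, label: str) -> str:
        return self.cells[(part, label)]

    def rows(self):
        for part in BODY_PARTS:
            yield [part] + [self.cells[(part, lab)] for lab in THRESHOLD_LABELS]

    def to_json(self, path=None):
        payload = {
            "scenario": self.scenario,
            "hypothermia": self.hypothermia,
            "min_core_c": self.min_core,
            "cells": {
                f"{part}|{lab}": {
                    "token": self.cells[(part, lab)],
                    "minutes": self.times[(part, lab)],
                }
                for part in BODY_PARTS
                for lab in THRESHOLD_LABELS
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            list(self.rows()),
            columns=["body_part", *THRESHOLD_LABELS],
        ).assign(scenario=self.scenario)


def assess_scenario(
    trajectory: Trajectory, thresholds: ThresholdSet = ThresholdSet()
) -> RiskReport:
    """Fill the body-part × threshold table and the hypothermia flag.

    The trajectory must cover the full reporting horizon.  The hypothermia
    flag is true iff the central core temperature drops below the
    hypothermia threshold within the horizon.
    """
    if trajectory.minutes[-1] + 1e-9 < thresholds.horizon:
        raise ValidationError(
            f"trajectory covers {trajectory.minutes[-1]:.1f} min, "
            f"horizon is {thresholds.horizon:.0f} min"
        )
    report = RiskReport(scenario=trajectory.label)
    for part, node in BODY_PARTS.items():
        for lab, thr in thresholds.skin_thresholds.items():
            t = time_to_threshold(trajectory, node, thr)
            if t is not None and t > thresholds.horizon:
                t_report = None
            else:
                t_report = t
            report.times[(part, lab)] = t_report
            report.cells[(part, lab)] = format_report_time(t_report, thresholds)
    in_horizon = trajectory.minutes <= thresholds.horizon + 1e-9
    report.min_core = float(trajectory.blood[in_horizon].min())
    report.hypothermia = bool(report.min_core < thresholds.hypothermia)
    return report
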