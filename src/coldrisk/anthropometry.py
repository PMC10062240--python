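"""Six-cylinder anthropometric body model.

The body is represented as six cylinders (head, torso, arms, hands, legs,
feet), each split into a core and a skin thermal node.  Whole-body height,
mass and body-fat fraction are partitioned into per-segment surface areas,
masses, heat capacities and core-to-skin tissue conductances.

Surface area uses the DuBois formula; the segment partition is a
Stolwijk-style fraction table that can be overridden per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENTS",
    "BodyInput",
    "BodyModel",
    "FractionTable",
    "body_surface_area",
    "build_body_model",
]

#: Canonical segment order used by every array in the package.
SEGMENTS = ("head", "torso", "arms", "hands", "legs", "feet")

#: Specific heat of soft tissue, J/(kg K).
TISSUE_SPECIFIC_HEAT = 3490.0

#: Fraction of each segment's mass assigned to the core node (rest is skin).
CORE_MASS_FRACTION = 0.90

#: Baseline core-to-skin tissue conductance per unit area, W/(m^2 K).
TISSUE_CONDUCTANCE = 5.0


class ValidationError(ValueError):
    """Raised when a physical input falls outside its admissible range."""


def _check_range(name: str, value: float, lo: float, hi: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (lo <= value <= hi):
        raise ValidationError(
            f"{name}={value!r} outside admissible range [{lo}, {hi}]"
        )
    return value


@dataclass(frozen=True)
class BodyInput:
    """Whole-body anthropometry.

    Parameters
    ----------
    height : float
        Stature in metres, within [1.2, 2.2].
    mass : float
        Body mass in kilograms, within [35, 180].
    body_fat : float
        Body-fat fraction in [0.03, 0.55].
    """

    height: float
    mass: float
    body_fat: float

    def __post_init__(self) -> None:
        _check_range("height", self.height, 1.2, 2.2)
        _check_range("mass", self.mass, 35.0, 180.0)
        _check_range("body_fat", self.body_fat, 0.03, 0.55)


#: Anthropometry of the reference simulated individual (healthy lean young man).
REFERENCE_BODY = BodyInput(height=1.75, mass=83.5, body_fat=0.249)


@dataclass(frozen=True)
class FractionTable:
    """Per-segment area and mass fractions (each sums to 1).

    Area fractions follow a Stolwijk-style partition.  Mass fractions use
    anatomical hand/foot segment masses (≈0.6% per hand, ≈1.25% per foot);
    the light distal segments are what lets extremities cool on the tens-of-
    minutes timescale seen in cold-exposure data.
    """

    area: tuple = (0.07, 0.36, 0.14, 0.05, 0.31, 0.07)
    mass: tuple = (0.07, 0.49, 0.13, 0.012, 0.273, 0.025)

    def __post_init__(self) -> None:
        for name, fr in (("area", self.area), ("mass", self.mass)):
            arr = np.asarray(fr, dtype=float)
            if arr.shape != (6,):
                raise ValidationError(f"{name} fractions must have 6 entries")
            if np.any(arr <= 0):
                raise ValidationError(f"{name} fractions must be positive")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"{name} fractions sum to {arr.sum()!r}, expected 1"
                )

    @property
    def area_array(self) -> np.ndarray:
        return np.asarray(self.area, dtype=float)

    @property
    def mass_array(self) -> np.ndarray:
        return np.asarray(self.mass, dtype=float)


@dataclass(frozen=True)
class BodyModel:
    """Thermal body model: per-segment geometry, capacity and conductance.

    All per-segment arrays follow the :data:`SEGMENTS` order.  Conservation
    invariants (areas sum to ``total_area``, masses to body mass) hold by
    construction.
    """

    body: BodyInput
    total_area: float
    area: np.ndarray            # m^2, (6,)
    mass: np.ndarray            # kg, (6,)
    core_heat_capacity: np.ndarray   # J/K, (6,)
    skin_heat_capacity: np.ndarray   # J/K, (6,)
    core_skin_conductance: np.ndarray  # W/K, (6,)
    area_fraction: np.ndarray = field(repr=False, default=None)

    def segment(self, name: str) -> dict:
        i = SEGMENTS.index(name)
        return {
            "surface_area": float(self.area[i]),
            "mass": float(self.mass[i]),
            "core_heat_capacity": float(self.core_heat_capacity[i]),
            "skin_heat_capacity": float(self.skin_heat_capacity[i]),
            "core_skin_conductance": float(self.core_skin_conductance[i]),
        }


def body_surface_area(body: BodyInput) -> float:
    """DuBois body surface area, m^2.

    ``area = 0.202 * mass**0.425 * height**0.725``
    """
    return 0.202 * body.mass ** 0.425 * body.height ** 0.725


def build_body_model(
    body: BodyInput,
    fractions: FractionTable | None = None,
    tissue_conductance: float = TISSUE_CONDUCTANCE,
) -> BodyModel:
    """Partition whole-body anthropometry into the six-cylinder model.

    Core-to-skin tissue conductance per segment is
    ``tissue_conductance * area_i * (1 - 0.9 * body_fat)``: subcutaneous fat
    insulates the core, so the conductance decreases with body-fat fraction.
    """
    fractions = fractions or FractionTable()
    total_area = body_surface_area(body)
    area = fractions.area_array * total_area
    mass = fractions.mass_array * body.mass
    core_cap = CORE_MASS_FRACTION * mass * TISSUE_SPECIFIC_HEAT
    skin_cap = (1.0 - CORE_MASS_FRACTION) * mass * TISSUE_SPECIFIC_HEAT
    conductance = tissue_conductance * area * (1.0 - 0.9 * body.body_fat)
    return BodyModel(
        body=body,
        total_area=total_area,
        area=area,
        mass=mass,
        core_heat_capacity=core_cap,
        skin_heat_capacity=skin_cap,
        core_skin_conductance=conductance,
        area_fraction=fractions.area_array,
    )
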