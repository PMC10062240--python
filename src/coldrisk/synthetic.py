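"""Seeded generator of physiologically plausible random scenarios.

Used for property-based testing of the whole pipeline without external
data: uniform independent draws over ranges that bracket realistic cold
environments, insulation levels and work rates, plus ordered scenario
pairs that differ on exactly one axis (air temperature, insulation, or
metabolic rate) for monotonicity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import BodyInput, ValidationError
from .clothing import Environment, EnsembleSpec
from .scenarios import Scenario

__all__ = ["ScenarioRanges", "sample_scenario", "ordered_pair", "ORDER_AXES"]

ORDER_AXES = ("ta", "clo", "met")


@dataclass(frozen=True)
class ScenarioRanges:
    """Uniform sampling ranges; defaults bracket the reference conditions."""

    ta: tuple = (-40.0, 10.0)
    rh: tuple = (0.2, 0.95)
    wind: tuple = (0.0, 40.0)
    met: tuple = (100.0, 400.0)
    clo: tuple = (0.3, 7.0)
    im: tuple = (0.1, 0.95)
    height: tuple = (1.5, 2.0)
    mass: tuple = (50.0, 120.0)
    body_fat: tuple = (0.08, 0.40)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"range {name} must satisfy low < high")


def _draw(rng, bounds, size=None):
    lo, hi = bounds
    return rng.uniform(lo, hi, size)


def sample_scenario(
    seed: int, ranges: ScenarioRanges | None = None, label: str | None = None
) -> Scenario:
    """Deterministic uniform scenario draw for a given seed."""
    ranges = ranges or ScenarioRanges()
    rng = np.random.default_rng(seed)
    env = Environment(
        ta=_draw(rng, ranges.ta), rh=_draw(rng, ranges.rh), wind=_draw(rng, ranges.wind)
    )
    ensemble = EnsembleSpec(
        name=f"synthetic_{seed}",
        clo=tuple(_draw(rng, ranges.clo, 6)),
        im=tuple(_draw(rng, ranges.im, 6)),
    )
    body = BodyInput(
        height=_draw(rng, ranges.height),
        mass=_draw(rng, ranges.mass),
        body_fat=_draw(rng, ranges.body_fat),
    )
    return Scenario(
        label=label or f"synthetic_{seed}",
        environment=env,
        ensemble=ensemble,
        body=body,
        metabolic_rate=_draw(rng, ranges.met),
    )


def ordered_pair(seed: int, axis: str, ranges: ScenarioRanges | None = None):
    """Two scenarios identical except one axis; the second is strictly milder.

    ``axis`` is one of ``ta`` (second warmer), ``clo`` (second better
    insulated on every segment) or ``met`` (second more active).
    """
    if axis not in ORDER_AXES:
        raise ValidationError(f"unknown axis {axis!r}; expected one of {ORDER_AXES}")
    ranges = ranges or ScenarioRanges()
    base = sample_scenario(seed, ranges, label=f"pair_{seed}_{axis}_lo")
    rng = np.random.default_rng((seed, ORDER_AXES.index(axis) + 1))
    if axis == "ta":
        lo, hi = ranges.ta
        delta = rng.uniform(2.0, 10.0)
        ta0 = min(base.environment.ta, hi - delta)
        first = _with_env(base, ta=ta0)
        second = _with_env(first, ta=ta0 + delta)
    elif axis == "clo":
        bump = rng.uniform(0.3, 1.5)
        first = base
        clo2 = tuple(np.asarray(base.ensemble.clo_array) + bump)
        second = _with_ensemble(base, clo2)
    else:  # met
        lo, hi = ranges.met
        delta = rng.uniform(20.0, 80.0)
        met0 = min(base.metabolic_rate, hi - delta)
        first = _with_met(base, met0)
        second = _with_met(base, met0 + delta)
    second = _relabel(second, f"pair_{seed}_{axis}_hi")
    return first, second


def _with_env(sc: Scenario, **env_kw) -> Scenario:
    env = sc.environment
    new_env = Environment(
        ta=env_kw.get("ta", env.ta),
        rh=env_kw.get("rh", env.rh),
        wind=env_kw.get("wind", env.wind),
    )
    return Scenario(
        label=sc.label, environment=new_env, ensemble=sc.ensemble, body=sc.body,
        metabolic_rate=sc.metabolic_rate, duration_min=sc.duration_min,
        exposed_face=sc.exposed_face,
    )


def _with_ensemble(sc: Scenario, clo) -> Scenario:
    ens = EnsembleSpec(name=sc.ensemble.name + "_warm", clo=clo, im=sc.ensemble.im)
    return Scenario(
        label=sc.label, environment=sc.environment, ensemble=ens, body=sc.body,
        metabolic_rate=sc.metabolic_rate, duration_min=sc.duration_min,
        exposed_face=sc.exposed_face,
    )


def _with_met(sc: Scenario, met: float) -> Scenario:
    return Scenario(
        label=sc.label, environment=sc.environment, ensemble=sc.ensemble, body=sc.body,
        metabolic_rate=met, duration_min=sc.duration_min,
        exposed_face=sc.exposed_face,
    )


def _relabel(sc: Scenario, label: str) -> Scenario:
    return Scenario(
        label=label, environment=sc.environment, ensemble=sc.ensemble, body=sc.body,
        metabolic_rate=sc.metabolic_rate, duration_min=sc.duration_min,
        exposed_face=sc.exposed_face,
    )
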