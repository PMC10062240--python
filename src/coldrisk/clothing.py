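"""Clothing biophysics: clo / i_m to dry and evaporative resistances.

A garment's thermal insulation is given in clo (1 clo = 0.155 m^2 K/W of dry
resistance) and its vapour permeability index i_m relates evaporative to dry
resistance through the Lewis relation (16.5 K/kPa).  Wind erodes the boundary
air layer that sits outside the clothing (or outside bare skin); garment
insulation itself is treated as wind-independent.

The two ensembles measured for the reference analysis (a "low protection"
set with light gloves and all-weather boots, and a "high protection" set
with mittens and cold-weather boots) ship as a bundled CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .anthropometry import SEGMENTS, ValidationError, _check_range

__all__ = [
    "CLO_SI",
    "LEWIS_RELATION",
    "AIR_LAYER_IM",
    "Environment",
    "EnsembleSpec",
    "SegmentResistances",
    "clo_to_rct",
    "ret_from_im",
    "im_from_resistances",
    "air_layer_insulation",
    "total_segment_resistance",
    "saturation_vapour_pressure",
    "bundled_ensemble",
]

#: Dry resistance of 1 clo, m^2 K/W.
CLO_SI = 0.155

#: Lewis relation, K/kPa.
LEWIS_RELATION = 16.5

#: Effective vapour permeability index of the boundary air layer.  Radiation
#: contributes to dry but not evaporative exchange, so the air layer behaves
#: as roughly half-permeable rather than ideal.
AIR_LAYER_IM = 0.5

#: Still-air boundary layer insulation, clo.
STILL_AIR_CLO = 0.70
#: Fraction of still-air insulation surviving at infinite wind.
WIND_FLOOR = 0.25
#: Wind decay constant, per km/h.
WIND_DECAY = 0.05


def saturation_vapour_pressure(t_celsius):
    """Saturation vapour pressure over (supercooled) water, kPa.

    Arden Buck curve; monotone in temperature and valid well below 0 °C.
    """
    t = np.asarray(t_celsius, dtype=float)
    p = 0.61121 * np.exp((18.678 - t / 234.5) * t / (257.14 + t))
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions: air temperature (°C), RH fraction, wind (km/h)."""

    ta: float
    rh: float
    wind: float

    def __post_init__(self) -> None:
        _check_range("ta", self.ta, -60.0, 50.0)
        _check_range("rh", self.rh, 0.0, 1.0)
        if not np.isfinite(self.wind) or self.wind < 0:
            raise ValidationError(f"wind={self.wind!r} must be >= 0 km/h")

    @property
    def vapour_pressure(self) -> float:
        """Ambient water vapour pressure, kPa."""
        return self.rh * saturation_vapour_pressure(self.ta)


@dataclass(frozen=True)
class SegmentResistances:
    """Total dry (m^2 K/W) and evaporative (m^2 kPa/W) resistance."""

    rct: float
    ret: float
    includes_air_layer: bool = True

    def __post_init__(self) -> None:
        if self.rct < 0:
            raise ValidationError(f"rct={self.rct!r} must be >= 0")
        if self.ret <= 0:
            raise ValidationError(f"ret={self.ret!r} must be > 0")


def clo_to_rct(clo: float) -> float:
    """Dry resistance (m^2 K/W) of an insulation given in clo."""
    if clo < 0:
        raise ValidationError(f"clo={clo!r} must be >= 0")
    return clo * CLO_SI


def ret_from_im(rct: float, im: float) -> float:
    """Evaporative resistance (m^2 kPa/W) from dry resistance and i_m.

    ``ret = rct / (im * LR)`` with the Lewis relation LR = 16.5 K/kPa.
    """
    if rct <= 0:
        raise ValidationError(f"rct={rct!r} must be > 0")
    if not (0 < im <= 1):
        raise ValidationError(f"im={im!r} must lie in (0, 1]")
    return rct / (im * LEWIS_RELATION)


def im_from_resistances(rct: float, ret: float) -> float:
    """Recover i_m from measured dry and evaporative resistances."""
    return rct / (ret * LEWIS_RELATION)


def air_layer_insulation(
    wind: float,
    still_air_clo: float = STILL_AIR_CLO,
    floor: float = WIND_FLOOR,
    decay: float = WIND_DECAY,
) -> float:
    """Boundary air layer insulation (clo) at a given wind speed (km/h).

    Still air provides ``still_air_clo``; wind erodes it exponentially down
    to a ``floor`` fraction that survives at any speed:
    ``Ia = Ia0 * (floor + (1 - floor) * exp(-decay * wind))`` for
    wind above 0.5 km/h, and Ia0 below.
    """
    if wind < 0:
        raise ValidationError(f"wind={wind!r} must be >= 0 km/h")
    if wind <= 0.5:
        return still_air_clo
    return still_air_clo * (floor + (1.0 - floor) * np.exp(-decay * wind))


@dataclass(frozen=True)
class EnsembleSpec:
    """Per-segment clothing biophysics: clo and i_m for the six segments."""

    name: str
    clo: tuple
    im: tuple

    def __post_init__(self) -> None:
        clo = np.asarray(self.clo, dtype=float)
        im = np.asarray(self.im, dtype=float)
        if clo.shape != (6,) or im.shape != (6,):
            raise ValidationError("clo and im need one value per segment (6)")
        if np.any(clo < 0):
            raise ValidationError("clo must be >= 0 for every segment")
        if np.any((im <= 0) | (im > 1)):
            raise ValidationError("im must lie in (0, 1] for every segment")

    @property
    def clo_array(self) -> np.ndarray:
        return np.asarray(self.clo, dtype=float)

    @property
    def im_array(self) -> np.ndarray:
        return np.asarray(self.im, dtype=float)

    def segment(self, name: str) -> tuple:
        i = SEGMENTS.index(name)
        return float(self.clo[i]), float(self.im[i])

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "EnsembleSpec":
        df = df.set_index("segment").loc[list(SEGMENTS)]
        return cls(name=name, clo=tuple(df["clo"]), im=tuple(df["im"]))

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "EnsembleSpec":
        df = pd.read_csv(path)
        missing = {"segment", "clo", "im"} - set(df.columns)
        if missing:
            raise ValidationError(f"ensemble CSV missing columns {sorted(missing)}")
        return cls.from_frame(name or str(path), df)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment": SEGMENTS, "clo": self.clo_array, "im": self.im_array}
        )


def _bundled_frame() -> pd.DataFrame:
    text = resources.files("coldrisk.data").joinpath("ensembles.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def bundled_ensemble(name: str) -> EnsembleSpec:
    """Load one of the bundled ensembles: ``low_protection`` / ``high_protection``."""
    df = _bundled_frame()
    if name not in set(df["ensemble"]):
        raise ValidationError(
            f"unknown ensemble {name!r}; bundled: {sorted(set(df['ensemble']))}"
        )
    return EnsembleSpec.from_frame(name, df[df["ensemble"] == name])


def total_segment_resistance(
    clo: float,
    im: float,
    env: Environment,
    exposed: bool = False,
    still_air_clo: float = STILL_AIR_CLO,
    floor: float = WIND_FLOOR,
    decay: float = WIND_DECAY,
) -> SegmentResistances:
    """Total skin-to-air resistances of one segment.

    Clothed segments combine the garment layer (Table-derived clo and i_m)
    in series with the wind-adjusted boundary air layer; exposed skin sees
    only the air layer.
    """
    ia = air_layer_insulation(env.wind, still_air_clo, floor, decay)
    r_air = clo_to_rct(ia)
    ret_air = r_air / (AIR_LAYER_IM * LEWIS_RELATION)
    if exposed or clo == 0:
        return SegmentResistances(rct=r_air, ret=ret_air)
    r_cl = clo_to_rct(clo)
    ret_cl = ret_from_im(r_cl, im)
    return SegmentResistances(rct=r_cl + r_air, ret=ret_cl + ret_air)
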