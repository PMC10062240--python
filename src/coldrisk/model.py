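"""Two-node six-cylinder heat-balance model with cold-defence control.

Each body segment carries a core and a skin node; a central blood
compartment couples the segment cores, and an auxiliary thin "exposed skin"
node (the face) is perfused directly from the blood pool.  Cold defence is
modelled by two controllers driven by a common cold signal built from the
area-weighted mean skin temperature and the central blood temperature:

* vasoconstriction — the skin-perfusion conductance of each segment group
  (proximal, hands, feet, face) decays exponentially with the cold signal
  down to a group-specific minimum fraction; extremities constrict more
  steeply than the trunk;
* shivering — extra metabolic heat proportional to the product of the core
  and mean-skin deviations below their setpoints, clipped to a cap.

Heat leaves through dry exchange across the total segment resistance,
diffusion-limited evaporation (fixed 6% skin wetness: cold scenarios only),
and respiration.  Integration is fixed-step classical Runge-Kutta (RK4);
the integrator is vectorised over a leading batch dimension so parameter
sweeps and scenario suites run in a single pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from hashlib import sha256
from importlib import resources

import numpy as np

from .anthropometry import (
    SEGMENTS,
    BodyModel,
    ValidationError,
    build_body_model,
)
from .clothing import (
    AIR_LAYER_IM,
    LEWIS_RELATION,
    Environment,
    air_layer_insulation,
    clo_to_rct,
    ret_from_im,
    saturation_vapour_pressure,
)

__all__ = [
    "ControllerParams",
    "PhysioState",
    "Trajectory",
    "IntegrationError",
    "dry_heat_flux",
    "evaporative_heat_flux",
    "respiratory_heat_loss",
    "shivering_thermogenesis",
    "skin_blood_flow",
    "simulate",
    "simulate_batch",
    "crossing_times_batch",
]

#: Controller groups and segment membership (face is the auxiliary node).
GROUPS = ("prox", "hands", "feet", "face")
SEGMENT_GROUP = ("prox", "prox", "prox", "hands", "prox", "feet")

#: Skin diffusional wetness used in all cold scenarios.
SKIN_WETNESS = 0.06

#: Fraction of head area treated as exposed facial skin when uncovered.
FACE_AREA_FRACTION = 0.25

#: Whole-body metabolic heat allocation across segments.
MET_FRACTION = np.array([0.10, 0.70, 0.05, 0.025, 0.10, 0.025])

#: Shivering heat allocation (predominantly trunk musculature).
SHIVER_FRACTION = np.array([0.0, 0.85, 0.05, 0.0, 0.10, 0.0])

#: Thermal capacity of the central blood compartment, J/K.
BLOOD_CAPACITY = 2.5 * 3490.0

#: Core temperature below which the hypothermia flag is raised, °C.
HYPOTHERMIA_CORE = 35.0

_INIT_CORE = 37.0
_INIT_SKIN = 33.5


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class ControllerParams:
    """Cold-defence controller constants and boundary-layer wind law.

    This is the model's named calibration vector.  The packaged default
    (:meth:`defaults`) was obtained by searching these constants against
    the reference threshold-time tables; :meth:`off` disables both
    controllers for passive (open-loop) runs.

    Units: setpoints °C; ``shiver_gain`` W/K²; ``shiver_cap`` W;
    ``skin_blood`` W/(m² K) thermoneutral skin-perfusion conductance per
    group; ``vaso_gain`` 1/K of cold signal; ``min_flow`` dimensionless
    floor fraction; ``core_blood_distal`` W/K; ``civd_gain`` W/(m² K²)
    strength of cold-induced vasodilation (the hunting response) for hands
    and feet below ``civd_threshold`` °C; ``face_sheath_capacity``
    J/(m² K); wind constants as in :func:`~coldrisk.clothing.air_layer_insulation`.
    """

    core_setpoint: float = 36.8
    skin_setpoint: float = 33.7
    core_signal_weight: float = 4.0
    shiver_gain: float = 40.0
    shiver_cap: float = 350.0
    vaso_gain: dict = field(
        default_factory=lambda: {"prox": 0.25, "hands": 0.35, "feet": 0.5, "face": 3.5}
    )
    min_flow: dict = field(
        default_factory=lambda: {"prox": 0.15, "hands": 0.22, "feet": 0.08, "face": 0.003}
    )
    skin_blood: dict = field(
        default_factory=lambda: {"prox": 6.0, "hands": 20.0, "feet": 12.0, "face": 6.0}
    )
    core_blood_total: float = 35.0
    core_blood_distal: dict = field(
        default_factory=lambda: {"hands": 2.0, "feet": 1.5}
    )
    #: cold-induced vasodilation (hunting response): extra skin perfusion
    #: from the central pool, bell-shaped in local skin temperature with a
    #: peak a few degrees above freezing — the response is strongest just
    #: above the freezing point and wanes with deeper tissue cooling
    civd_gain: dict = field(default_factory=lambda: {"hands": 0.0, "feet": 0.0})
    civd_peak: float = 3.0
    civd_width: float = 3.0
    #: weight of the segment's own skin-temperature deficit in its
    #: vasoconstriction signal (local cooling constricts cutaneous vessels
    #: directly, on top of the central drive); 0 = purely central control.
    #: The deficit is measured below ``local_reference`` — extremity skin
    #: engages strong local constriction only well below thermoneutral
    local_gain: dict = field(default_factory=lambda: {"hands": 0.0, "feet": 0.0})
    local_reference: float = 20.0
    face_sheath_capacity: float = 1700.0
    still_air_clo: float = 0.70
    wind_floor: float = 0.25
    wind_decay: float = 0.05
    tissue_conductance: float = 5.0
    met_fraction: tuple = tuple(MET_FRACTION)
    shiver_fraction: tuple = tuple(SHIVER_FRACTION)
    enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("met_fraction", "shiver_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (6,) or abs(arr.sum() - 1.0) > 1e-9 or np.any(arr < 0):
                raise ValidationError(f"{name} must be 6 non-negative values summing to 1")
        if not (200.0 <= self.shiver_cap <= 600.0):
            raise ValidationError("shiver_cap must lie in [200, 600] W")
        if not (36.0 <= self.core_setpoint <= 38.0):
            raise ValidationError("core_setpoint must lie in [36, 38] °C")
        if not (30.0 <= self.skin_setpoint <= 35.0):
            raise ValidationError("skin_setpoint must lie in [30, 35] °C")
        for d in (self.vaso_gain, self.min_flow, self.skin_blood):
            missing = set(GROUPS) - set(d)
            if missing:
                raise ValidationError(f"missing controller groups {sorted(missing)}")

    @classmethod
    def off(cls) -> "ControllerParams":
        """Controllers disabled: no shivering, perfusion pinned at baseline."""
        return cls(
            shiver_gain=0.0,
            vaso_gain={g: 0.0 for g in GROUPS},
            min_flow={g: 1.0 for g in GROUPS},
            enabled=False,
        )

    @classmethod
    def defaults(cls) -> "ControllerParams":
        """The bundled calibrated vector."""
        text = resources.files("coldrisk.data").joinpath("calibration.json").read_text()
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerParams":
        return cls(**d)

    def replace(self, **kw) -> "ControllerParams":
        return replace(self, **kw)

    @property
    def digest(self) -> str:
        """Short content hash identifying the calibration vector."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return sha256(blob).hexdigest()[:12]


@dataclass
class PhysioState:
    """Instantaneous physiological state of the model."""

    core: np.ndarray          # (6,) segment core temperatures, °C
    skin: np.ndarray          # (6,) segment skin temperatures, °C
    blood: float              # central blood temperature, °C
    face: float               # exposed facial skin temperature, °C
    shiver_energy: float = 0.0  # cumulative shivering heat, J
    skin_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.07, 0.36, 0.14, 0.05, 0.31, 0.07])
    )

    @property
    def mean_skin(self) -> float:
        """Area-weighted mean skin temperature, °C."""
        return float(np.dot(self.skin_weights, self.skin))


# ---------------------------------------------------------------------------
# Elemental heat-flow operations (vectorised; used directly by the integrator)
# ---------------------------------------------------------------------------

def dry_heat_flux(t_skin, ta, rct):
    """Sensible heat flux skin→environment, W/m²: ``(t_skin − ta) / rct``."""
    rct = np.asarray(rct, dtype=float)
    if np.any(rct <= 0):
        raise ValidationError("rct must be > 0")
    out = (np.asarray(t_skin, dtype=float) - ta) / rct
    return out if out.ndim else float(out)


def evaporative_heat_flux(t_skin, env: Environment, ret, wetness=SKIN_WETNESS):
    """Latent heat flux skin→environment, W/m², floored at zero.

    ``wetness * (p_sat(t_skin) − rh * p_sat(ta)) / ret`` — diffusion-limited
    sweating only (no thermoregulatory sweating below the setpoints).
    """
    ret = np.asarray(ret, dtype=float)
    if np.any(ret <= 0):
        raise ValidationError("ret must be > 0")
    grad = saturation_vapour_pressure(t_skin) - env.vapour_pressure
    out = np.maximum(0.0, wetness * np.asarray(grad) / ret)
    return out if out.ndim else float(out)


def respiratory_heat_loss(met, env: Environment):
    """Respiratory (sensible + latent) heat loss, W, floored at zero.

    ``0.0014·met·(34 − ta) + 0.0173·met·(5.87 − pa)`` with ambient vapour
    pressure ``pa`` in kPa.
    """
    met = np.asarray(met, dtype=float)
    if np.any(met <= 0):
        raise ValidationError("met must be > 0")
    pa = env.vapour_pressure
    out = np.maximum(0.0, 0.0014 * met * (34.0 - env.ta) + 0.0173 * met * (5.87 - pa))
    return out if out.ndim else float(out)


def shivering_thermogenesis(state: PhysioState, params: ControllerParams) -> float:
    """Shivering heat production, W, clipped to ``[0, shiver_cap]``.

    ``gain × max(0, core_set − t_core) × max(0, skin_set − mean_skin)``.
    """
    d_core = max(0.0, params.core_setpoint - state.blood)
    d_skin = max(0.0, params.skin_setpoint - state.mean_skin)
    return float(np.clip(params.shiver_gain * d_core * d_skin, 0.0, params.shiver_cap))


def _cold_signal(mean_skin, blood, params: ControllerParams):
    return np.maximum(0.0, params.skin_setpoint - mean_skin) + (
        params.core_signal_weight * np.maximum(0.0, params.core_setpoint - blood)
    )


def _flow_fraction(signal, gain, floor):
    return np.clip(np.exp(-gain * np.asarray(signal)), floor, 1.0)


def skin_blood_flow(
    state: PhysioState, params: ControllerParams, body: BodyModel | None = None
) -> np.ndarray:
    """Per-segment skin-perfusion conductance addition, W/K.

    At thermoneutrality each segment contributes its baseline
    ``skin_blood[group] × area``; the common cold signal scales this down
    multiplicatively, never below ``min_flow[group]`` of baseline, with
    steeper constriction in the extremities than in the trunk.
    """
    from .anthropometry import REFERENCE_BODY  # default geometry

    body = body or build_body_model(REFERENCE_BODY)
    sig = _cold_signal(state.mean_skin, state.blood, params)
    out = np.empty(6)
    for i, g in enumerate(SEGMENT_GROUP):
        phi = _flow_fraction(sig, params.vaso_gain[g], params.min_flow[g])
        out[i] = phi * params.skin_blood[g] * body.area[i]
    return out


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Recorded time course of a simulation plus heat-flow diagnostics.

    ``time`` is in seconds on a uniform grid; temperatures in °C; fluxes in
    W (whole-segment, not per area).
    """

    time: np.ndarray          # (n,)
    core: np.ndarray          # (n, 6)
    skin: np.ndarray          # (n, 6)
    blood: np.ndarray         # (n,)
    face: np.ndarray          # (n,)
    dry: np.ndarray           # (n, 6) dry loss per segment, W
    evap: np.ndarray          # (n, 6) evaporative loss per segment, W
    face_dry: np.ndarray      # (n,)
    face_evap: np.ndarray     # (n,)
    respiratory: np.ndarray   # (n,)
    shiver: np.ndarray        # (n,) shivering power, W
    metabolic_rate: float
    skin_weights: np.ndarray
    label: str = ""
    params_digest: str = ""
    core_capacity: np.ndarray | None = None    # J/K, (6,)
    skin_capacity: np.ndarray | None = None    # J/K, (6,)
    face_capacity: float = 0.0                 # J/K
    blood_capacity: float = 0.0                # J/K

    @property
    def minutes(self) -> np.ndarray:
        return self.time / 60.0

    @property
    def mean_skin(self) -> np.ndarray:
        return self.skin @ self.skin_weights

    def series(self, node: str) -> np.ndarray:
        """Temperature series for a named node.

        Accepted names: ``exposed_skin`` (alias ``face``), ``blood``,
        ``hands`` / ``feet`` (their skin nodes), ``skin:<segment>`` and
        ``core:<segment>``.
        """
        if node in ("exposed_skin", "face"):
            return self.face
        if node == "blood":
            return self.blood
        if node in SEGMENTS:
            return self.skin[:, SEGMENTS.index(node)]
        kind, _, seg = node.partition(":")
        if seg in SEGMENTS and kind in ("skin", "core"):
            arr = self.skin if kind == "skin" else self.core
            return arr[:, SEGMENTS.index(seg)]
        raise ValidationError(f"unknown node {node!r}")

    def to_dataframe(self):
        import pandas as pd

        data = {"time_s": self.time}
        for i, s in enumerate(SEGMENTS):
            data[f"core_{s}"] = self.core[:, i]
        for i, s in enumerate(SEGMENTS):
            data[f"skin_{s}"] = self.skin[:, i]
        data["blood"] = self.blood
        data["exposed_skin"] = self.face
        for i, s in enumerate(SEGMENTS):
            data[f"dry_{s}"] = self.dry[:, i]
        for i, s in enumerate(SEGMENTS):
            data[f"evap_{s}"] = self.evap[:, i]
        data["dry_face"] = self.face_dry
        data["evap_face"] = self.face_evap
        data["respiratory"] = self.respiratory
        data["shiver"] = self.shiver
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "label": self.label,
            "duration_min": float(self.minutes[-1]),
            "min_core": float(self.blood.min()),
            "final_mean_skin": float(self.mean_skin[-1]),
            "final_feet_skin": float(self.skin[-1, SEGMENTS.index("feet")]),
            "final_hands_skin": float(self.skin[-1, SEGMENTS.index("hands")]),
            "final_exposed_skin": float(self.face[-1]),
            "shiver_peak_w": float(self.shiver.max()),
            "params_digest": self.params_digest,
        }

    def plot(self, ax=None):
        """Time-course plot: per-node temperatures against exposure time.

        Requires matplotlib (optional dependency).  Returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        m = self.minutes
        ax.plot(m, self.blood, label="core (blood)", lw=2, color="k")
        ax.plot(m, self.mean_skin, label="mean skin", lw=1.5, color="tab:gray")
        for seg, color in (("hands", "tab:orange"), ("feet", "tab:red")):
            ax.plot(m, self.series(seg), label=f"{seg} skin", color=color)
        ax.plot(m, self.face, label="exposed skin", color="tab:blue")
        for thr, style in ((8.0, ":"), (5.0, "--"), (1.0, "-.")):
            ax.axhline(thr, color="0.8", ls=style, lw=0.8)
        ax.set_xlabel("exposure time (min)")
        ax.set_ylabel("temperature (°C)")
        ax.set_title(self.label or "trajectory")
        ax.legend(loc="best", fontsize=8)
        return ax

    def energy_audit(self) -> dict:
        """Closed heat-balance bookkeeping over the recorded trajectory.

        Compares the change in total body heat content against the time
        integral (trapezoid) of metabolic + shivering input minus dry,
        evaporative and respiratory losses.  Returns the two energies, their
        residual, and the total metabolic energy used to normalise it.
        """
        if self.core_capacity is None:
            raise ValidationError("trajectory carries no capacity metadata")
        d_heat = (
            float(self.core_capacity @ (self.core[-1] - self.core[0]))
            + float(self.skin_capacity @ (self.skin[-1] - self.skin[0]))
            + self.blood_capacity * float(self.blood[-1] - self.blood[0])
            + self.face_capacity * float(self.face[-1] - self.face[0])
        )
        net = (
            self.metabolic_rate
            + self.shiver
            - self.dry.sum(axis=1)
            - self.evap.sum(axis=1)
            - self.face_dry
            - self.face_evap
            - self.respiratory
        )
        net_energy = float(np.trapezoid(net, self.time))
        met_energy = float(np.trapezoid(self.metabolic_rate + self.shiver, self.time))
        return {
            "delta_heat_j": d_heat,
            "net_input_j": net_energy,
            "residual_j": d_heat - net_energy,
            "metabolic_energy_j": met_energy,
        }


# ---------------------------------------------------------------------------
# Batched integrator
# ---------------------------------------------------------------------------

class _Packed:
    """Scenario/parameter arrays broadcast over a batch dimension."""

    def __init__(self, scenarios, params_list):
        B = len(scenarios)
        assert len(params_list) == B
        self.B = B
        self.area = np.empty((B, 6))        # environmental exchange area
        self.w_skin = np.empty((B, 6))      # mean-skin weights (area fractions)
        self.cc = np.empty((B, 6))
        self.csk = np.empty((B, 6))
        self.kcond = np.empty((B, 6))
        self.rct = np.empty((B, 6))
        self.ret = np.empty((B, 6))
        self.ta = np.empty(B)
        self.pa = np.empty(B)
        self.met = np.empty(B)
        self.met_frac = np.empty((B, 6))
        self.shiv_frac = np.empty((B, 6))
        self.k_vaso = np.empty((B, 6))
        self.fmin = np.empty((B, 6))
        self.g0a = np.empty((B, 6))         # baseline skin-blood conductance, W/K
        self.cb_fixed = np.empty((B, 6))    # proximal core-blood conductance, W/K
        self.cb0 = np.empty((B, 6))         # constrictable distal core-blood, W/K
        self.civd = np.zeros((B, 6))        # hunting-response conductance, W/K
        self.civd_peak = np.empty(B)
        self.civd_width = np.empty(B)
        self.local_gain = np.zeros((B, 6))  # local-cooling constriction weight
        self.local_ref = np.empty(B)
        self.k_face = np.empty(B)
        self.fmin_face = np.empty(B)
        self.g0a_face = np.empty(B)
        self.c_face = np.empty(B)
        self.a_face = np.empty(B)
        self.r_face = np.empty(B)
        self.ret_face = np.empty(B)
        self.core_set = np.empty(B)
        self.skin_set = np.empty(B)
        self.w_core = np.empty(B)
        self.sh_gain = np.empty(B)
        self.sh_cap = np.empty(B)

        distal = {"hands": SEGMENTS.index("hands"), "feet": SEGMENTS.index("feet")}
        for b, (sc, p) in enumerate(zip(scenarios, params_list)):
            body = build_body_model(
                sc.body,
                fractions=getattr(sc, "fractions", None),
                tissue_conductance=p.tissue_conductance,
            )
            env = sc.environment
            ia = air_layer_insulation(env.wind, p.still_air_clo, p.wind_floor, p.wind_decay)
            r_air = clo_to_rct(ia)
            ret_air = r_air / (AIR_LAYER_IM * LEWIS_RELATION)
            clo = sc.ensemble.clo_array
            im = sc.ensemble.im_array
            r_cl = clo * 0.155
            with np.errstate(divide="ignore"):
                ret_cl = np.where(r_cl > 0, r_cl / (np.maximum(im, 1e-12) * LEWIS_RELATION), 0.0)
            self.rct[b] = r_cl + r_air
            self.ret[b] = ret_cl + ret_air

            a_face = FACE_AREA_FRACTION * body.area[0] if sc.exposed_face else 0.0
            area = body.area.copy()
            area[0] -= a_face
            self.area[b] = area
            self.w_skin[b] = body.area_fraction
            c_face_real = p.face_sheath_capacity * a_face
            c_face = max(c_face_real, 1.0)  # decoupled dummy node when covered
            self.cc[b] = body.core_heat_capacity
            csk = body.skin_heat_capacity.copy()
            csk[0] = max(csk[0] - c_face_real, 0.5 * body.skin_heat_capacity[0])
            self.csk[b] = csk
            self.kcond[b] = body.core_skin_conductance
            self.ta[b] = env.ta
            self.pa[b] = env.vapour_pressure
            self.met[b] = sc.metabolic_rate
            self.met_frac[b] = np.asarray(p.met_fraction, dtype=float)
            self.shiv_frac[b] = np.asarray(p.shiver_fraction, dtype=float)

            for i, g in enumerate(SEGMENT_GROUP):
                self.k_vaso[b, i] = p.vaso_gain[g]
                self.fmin[b, i] = p.min_flow[g]
                self.g0a[b, i] = p.skin_blood[g] * body.area[i]
            self.cb_fixed[b] = p.core_blood_total * self.met_frac[b]
            self.cb0[b] = 0.0
            for g, i in distal.items():
                self.cb_fixed[b, i] = 0.0
                self.cb0[b, i] = p.core_blood_distal[g]
                self.civd[b, i] = p.civd_gain.get(g, 0.0) * body.area[i]
                self.local_gain[b, i] = p.local_gain.get(g, 0.0)
            self.civd_peak[b] = p.civd_peak
            self.civd_width[b] = p.civd_width
            self.local_ref[b] = p.local_reference

            self.k_face[b] = p.vaso_gain["face"]
            self.fmin_face[b] = p.min_flow["face"]
            self.g0a_face[b] = p.skin_blood["face"] * a_face
            self.c_face[b] = c_face
            self.a_face[b] = a_face
            self.r_face[b] = r_air
            self.ret_face[b] = ret_air
            self.core_set[b] = p.core_setpoint
            self.skin_set[b] = p.skin_setpoint
            self.w_core[b] = p.core_signal_weight
            self.sh_gain[b] = p.shiver_gain
            self.sh_cap[b] = p.shiver_cap

    def initial_state(self) -> np.ndarray:
        s = np.empty((self.B, 14))
        s[:, :6] = _INIT_CORE
        s[:, 6:12] = _INIT_SKIN
        s[:, 12] = _INIT_CORE
        s[:, 13] = _INIT_SKIN
        return s

    def rhs(self, state: np.ndarray, extras: dict | None = None) -> np.ndarray:
        tc = state[:, :6]
        tsk = state[:, 6:12]
        tbl = state[:, 12]
        tf = state[:, 13]

        mean_sk = np.einsum("bi,bi->b", self.w_skin, tsk)
        sig = np.maximum(0.0, self.skin_set - mean_sk) + self.w_core * np.maximum(
            0.0, self.core_set - tbl
        )
        sig_seg = sig[:, None] + self.local_gain * np.maximum(
            0.0, self.local_ref[:, None] - tsk
        )
        phi = np.clip(np.exp(-self.k_vaso * sig_seg), self.fmin, 1.0)
        phi_f = np.clip(np.exp(-self.k_face * sig), self.fmin_face, 1.0)

        ksk = self.kcond + phi * self.g0a
        kcb = self.cb_fixed + phi * self.cb0
        shiv = np.clip(
            self.sh_gain
            * np.maximum(0.0, self.core_set - tbl)
            * np.maximum(0.0, self.skin_set - mean_sk),
            0.0,
            self.sh_cap,
        )
        m_tot = self.met + shiv
        resp = np.maximum(
            0.0,
            0.0014 * m_tot * (34.0 - self.ta) + 0.0173 * m_tot * (5.87 - self.pa),
        )

        q_dry = self.area * (tsk - self.ta[:, None]) / self.rct
        q_evap = self.area * SKIN_WETNESS * np.maximum(
            0.0, saturation_vapour_pressure(tsk) - self.pa[:, None]
        ) / self.ret
        qf_dry = self.a_face * (tf - self.ta) / self.r_face
        qf_evap = self.a_face * SKIN_WETNESS * np.maximum(
            0.0, saturation_vapour_pressure(tf) - self.pa
        ) / self.ret_face
        kbf_face = phi_f * self.g0a_face

        cond = ksk * (tc - tsk)
        # hunting response: extra skin perfusion from the central pool,
        # bell-shaped in local skin temperature around the CIVD peak
        k_civd = self.civd * np.exp(
            -(((tsk - self.civd_peak[:, None]) / self.civd_width[:, None]) ** 2)
        )
        q_civd = k_civd * (tbl[:, None] - tsk)
        resp_vec = np.zeros_like(tc)
        resp_vec[:, 1] = resp
        d_tc = (
            self.met[:, None] * self.met_frac
            + shiv[:, None] * self.shiv_frac
            - cond
            - resp_vec
            + kcb * (tbl[:, None] - tc)
        ) / self.cc
        d_tsk = (cond + q_civd - q_dry - q_evap) / self.csk
        d_tbl = (
            np.einsum("bi,bi->b", kcb, tc - tbl[:, None])
            - q_civd.sum(axis=1)
            + kbf_face * (tf - tbl)
        ) / BLOOD_CAPACITY
        d_tf = (kbf_face * (tbl - tf) - qf_dry - qf_evap) / self.c_face

        if extras is not None:
            extras.update(
                dry=q_dry, evap=q_evap, face_dry=qf_dry, face_evap=qf_evap,
                resp=resp, shiv=shiv,
            )
        out = np.empty_like(state)
        out[:, :6] = d_tc
        out[:, 6:12] = d_tsk
        out[:, 12] = d_tbl
        out[:, 13] = d_tf
        return out


def _rk4_step(packed: _Packed, state: np.ndarray, dt: float) -> np.ndarray:
    k1 = packed.rhs(state)
    k2 = packed.rhs(state + 0.5 * dt * k1)
    k3 = packed.rhs(state + 0.5 * dt * k2)
    k4 = packed.rhs(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _check_dt(dt: float) -> None:
    if not (0.5 <= dt <= 60.0):
        raise ValidationError(f"dt={dt!r} s outside admissible range [0.5, 60]")


def simulate_batch(scenarios, params_list=None, dt: float = 1.0, record_every: int = 1):
    """Integrate several scenarios side by side; returns a list of Trajectory.

    ``record_every`` keeps every k-th step in the output (the integration
    step itself is always ``dt``).
    """
    _check_dt(dt)
    if params_list is None:
        params_list = [ControllerParams.defaults()] * len(scenarios)
    elif isinstance(params_list, ControllerParams):
        params_list = [params_list] * len(scenarios)
    for sc in scenarios:
        if sc.duration_min * 60.0 < dt:
            raise ValidationError("duration must be at least one time step")
    n_steps = int(round(max(sc.duration_min for sc in scenarios) * 60.0 / dt))
    packed = _Packed(scenarios, params_list)
    state = packed.initial_state()

    rec_idx = list(range(0, n_steps + 1, record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    n_rec = len(rec_idx)
    B = packed.B
    rec = {
        "core": np.empty((n_rec, B, 6)), "skin": np.empty((n_rec, B, 6)),
        "blood": np.empty((n_rec, B)), "face": np.empty((n_rec, B)),
        "dry": np.empty((n_rec, B, 6)), "evap": np.empty((n_rec, B, 6)),
        "face_dry": np.empty((n_rec, B)), "face_evap": np.empty((n_rec, B)),
        "resp": np.empty((n_rec, B)), "shiv": np.empty((n_rec, B)),
        "t": np.empty(n_rec),
    }

    def record(j, step, st):
        extras: dict = {}
        packed.rhs(st, extras)
        rec["core"][j] = st[:, :6]
        rec["skin"][j] = st[:, 6:12]
        rec["blood"][j] = st[:, 12]
        rec["face"][j] = st[:, 13]
        for k in ("dry", "evap", "face_dry", "face_evap", "resp", "shiv"):
            rec[k][j] = extras[k]
        rec["t"][j] = step * dt

    next_rec = 0
    for step in range(n_steps + 1):
        if next_rec < n_rec and step == rec_idx[next_rec]:
            record(next_rec, step, state)
            next_rec += 1
        if step < n_steps:
            state = _rk4_step(packed, state, dt)
            if step % 200 == 0 and not np.all(np.isfinite(state)):
                raise IntegrationError(f"non-finite state at step {step}")
    if not np.all(np.isfinite(state)):
        raise IntegrationError(f"non-finite state at step {n_steps}")

    out = []
    for b, (sc, p) in enumerate(zip(scenarios, params_list)):
        out.append(
            Trajectory(
                time=rec["t"].copy(),
                core=rec["core"][:, b], skin=rec["skin"][:, b],
                blood=rec["blood"][:, b], face=rec["face"][:, b],
                dry=rec["dry"][:, b], evap=rec["evap"][:, b],
                face_dry=rec["face_dry"][:, b], face_evap=rec["face_evap"][:, b],
                respiratory=rec["resp"][:, b], shiver=rec["shiv"][:, b],
                metabolic_rate=sc.metabolic_rate,
                skin_weights=packed.w_skin[b].copy(),
                label=sc.label, params_digest=p.digest,
                core_capacity=packed.cc[b].copy(),
                skin_capacity=packed.csk[b].copy(),
                face_capacity=float(packed.c_face[b]),
                blood_capacity=BLOOD_CAPACITY,
            )
        )
    return out


def simulate(scenario, params: ControllerParams | None = None, dt: float = 1.0,
             record_every: int = 1) -> Trajectory:
    """Integrate one scenario; see :func:`simulate_batch`."""
    params = params or ControllerParams.defaults()
    return simulate_batch([scenario], [params], dt=dt, record_every=record_every)[0]


#: Probe nodes available to the fast crossing tracker.
_PROBE_INDEX = {"feet": 6 + SEGMENTS.index("feet"),
                "hands": 6 + SEGMENTS.index("hands"),
                "face": 13, "exposed_skin": 13}


def crossing_times_batch(scenarios, params_list, probes, dt: float = 2.0):
    """First downward-crossing times (minutes) without storing trajectories.

    ``probes`` is a sequence of ``(node, threshold)`` pairs with node in
    ``{feet, hands, exposed_skin}``.  Returns ``(times, min_core,
    min_node)`` where ``times`` has shape (B, n_probes) with NaN for no
    crossing, ``min_core`` is the running minimum of the central blood
    temperature and ``min_node`` the running minimum of each probe node.
    Used by the calibration search.
    """
    _check_dt(dt)
    if isinstance(params_list, ControllerParams):
        params_list = [params_list] * len(scenarios)
    n_steps = int(round(max(sc.duration_min for sc in scenarios) * 60.0 / dt))
    packed = _Packed(scenarios, params_list)
    state = packed.initial_state()
    B = packed.B
    idx = np.array([_PROBE_INDEX[node] for node, _ in probes])
    thr = np.array([t for _, t in probes], dtype=float)
    times = np.full((B, len(probes)), np.nan)
    min_core = np.full(B, np.inf)

    prev = state[:, idx]
    min_node = prev.copy()
    min_core = np.minimum(min_core, state[:, 12])
    for step in range(n_steps):
        state = _rk4_step(packed, state, dt)
        if step % 500 == 0 and not np.all(np.isfinite(state)):
            raise IntegrationError(f"non-finite state at step {step}")
        cur = state[:, idx]
        hit = (cur <= thr) & (prev > thr) & np.isnan(times)
        if np.any(hit):
            denom = prev - cur
            safe = np.where(denom > 1e-12, denom, 1.0)
            frac = np.where(denom > 1e-12, (prev - thr) / safe, 1.0)
            t_cross = (step + frac) * dt / 60.0
            times[hit] = t_cross[hit]
        prev = cur
        np.minimum(min_node, cur, out=min_node)
        min_core = np.minimum(min_core, state[:, 12])
    return times, min_core, min_node
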