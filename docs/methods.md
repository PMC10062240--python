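# Methods

`coldrisk` predicts how long a clothed, working human can be exposed to cold
air before skin reaches injury thresholds, and whether core temperature
approaches hypothermia.  This note documents the model, its assumptions, the
constants that matter, and what the tests do and do not demonstrate.

## Model structure

The body is six cylinders — head, torso, arms, hands, legs, feet — each with
a **core** node (90% of segment mass) and a **skin** node (10%), plus a
central **blood** compartment and a thin **exposed-skin** (face) node.  That
is 14 state variables.  Tissue specific heat is 3490 J/(kg·K); the blood
pool carries 2.5 kg-equivalent.

Whole-body inputs are partitioned with a fraction table (overridable per
scenario).  Area fractions are a Stolwijk-style split (head 0.07, torso
0.36, arms 0.14, hands 0.05, legs 0.31, feet 0.07).  Mass fractions use
anatomical segment masses for the extremities (hands 0.012, feet 0.025 of
body mass, i.e. ≈0.5 kg per hand and ≈1.05 kg per foot for the reference
83.5 kg body; torso 0.49, legs 0.273, arms 0.13, head 0.07).  The light
distal masses matter: with several-fold heavier hands or feet the maximum
possible dry heat loss through the tabulated boot/glove insulation cannot
drain the segment's heat content on the tens-of-minutes timescale that
cold-chamber and field experience show for extremity cooling — the choice is
forced by an energy budget, not tuned to any particular output.

Surface area uses DuBois, `A_D = 0.202·m^0.425·h^0.725` (1.99 m² for the
1.75 m / 83.5 kg reference body).  Core→skin tissue conductance per segment
is `5.0 W/(m²K) × area × (1 − 0.9·body_fat)`: subcutaneous fat insulates
the core, so a fatter body has a lower conductance; the factor is a
calibratable engineering rule, not asserted physiology.

### Heat flows

Per segment, with temperatures in °C, conductances in W/K:

* skin node:  `C_sk·dT_sk/dt = K(T_c − T_sk) − Q_dry − Q_evap`
* core node:  `C_c·dT_c/dt = M_i + S_i − K(T_c − T_sk) − R_i + K_cb(T_bl − T_c)`
* blood:      `C_bl·dT_bl/dt = Σ K_cb,i (T_c,i − T_bl) + K_bf,f (T_f − T_bl)`
* face:       `C_f·dT_f/dt = K_bf,f (T_bl − T_f) − Q_dry,f − Q_evap,f`

where `K = K_tissue + K_perfusion(t)` (vasoconstriction acts on the
perfusion part), `M_i` is the segment's share of whole-body metabolic rate
(70% torso, 10% head, 10% legs, 5% arms, 2.5% each hand/foot group), `S_i`
the shivering share (85% torso, 10% legs, 5% arms), and `R_i` the
respiratory loss (torso only).

Dry loss is `A·(T_sk − T_a)/R_ct` through the total dry resistance
`R_ct = 0.155·clo + 0.155·I_a(wind)`: the tabulated garment clo in series
with the boundary air layer, `I_a = 0.70·(floor + (1−floor)·e^(−k·wind))`
clo (defaults floor 0.25, k 0.05 per km/h; both part of the calibration
vector).  Wind therefore erodes only the air layer, never the garment
value.  Evaporative loss is diffusion-limited:
`A·w·(p_sat(T_sk) − p_a)/R_et` with fixed skin wetness w = 0.06 (no
thermoregulatory sweating in cold), `R_et = R_ct,cl/(i_m·16.5) +
R_a/(0.5·16.5)` via the Lewis relation, and `p_sat` the Buck curve over
(supercooled) water.  Respiratory loss is the standard
`0.0014·M·(34 − T_a) + 0.0173·M·(5.87 − p_a)` with M including shivering.

### Control

A central cold signal drives both effectors:
`s = (T_sk,set − T̄_sk)₊ + w_c·(36.8 − T_bl)₊` (area-weighted mean skin;
the core term is weighted because core deviations are small but potent).

* **Vasoconstriction.** Each group g ∈ {proximal, hands, feet, face} scales
  its thermoneutral skin-perfusion conductance `g0_g·A_i` by
  `φ_g = clip(e^(−k_g·s_i), f_min,g, 1)`.  For the extremities the signal
  carries an additional local component,
  `s_i = s + λ_g·(T_ref − T_sk,i)₊`: local cooling constricts cutaneous
  vessels directly, measured below a local reference temperature `T_ref`
  well under the central setpoint.  Extremity gains are steeper than
  proximal ones, and the face floor is near zero — exposed facial skin in
  severe cold is essentially unperfused, which is what lets it fall toward
  (and slightly below) air temperature under evaporation.  Hands and feet
  additionally have their core-to-blood conductance scaled by the same φ
  (distal arterial inflow constricts too); proximal segments keep a fixed
  core-blood coupling proportional to their metabolic share.
* **Cold-induced vasodilation (hunting response).**  Extremity skin
  receives perfusion directly from the central pool through a conductance
  that is bell-shaped in the local skin temperature,
  `k_CIVD,i = c_g·A_i·exp(−((T_sk,i − T_peak)/w)²)`, with the peak a few
  degrees above freezing — the hunting response is strongest just above
  the tissue freezing point and wanes both at warmer skin and with deeper
  cooling.  This is what arrests extremity cooling near the frostbite
  threshold instead of letting the skin slide to ambient.
* **Shivering.** `S = clip(gain·(36.8 − T_bl)₊·(T_sk,set − T̄_sk)₊, 0, cap)`
  W whole-body, cap 350 W.

The face node is a thin sheath (calibratable areal capacity, ≈1.7 kJ/(m²K),
i.e. ≈0.5 mm of tissue) carved out of the head skin node over 25% of head
area, coupled to the body only through its perfusion conductance.  A fixed
conduction path from the deep head core was deliberately omitted: facial
skin overlies bone and sinus, not the brain core, and any appreciable fixed
coupling pins the face several degrees above air temperature, contradicting
the near-immediate facial numbness/pain onsets observed in mild wind-chill
conditions.

## Numerical scheme

Fixed-step classical Runge-Kutta (RK4), default dt = 1 s, initial state
core 37.0 °C / skin 33.5 °C everywhere, no pre-stabilisation run.  The
system is non-stiff at this step (fastest node time constant ≈ 2 min);
halving dt moves no reported threshold time by more than a reporting bin
(tested).  The integrator is vectorised over a batch dimension, so the
ten-scenario suite, parameter-search populations and the monotonicity
battery each run as one pass.  Threshold crossings are linearly
interpolated between steps, then snapped to the 5-minute reporting grid
(ties down); times under 10 min print as "<10 min" and crossings beyond
250 min are censored to "-".  Energy bookkeeping closes to ≲10⁻⁵ of
metabolic input (trapezoid audit of recorded fluxes against heat-content
change).

## Calibration

The reference decision-aid's internal controller constants are not public;
its *outputs* are: two tables of threshold times for ten standard scenarios
(printed on a 5-min grid, 14 finite cells, plus "<10 min" floors and
censored cells).  The 28-component calibration vector — perfusion baselines,
vasoconstriction gains and floors per group, local-signal weights and
reference, CIVD amplitude/peak/width, distal core-perfusion conductances,
face sheath capacity, shivering gain, setpoints, still-air and wind-decay
constants — was searched with seeded differential evolution and group-wise
coordinate descent (vectorised population evaluation at dt = 5 and 2 s)
and finished with coordinate polishing at the dt = 1 s reporting step.
The loss is the squared error of finite cells in units of reporting bins
(capped per cell so an unreachable cell cannot distort the rest), a
continuous distance-to-threshold term when a required crossing never
happens, hinge penalties for censored cells that cross before 255 min and
floor cells that cross after 9 min, and a hinge keeping minimum core
temperature above 35.3 °C.  The winning vector ships as
`src/coldrisk/data/calibration.json` and is the package default;
`coldrisk calibrate` re-runs a search.

What the calibration reproduces — and what it does not.  With the packaged
vector (quantities the acceptance suite recomputes): both hand/finger
dexterity-loss times (205 and 65 min), the exposed-skin pain time at 5 °C
(40 min), every hand and exposed-skin floor/censor cell except one
borderline floor (exposed-skin pain at 5 °C, low protection: 10.8 min vs
"<10 min"), and the no-hypothermia outcome (minimum core 36.9 °C) land on
the reference grid cells.  The foot/toe block does not fit: its finite
times carry systematic residuals of roughly 15–40 min and two cells stall
just above their thresholds.  The reference foot times switch between
regimes in a way that, in a two-node foot, would require the deep-cold
perfusion to differ in opposite directions between boot types at similar
foot temperatures; no single supply law of local and central state can
satisfy all four scenarios at once, so this residual is a structural limit
of the two-node cylinder (the reference model is a multilayer hybrid), not
a calibration shortfall.  Users should read predicted foot times as
indicative (tens of minutes, correct ordering across conditions) rather
than cell-exact.

## Synthetic scenarios

`coldrisk.synthetic` draws uniform, independent scenario parameters over
ranges bracketing the reference conditions (Ta −40…10 °C, wind 0…40 km/h,
met 100…400 W, per-segment clo 0.3…7, …).  It emulates *coverage*, not
demography: no joint structure, no realistic co-variation of body size and
clothing.  Ordered pairs differ on exactly one axis (warmer air, uniformly
higher clo, higher met) and feed the monotonicity battery.  Passing those
properties shows the model is internally coherent over the plausible input
space; it does not validate predictions against human cold-injury data
beyond the calibrated reference tables.

## Tunable parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| tissue conductance | 5.0 | W/(m²K) | passive core→skin coupling |
| skin wetness | 0.06 | — | diffusional evaporation |
| skin/core setpoints | calibrated / 36.8 | °C | controller thresholds |
| shivering gain / cap | calibrated / 350 | W/K² / W | cold-induced thermogenesis |
| vaso gains k_g | calibrated | 1/K | constriction steepness per group |
| local weight λ_g, reference T_ref | calibrated | —, °C | local cold constriction (extremities) |
| CIVD amplitude / peak / width | calibrated | W/(m²K), °C, K | hunting response |
| min flow f_min,g | calibrated | — | deep-cold perfusion floor |
| still-air layer / wind decay | calibrated ≈1.0 clo / calibrated | — | boundary layer law |
| face sheath capacity | calibrated ≈500 | J/(m²K) | exposed-skin response speed |
| dt | 1 | s | integration step (0.5–60 allowed) |

## Degenerate inputs and edge rules

Zero clo with `exposed=False` equals bare skin; wind ≤ 0.5 km/h counts as
still air; evaporative and respiratory fluxes are floored at zero (no
condensation heat gain); non-finite states abort integration with the step
index; scenario configs reject unknown keys and out-of-range values naming
the offending field.

## Known limitations

* Foot/toe threshold times reproduce the correct ordering and magnitude
  across conditions but not the reference tables cell-exactly (see the
  calibration section); hand, exposed-skin and core predictions are
  grid-exact.
* The two-node cylinders have no digit resolution: "hands/fingers" is the
  whole-hand skin node, so finger-tip times are optimistic.
* No wet-clothing, immersion, or moisture-accumulation effects; wetness is
  fixed at its diffusion floor.
* No posture/contact conduction (e.g. seated contact with cold metal in a
  vehicle), no radiant asymmetry or solar load.
* Underfeeding, fatigue, dehydration and individual variability are not
  modelled; predictions are best-case group averages for a healthy young
  man, and each unmodelled stressor would shorten real injury times.
* The hypothermia output is a flag on central core temperature (< 35 °C),
  not a survival-time model.
* The frostbite threshold is the conservative 1 °C modelling convention;
  actual skin freezing occurs below −0.6 to −4.8 °C.
* The bundled high-protection hands i_m of 0.94 is unusually high for
  mittens; the value is used verbatim from the source measurement table.
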