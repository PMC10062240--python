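"""Model sanity properties on random scenarios: energy closure and monotonicity.

Draws seeded random-but-plausible scenarios, verifies that the heat-balance
bookkeeping closes, and that making a scenario strictly milder on one axis
(warmer air, more insulation, higher work rate) never makes any reported
injury time earlier.
"""

import numpy as np

from coldrisk import ControllerParams, ThresholdSet, ordered_pair, simulate_batch
from coldrisk.injury import BODY_PARTS, THRESHOLD_LABELS, assess_scenario

params = ControllerParams.defaults()
thresholds = ThresholdSet()

# --- energy closure on one random scenario -------------------------------
from coldrisk import sample_scenario

sc = sample_scenario(seed=11)
traj = simulate_batch([sc], params, dt=2.0, record_every=1)[0]
audit = traj.energy_audit()
rel = abs(audit["residual_j"]) / audit["metabolic_energy_j"]
print(f"Energy closure on '{sc.label}': residual "
      f"{audit['residual_j']:.1f} J of {audit['metabolic_energy_j']:.0f} J "
      f"metabolic input ({rel:.2e} relative)")

# --- monotonicity over ordered pairs -------------------------------------
violations = 0
checked = 0
for axis in ("ta", "clo", "met"):
    pairs = [ordered_pair(seed, axis) for seed in range(1, 11)]
    flat = [s for pair in pairs for s in pair]
    trajs = simulate_batch(flat, params, dt=10.0, record_every=6)
    for k in range(0, len(trajs), 2):
        rep_lo = assess_scenario(trajs[k], thresholds)
        rep_hi = assess_scenario(trajs[k + 1], thresholds)
        for part in BODY_PARTS:
            for lab in THRESHOLD_LABELS:
                t_lo = rep_lo.times[(part, lab)]
                t_hi = rep_hi.times[(part, lab)]
                checked += 1
                if t_hi is not None and (t_lo is None or t_hi < t_lo - 0.5):
                    violations += 1
print(f"Monotonicity: {checked} report cells compared across 30 ordered pairs, "
      f"{violations} violations")
print()
print("A milder exposure never crosses an injury threshold earlier; the energy")
print("residual is the bookkeeping error of the integrator, orders of magnitude")
print("below physiological heat flows.")
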