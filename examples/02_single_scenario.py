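"""Simulate one cold-exposure scenario end to end and print its risk report.

The scenario is the harshest bundled one: sitting in an unheated vehicle at
-20 °C with light gloves and all-weather boots.  The report lists, per body
part, the predicted time until skin reaches the numbness (8 °C), pain
(5 °C) and frostbite (1 °C) thresholds within a 250-minute exposure.
"""

from coldrisk import paper_scenarios, run_scenario

scenario = next(s for s in paper_scenarios() if s.label == "vehicle_m20_low")
trajectory, report = run_scenario(scenario, dt=1.0)

print(f"Scenario: {scenario.label}  "
      f"(Ta {scenario.environment.ta:g} °C, wind {scenario.environment.wind:g} km/h, "
      f"{scenario.metabolic_rate:g} W)")
print(f"{'body part':<15}{'numbness':>10}{'pain':>10}{'frostbite':>11}")
for part, *tokens in report.rows():
    print(f"{part:<15}" + "".join(f"{tok:>10}" for tok in tokens))
print(f"Hypothermia within 250 min: {'YES' if report.hypothermia else 'no'} "
      f"(minimum core temperature {report.min_core:.2f} °C)")
print()
print("Skin temperatures after 60 / 120 / 250 minutes (°C):")
for minutes in (60, 120, 250):
    i = int(minutes * 60 / (trajectory.time[1] - trajectory.time[0]))
    print(f"  t={minutes:>3} min  feet {trajectory.series('feet')[i]:6.1f}   "
          f"hands {trajectory.series('hands')[i]:6.1f}   "
          f"face {trajectory.series('exposed_skin')[i]:6.1f}   "
          f"core {trajectory.series('blood')[i]:6.2f}")
print()
print("Feet and hands sink toward their cold-constricted equilibria over hours;")
print("the thin exposed-face node plunges within minutes, which is why exposed")
print("skin dominates early frostbite risk.")
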