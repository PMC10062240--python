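"""Build a custom scenario from scratch: different body, clothing and weather.

Shows the scenario config round trip (write YAML, load it back) and how
insulation and activity shift the predicted injury times.
"""

import tempfile
from pathlib import Path

from coldrisk import (
    BodyInput,
    EnsembleSpec,
    Environment,
    Scenario,
    load_scenario,
    run_scenario,
    save_scenario,
)

ensemble = EnsembleSpec(
    name="patrol_kit",
    #      head  torso  arms  hands  legs  feet
    clo=(1.2, 4.8, 3.5, 1.1, 3.6, 1.0),
    im=(0.40, 0.35, 0.40, 0.35, 0.38, 0.18),
)

scenario = Scenario(
    label="night_patrol",
    environment=Environment(ta=-15.0, rh=0.7, wind=25.0),
    ensemble=ensemble,
    body=BodyInput(height=1.82, mass=90.0, body_fat=0.18),
    metabolic_rate=220.0,   # brisk walk with load
    duration_min=250.0,
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "night_patrol.yaml"
    save_scenario(scenario, path)
    reloaded = load_scenario(path)
    assert reloaded == scenario
    print(f"Config round trip OK: {path.name}")

for met, note in [(220.0, "marching"), (116.0, "halted, sitting")]:
    sc = Scenario(
        label=f"night_patrol_{int(met)}W",
        environment=scenario.environment,
        ensemble=ensemble,
        body=scenario.body,
        metabolic_rate=met,
    )
    _, report = run_scenario(sc, dt=2.0)
    print(f"\n{sc.label} ({note}):")
    for part, *tokens in report.rows():
        print(f"  {part:<15}" + "".join(f"{tok:>10}" for tok in tokens))

print()
print("Dropping from marching (220 W) to sitting (116 W) removes most of the")
print("metabolic heat that was keeping the extremities above the thresholds —")
print("halted troops are the ones who get frostbite.")
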