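"""Convert clothing clo / i_m values into dry and evaporative resistances.

Loads the two bundled ensembles, derives total skin-to-air resistances for
calm (in-vehicle) and windy (outside) conditions, and prints them.
"""

from coldrisk import (
    Environment,
    air_layer_insulation,
    bundled_ensemble,
    total_segment_resistance,
)
from coldrisk.anthropometry import SEGMENTS

calm = Environment(ta=-20.0, rh=0.6, wind=1.0)
windy = Environment(ta=-20.0, rh=0.6, wind=17.0)

print(f"Boundary air layer: {air_layer_insulation(1.0):.3f} clo at 1 km/h, "
      f"{air_layer_insulation(17.0):.3f} clo at 17 km/h")
print()
for name in ("low_protection", "high_protection"):
    ens = bundled_ensemble(name)
    print(name)
    print(f"  {'segment':<8}{'clo':>6}{'im':>6}{'Rct calm':>10}{'Rct windy':>11}{'Ret calm':>10}")
    for seg in SEGMENTS:
        clo, im = ens.segment(seg)
        rc = total_segment_resistance(clo, im, calm)
        rw = total_segment_resistance(clo, im, windy)
        print(f"  {seg:<8}{clo:>6.2f}{im:>6.2f}{rc.rct:>10.4f}{rw.rct:>11.4f}{rc.ret:>10.4f}")
    print()

print("Rct in m^2.K/W (1 clo = 0.155), Ret in m^2.kPa/W; wind erodes only the")
print("boundary air layer, so windy totals are lower by the same offset everywhere.")
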