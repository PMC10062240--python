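label: outside_5_low
environment:
  ta: 5.0
  rh: 0.6
  wind: 17.0
ensemble:
  name: low_protection
  clo:
  - 1.8
  - 6.26
  - 4.37
  - 0.77
  - 4.49
  - 0.74
  im:
  - 0.37
  - 0.32
  - 0.41
  - 0.3
  - 0.39
  - 0.15
body:
  height: 1.75
  mass: 83.5
  body_fat: 0.249
metabolic_rate: 137.0
duration_min: 250.0
exposed_face: true
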