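{
  "core_setpoint": 36.8,
  "skin_setpoint": 33.38866593684008,
  "core_signal_weight": 4.411882365636018,
  "shiver_gain": 47.65151444769385,
  "shiver_cap": 350.0,
  "vaso_gain": {
    "prox": 0.06824,
    "hands": 0.7521725922644613,
    "feet": 1.233335616412806,
    "face": 5.7145633225437376
  },
  "min_flow": {
    "prox": 0.29599574722190825,
    "hands": 0.09981678319245224,
    "feet": 0.02570707296425593,
    "face": 0.007225824030713875
  },
  "skin_blood": {
    "prox": 6.1896606697491965,
    "hands": 40.292571610917776,
    "feet": 3.0,
    "face": 9.402714956319546
  },
  "core_blood_total": 35.0,
  "core_blood_distal": {
    "hands": 3.3778777982831536,
    "feet": 4.894619775113823
  },
  "civd_gain": {
    "hands": 2.3730652628058064,
    "feet": 0.16557486880564543
  },
  "civd_peak": 0.7999324539978856,
  "civd_width": 5.058587074926659,
  "local_gain": {
    "hands": 0.33088131697444767,
    "feet": 0.5722514368444438
  },
  "local_reference": 30.0,
  "face_sheath_capacity": 500.0,
  "still_air_clo": 1.0333411599521198,
  "wind_floor": 0.36131285364955007,
  "wind_decay": 0.13364735730938762,
  "tissue_conductance": 5.0,
  "met_fraction": [
    0.1,
    0.7,
    0.05,
    0.025,
    0.1,
    0.025
  ],
  "shiver_fraction": [
    0.0,
    0.85,
    0.05,
    0.0,
    0.1,
    0.0
  ],
  "enabled": true
}
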