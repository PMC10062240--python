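ensemble,segment,clo,im
low_protection,head,1.80,0.37
low_protection,torso,6.26,0.32
low_protection,arms,4.37,0.41
low_protection,hands,0.77,0.30
low_protection,legs,4.49,0.39
low_protection,feet,0.74,0.15
high_protection,head,1.80,0.37
high_protection,torso,6.26,0.32
high_protection,arms,4.45,0.42
high_protection,hands,2.41,0.94
high_protection,legs,4.49,0.39
high_protection,feet,1.44,0.14
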