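# kvp=102
energy_keV,fluence_per_mm2_per_mAs_at_1m
27.5,243822.613
32.5,269843.491
37.5,260278.6933
42.5,235654.073
47.5,206388.6304
52.5,177251.0231
57.5,149948.6313
62.5,125056.1713
67.5,102631.1109
72.5,82736.82071
77.5,64981.63563
82.5,48977.13062
87.5,34537.62779
92.5,21517.57087
97.5,9716.085545
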