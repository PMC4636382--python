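# kvp=80
energy_keV,fluence_per_mm2_per_mAs_at_1m
27.5,180681.7775
32.5,193935.8483
37.5,180345.4441
42.5,156180.4231
47.5,129422.5553
52.5,103550.8309
57.5,79726.43698
62.5,58261.73636
67.5,39102.749
72.5,22119.50573
77.5,6972.714855
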