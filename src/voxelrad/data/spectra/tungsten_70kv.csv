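# kvp=70
energy_keV,fluence_per_mm2_per_mAs_at_1m
27.5,154653.2616
32.5,161886.5825
37.5,145819.1993
42.5,121099.7157
47.5,94738.00387
52.5,69674.52964
57.5,46832.24242
62.5,26401.08291
67.5,8268.988511
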