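# kvp=120
energy_keV,fluence_per_mm2_per_mAs_at_1m
27.5,299024.7495
32.5,335569.8156
37.5,328836.9003
42.5,303184.7699
47.5,271190.8094
52.5,238745.4033
57.5,208022.4498
62.5,179814.0286
67.5,154264.8326
72.5,131588.5545
77.5,111342.5538
82.5,93033.14196
87.5,76463.74373
92.5,61524.77365
97.5,47985.38994
102.5,35633.15981
107.5,24336.38151
112.5,13989.24805
117.5,4475.533756
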