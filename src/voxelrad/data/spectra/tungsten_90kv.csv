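# kvp=90
energy_keV,fluence_per_mm2_per_mAs_at_1m
27.5,208541.1353
32.5,227608.7715
37.5,215989.2887
42.5,191798.6748
47.5,164086.2555
52.5,136901.6956
57.5,111650.2922
62.5,88763.56452
67.5,68239.59814
72.5,50039.02845
77.5,33800.92419
82.5,19204.98612
87.5,6070.976042
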