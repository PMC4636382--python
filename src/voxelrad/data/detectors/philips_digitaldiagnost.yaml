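# Philips DigitalDiagnost (DR, CsI flat panel).
# Noise coefficients are measured flat-field decomposition values anchored at
# 80 and 120 kV.  Response, grid and scatter entries are documented plausible
# defaults (not manufacturer calibrations): override from your own model file
# for quantitative work.
name: Philips DigitalDiagnost
pixel_pitch_mm: 0.14
bit_depth: 16
response:
  a: 1500.0
  b:
    70: 12600.0
    80: 12800.0
    90: 12950.0
    102: 13100.0
    120: 13300.0
noise:
  80: {alpha: 1.666e-3, beta: 4.494e-5, gamma: 0.0}
  120: {alpha: 1.808e-3, beta: 6.044e-5, gamma: 0.0}
grid:
  f_p: {70: 0.72, 120: 0.66}
  f_s: {70: 0.33, 120: 0.28}
scatter:
  sigma_mm: {70: 4.0, 120: 6.0}
  c_s: {70: 0.45, 120: 0.85}
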