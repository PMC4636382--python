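# Kodak DR 7500 (DR, CsI flat panel).  See note in philips preset: only the
# noise coefficients are measured values; the rest are plausible defaults.
name: Kodak DR 7500
pixel_pitch_mm: 0.14
bit_depth: 12
response:
  a: 250.0
  b:
    70: 1230.0
    80: 1250.0
    90: 1270.0
    102: 1290.0
    120: 1310.0
noise:
  80: {alpha: 5.803e-4, beta: 2.463e-5, gamma: 0.0}
  120: {alpha: 6.455e-4, beta: 2.253e-5, gamma: 0.0}
grid:
  f_p: {70: 0.72, 120: 0.66}
  f_s: {70: 0.33, 120: 0.28}
scatter:
  sigma_mm: {70: 4.0, 120: 6.0}
  c_s: {70: 0.45, 120: 0.85}
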