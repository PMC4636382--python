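# Kodak DirectView CR 900 (computed radiography, BaFBr:Eu storage phosphor).
# See note in philips preset: only the noise coefficients are measured
# values; the rest are plausible defaults.
name: Kodak CR 900
pixel_pitch_mm: 0.17
bit_depth: 12
response:
  a: 280.0
  b:
    70: 850.0
    80: 870.0
    90: 890.0
    102: 910.0
    120: 930.0
noise:
  80: {alpha: 1.732e-3, beta: 1.573e-4, gamma: 0.0}
  120: {alpha: 2.328e-3, beta: 1.376e-4, gamma: 0.0}
grid:
  f_p: {70: 0.72, 120: 0.66}
  f_s: {70: 0.33, 120: 0.28}
scatter:
  sigma_mm: {70: 4.0, 120: 6.0}
  c_s: {70: 0.45, 120: 0.85}
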