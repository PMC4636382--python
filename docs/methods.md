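# Methods

This note records the models implemented in `voxelrad`, their assumptions,
the defaults and why they were chosen, and what the synthetic phantoms and
tests do and do not demonstrate.

## Beam model and spectra

The source is an ideal point emitting a polychromatic beam described by
binned photon fluence (bin centres at (k+½)·5 keV, photons·mm⁻²·mAs⁻¹
normalised to 1 m). Fluence is stored *per mAs*: exposure scaling is a pure
multiplication, which makes mAs-linearity of the dose chain exact by
construction. Bundled spectra (70/80/90/102/120 kV) come from a deliberately
simple analytic tungsten model — Kramers continuum `(kVp − E)/E` filtered by
2.5 mm Al — normalised so the free-in-air kerma per mAs at 1 m equals a
nominal tube output of 9·10⁻³·kVp² µGy/mAs (≈58 µGy at 80 kV, a typical
general-purpose tube with inherent filtration). They omit characteristic
tungsten lines and anode-angle effects; every downstream computation is
agnostic to the spectrum's provenance, so measured or catalogue spectra can
be dropped in as CSV.

## Materials

Voxel attenuation is the affine CT-number model
μ = (HU/1000 + 1)·μ_water(60 keV)·f(E), clamped at zero below −1000 HU.
60 keV is the effective energy of a typical 120 kVp CT acquisition, the
natural calibration point for HU-derived attenuation. `f(E)` defaults to
water's energy dependence for every voxel ("uniform" mode); "threshold"
mode switches voxels above +300 HU to cortical bone's curve, which is what
gives bone/soft-tissue contrast its correct energy dependence. The embedded
tables (mass attenuation of water, cortical bone, aluminium; mass
energy-absorption of air) are transcriptions of standard reference
tabulations on a 20–150 keV grid, interpolated log-log (attenuation
coefficients are near-power-law in this range; log-log interpolation is
monotone between grid points and exact at them). No extrapolation: energies
outside the grid raise.

## Projection

One ray per pixel centre (detector pixels are idealised points; no aperture
integration, no finite focal spot, no heel effect). The ray is sampled at
`n_steps` midpoints with nearest-voxel lookup; the default step is half the
voxel size, the standard accuracy/cost compromise for this scheme. Because
per-voxel attenuation factorises into (HU-term)·μ_w60·f_class(E), the code
accumulates one path integral per material class and applies the spectral
factor afterwards, so cost is independent of the number of energy bins.

Numerical behaviour worth knowing: with nearest-voxel midpoint sampling the
path-length error at a material boundary is first-order in the step length
and oscillates with the sampling phase. Consequently (a) single-ray error
versus `n_steps` is not monotone — only the worst case over sampling phases
is — and (b) at the default half-voxel step, doubling `n_steps` can shift
any pixel by up to ~μ·Δx (≲1 % for soft tissue at 0.3 mm steps). The test
suite asserts exactly these envelope properties. Steps outside the phantom
bounding box contribute μ = 0: air attenuation over ≲2 m is negligible and
in-air detector calibration absorbs it.

Geometry: x lateral, y vertical (source above, detector below), z
cranio-caudal. The projection angle rotates the source–detector assembly in
the transverse plane (about z), the cranio-caudal angle tilts it about x;
rotations are rigid, right-handed, in degrees, about the phantom centre.
The default placement puts the phantom centre midway between source and
detector (magnification 2).

## Dosimetry

Per-bin air kerma is (μen/ρ)_air(E)·Ψ·(100/d)²·f_c with Ψ = Φatt·E the
attenuated energy fluence and d the per-pixel source distance in cm
(inverse-square is applied here, not during projection, because the fluence
is normalised at 1 m). The unit chain keV·mm⁻² × cm²·g⁻¹ → µGy collapses to
the single constant f_c = 1.602·10⁻⁵ (from 1.602·10⁻¹⁹ J/eV). Per-pixel
distances give the natural inverse-square fall-off towards the field
corners. Kerma is additive over any spectral partition and exactly linear
in mAs.

## Detector response and noise

Response is PV = b(kV) + a·ln(K_air): one global gain `a` per detector and
a per-beam-quality offset `b` interpolated linearly in kV between anchors.
Doses below 10⁻⁴ µGy are floored before the logarithm (far below any
clinically simulated kerma). The preset response values are *plausible
defaults*, chosen to land mid-dose pixel values in each detector's known
operating range; they are not manufacturer calibrations and are documented
as overridable in the preset YAML headers.

Noise follows σ²(D) = αD + βD² + γ with D in µGy: Poissonian,
multiplicative (fixed-pattern/gain) and additive (electronic) components.
The preset α/β at 80 and 120 kV are measured characterisation values;
γ defaults to 0 because the additive term is typically below 1 % of total
noise at diagnostic doses (it remains a settable field). Between/beyond the
anchors α, β, γ interpolate/extrapolate linearly in kV.

The noise sample is added in the **dose domain** — `K_noisy = K + x·σ(K)`,
then response conversion — rather than to the pixel values. This is the
package's own design choice, made because it is the arrangement under which
a logarithmically responding detector shows the physically expected
behaviour: pixel-value noise ≈ a·σ/D falls with exposure, so SNR rises with
mAs and bone/soft-tissue CNR falls with kVp. (Adding the same σ(D) law in
the PV domain instead makes SNR *decrease* with exposure whenever the mean
PV exceeds 2a, which contradicts flat-panel practice.) The variance law is
therefore characterised, and closed-loop-tested, on dose images — exactly
how grid and noise analyses are done on real systems, by converting PV
images back through the inverse response.

## Random numbers

Per-pixel independent streams: three Tausworthe shift-register components
(shift triplets (13,19,12), (2,25,4), (3,11,17) with the standard masks)
XOR-combined with an LCG (1664525·z + 1013904223 mod 2³²). The combined
word maps to (0,1) as (w + 0.5)·2⁻³², strictly inside the interval so
ln(u) is always finite. Box–Muller converts uniform pairs to standard
normals; the radius identity x₁² + x₂² = −2 ln u₁ holds to machine
precision. Tausworthe states below their minimum-seed constraints are
corrected deterministically at initialisation (+128).

Seeding: each pixel's four 32-bit states derive from a unique linear index
(row·2²¹ + col, valid for images narrower than 2²¹ columns) scrambled by
the Park–Miller multiplier plus golden-ratio offsets for image id and
global seed, then passed through a 64-bit avalanche finalizer. The
avalanche stage matters: adjacent indices must not produce correlated first
draws, and the flat-field autocorrelation tests check this directly. The
generator also exposes the classic failure mode on purpose: seeding by row
index alone (`index_mode="row"`) collapses every row to one stream and
produces the banded "strips of noise" artefact; the stripe-statistic test
asserts both that the proper seeding stays clean and that the degenerate
seeding is flagged. Statistical quality and determinism are the
requirements here, not bit-compatibility with any particular GPU
implementation.

## Scatter and grid

Scatter is modelled empirically as S = c_s(E)·G_σ(P): a sum-normalised
Gaussian blur of the primary dose image with σ(E) defined in mm on the
detector plane (independent of magnification — the calibration geometry
has the phantom on the detector), scaled by a scatter-to-primary
coefficient. Convolution uses mirror padding so borders carry no dark-edge
artefact that would corrupt edge-profile fitting. The grid multiplies
primary and scatter separately: f_P·P + f_S·S. Preset c_s rises with kVp
(0.45→0.85), f_P ≈ 0.72→0.66 and f_S ≈ 0.33→0.28 — plausible values
consistent with published scatter-to-primary fractions (0.7–0.9 uncorrected
chest, below ~0.3 behind a grid); they are flagged non-authoritative and
user-overridable. Limitations: the kernel is object-independent (no
thickness-dependent scatter), single-Gaussian, and not Monte Carlo.

Two calibration estimators mirror the experimental procedures: σ from an
erf-model fit to the averaged penumbra of a straight-edge dose profile
(error raised when plateau contrast < 5 %), and f_S from paired
with/without-grid exposures by subtracting the predicted free-air primary
in an ROI outside the phantom shadow and taking the ratio of the residual
scatter. Both close the loop on simulated data within a few percent.

## Phantoms

Builders are deterministic pure functions: homogeneous slabs (PMMA is
represented by the documented convention HU ≈ 120; PMMA is not a
CT-calibrated tissue and the tests rely on the HU→μ formula, not PMMA
realism), a half-field edge block, and a torso surrogate — an elliptic
soft-tissue cylinder (HU 40, 300×200 mm section, 200 mm long) with two
mirrored lung ellipsoids (HU −750) and a posterior vertebral column
cylinder (HU 700, radius 20 mm). The surrogate's default voxel is 2 mm
(clinical CT phantoms are ~0.6 mm; the coarser default keeps projection
affordable without changing any physics). It is x-mirror symmetric by
construction, which the projection symmetry tests exploit. NRRD round-trips
preserve the HU array, voxel size and origin bit-exactly.

What the surrogate does *not* emulate: realistic anatomy, heterogeneous
tissue HU distributions, patient-to-patient variation. Tests passing on it
show the physics chain is self-consistent, not that absolute pixel values
match any particular clinical system.

## Study conditions used by the characterisation tests

* **Variance closed loop**: ten dose levels log-spaced over 0.1–20 µGy
  (two decades, the flat-field characterisation range), variance measured
  in a central 2 cm × 2 cm ROI (≈143² pixels at 0.14 mm pitch), refit by
  non-negative least squares on the design (D, D², 1). NNLS enforces the
  physical signs without iterative tuning; recovery is typically within a
  few percent per coefficient, and replicated runs bound the Monte-Carlo
  standard error of the recovered coefficients.
* **Trend directions**: bone/soft-tissue CNR versus kVp is evaluated at a
  fixed 16 mAs — a representative spine/abdomen exposure at which the bone
  ROI is not photon-starved (at fractions of a mAs the Poisson term behind
  the spine dominates both ROIs' noise and masks the contrast trend).
  SNR versus mAs is evaluated at 90 kV over 0.5–8 mAs. Both are checked as
  directions, not magnitudes.
* **Projection oracles** use 0.62 mm voxels (the CT-derived phantom
  convention) and the analytic slab solution; end-to-end images in tests
  use coarser grids (≈100² pixels, 2–16 mm pitch) to keep the suite fast;
  the physics is resolution-independent.

## Degenerate inputs and tie-breaks

Unsorted spectrum files are rejected, never reordered. Rays that miss the
phantom transmit exactly 1. A source inside the phantom bounding box is an
error. σ → 0 scatter degenerates to c_s·P exactly. Constant ROIs report
infinite SNR explicitly. Quantisation clips to [0, 2^bit_depth − 1].
The CNR denominator is the quadrature-mean (pooled) SD of the two ROIs —
symmetric and standard where no single convention dominates.

## Known limitations

Point source (no focal-spot blur); no detector MTF or frequency-dependent
noise (noise is white by construction); empirical object-independent
scatter; no grid cutoff/moiré; no DICOM; response/grid/scatter preset
values are plausible rather than measured. The per-ray step loop is pure
NumPy — adequate at the image sizes used here, far from GPU speeds at full
clinical matrices.
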