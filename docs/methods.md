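# Methods

This note documents the models behind `smartscan`, the parameter choices
that matter, what the synthetic phantoms do and do not emulate, and the
numerical conventions that were genuinely open and had to be pinned.

## Forward model

A scene is a linear-mixing hyperspectral image: per pixel, the spectrum is
`Σ_k a_k(x,y) E_k(λ)` with abundances on the simplex (`a_k ≥ 0`,
`Σ_k a_k = 1`) and `E_k` non-negative endmember spectra on a shared
wavenumber axis. The default axis spans 400–1800 cm⁻¹ (the Raman
fingerprint region) with 940 bands at full scale and 128 in the test-scale
phantoms.

Default endmembers are bone-like: a mineral (apatite) phase dominated by the
ν₁PO₄ stretch at 960 cm⁻¹ and an organic (matrix) phase dominated by the
CH₂ deformation at 1450 cm⁻¹, each with secondary bands, Gaussian line
shapes (Lorentzian optional — band shapes are not critical to any pipeline
stage, only peak positions are), and a constant autofluorescence pedestal of
0.3× the main peak. The pedestal matters: raw 785 nm bone spectra sit on a
substantial background, and its presence controls how much chemical contrast
survives in a single-band ratio at low SNR. Without it, a 100 ms raster
retains enough class signal that the healthy/diabetic separation never
collapses the way it does on real noisy data.

### Spatial structure

`osteon_rings` (default) seeds ~1 osteon center per 1200 px² and draws
discrete alternating lamellae: the mineral fraction is
`0.45 ± 0.12 · sign(cos(πd/4))` (d = distance to the nearest center, ring
width 4 px, edges smoothed at σ=0.7 px to avoid aliasing) plus a smooth
random modulation of sd 0.05. Step-like banding, not a smooth gradient, is
deliberate: lamellar mineralization in cortical bone alternates discretely,
and the misregistration analysis depends on it — segmentation can only be
hurt by a shift if it had edges to adhere to in the first place. With a
smooth sinusoidal phantom, SLIC degenerates to a near-regular tiling whose
translation is statistically invisible and the shift sweep comes out flat.

Diabetic-class scenes get the mineral field shifted by +0.15 before
clipping, emulating the hyper-mineralization of type-2 diabetic bone; the
shift is the single knob behind every class-separation result. `blocks` and
`random_smooth` structures exist for controlled experiments; block-wise
scenes built *from* a segmentation (`make_blockwise_scene`) provide exact
superpixel-constant ground truth for round-trip tests.

### Fast-modality (SEM) image

The SEM image is an affine map of the mineral abundance plus a **spatially
smooth** random discrepancy (Gaussian field, correlation length 2 px,
sd 0.28 on the [0,1]-normalized contrast). Two modelling points:

* Electron micrographs at this magnification are effectively noise-free per
  pixel; what limits their agreement with Raman is that backscatter contrast
  is not chemistry. That discrepancy is structured, not white. White pixel
  noise of the same magnitude erases the intensity edges SLIC needs and
  decouples segmentation quality from registration.
* The sd was calibrated once so that the normalized cross-covariance between
  the SEM image and the noiseless ratio image of the default 100×100×940
  phantom sits near 0.6, the operating point measured for real backscatter
  SEM against Raman mineralization ratios. The resulting correlation against
  a high-SNR *acquired* ratio image lands at ~0.58–0.61.

## Acquisition noise and SNR

The virtual spectrometer draws
`counts ~ Poisson(photon_scale · I · dwell_ms)`, normalized back to
intensity units, plus Gaussian read noise (`read_noise_sd` counts) and a
dwell-independent multiplicative gain fluctuation (`gain_noise_rel_sd`,
laser-power/detector-gain jitter). The multiplicative term is load-bearing:
shot noise alone forces the SNR gap between 100 ms and 5000 ms dwells to
10·log₁₀(50) ≈ 17 dB, whereas measured Raman systems show ~14.6 dB
(8.7 → 23.3 dB); only a dwell-independent noise floor can close that gap.

SNR is *estimated*, never assumed: per spectrum,
`10·log₁₀(Σ I_S² / Σ e²)` with `I_S` the Savitzky–Golay smooth and `e` the
residual, averaged over spectra. Defaults are window 11, polyorder 3 for
940-band spectra; the window scales with band count
(`sg_window_for_bands`) so the filter keeps a constant width in cm⁻¹ —
at 128 bands an 11-band window spans ~120 cm⁻¹, cannot follow real Raman
bands, and its lack-of-fit floor alone would cap the estimate at ~8.5 dB.

`calibrate_noise_model` solves for the noise parameters that make the
*estimated* SNR hit the (8.7, 23.3) dB pair on a given phantom, by nested
1-D root finding with common random numbers. Two regimes arise:

* full scale (940 bands): the smoothing floor is negligible, the shot-noise
  gap is too wide, and the calibration fits `photon_scale` plus the
  multiplicative gain term;
* test scale (128 bands): the smoothing floor compresses the measured gap
  below 14.6 dB, so the calibration fits `photon_scale` plus additive read
  noise (which penalizes the short dwell more).

Both branches are automatic; no parameter is chosen per test.

## Pipeline conventions

* **SLIC** runs on the min–max normalized image with compactness 0.1 and
  sigma 0; connectivity is enforced and labels relabelled to 1..P. The
  achieved P is always read from the map, never assumed equal to the
  request. Default P targets ~3×3 px superpixels (⌈XY/9⌉).
* **Representatives** are the member pixels nearest their superpixel's
  center of mass (Euclidean); for non-convex superpixels whose centroid
  falls outside, this nearest-member rule is a documented choice. Exact
  distance ties break to the smaller row-major index for reproducibility.
* **Phasor convention**: `c_r = Σ_λ s(λ)·exp(−i2π(r−1)(λ−1)/L)` — the
  forward (analysis) DFT without a 1/L factor, i.e. numpy FFT bin `r−1`;
  `r=1` is the DC term and `r=2` the default working harmonic. The published
  transform is written in the synthesis direction and leaves the sign/scale
  convention open; only the relative geometry of the cloud matters for hull
  selection, so any fixed convention selects the same pixels. L1
  normalization is applied to the coefficient (dividing by `Σ|s|`);
  normalizing the spectra before the DFT differs by the same positive
  factor and yields the identical hull.
* **Hull degeneracies**: coincident clouds give H=1, collinear clouds their
  two extremes, duplicate coordinates are deduplicated (first kept). No
  denoising precedes the hull: noise can add vertices but never removes
  interior coverage, which the least-squares reconstruction tolerates.
* **Unmixing** is plain unconstrained least squares via the normal
  equations, exactly as the estimator is defined; concentrations may go
  negative under noise and negative reconstructed intensities pass through
  unclipped (the ratio metric masks near-zero denominators instead). A
  non-negative mode (`nonnegative=True`, scipy NNLS) exists behind a flag.
  A reciprocal condition number of the Gram matrix below 1e-10 (near-
  duplicate hull vertices) falls back to the minimum-norm pseudo-inverse
  with a warning instead of crashing.
* **Ratio image**: single-band intensities at the bands nearest 960 and
  1450 cm⁻¹ (not integrated areas). Denominators below 1e-12× the cube
  maximum are masked; masked pixels are excluded from histograms and
  cross-covariances.
* **Histograms / D_B**: bin width defaults to Freedman–Diaconis on the
  pooled values; the Bhattacharyya distance is computed on probability
  masses over the union grid (common δ required), with +inf for disjoint
  supports. Gaussian-smoothed densities exist for display only and never
  feed D_B. When pooling ratio pixels for class comparisons, values are
  restricted to the physiologically plausible window (0, 10] so that
  low-SNR ratio blow-ups (near-zero denominators) cannot dictate the grid.

## Timing model

Per-point times: dwell + 30 ms stage transfer. The transfer constant is
inferred from the full low-SNR raster budget (1300 s for 10⁴ points at
100 ms dwell ⇒ 30 ms/point overhead) and is configurable. The reference
raster is quoted without transfer overhead (50 000 s = 10⁴ × 5 s exactly),
matching how such scans are reported; a switch adds it. The SEM pass is a
fixed 120 s. Processing time is an *input*, reported separately — the model
never measures wall-clock time, keeping tests hardware-independent.
Protocol totals:

| protocol | total |
|---|---|
| reference | `n·dwell_high` |
| low_snr | `n·(dwell_low + transfer)` |
| two_pass | `n·(dwell_low + transfer) + H·(dwell_high + transfer) + processing` |
| three_pass | `sem + P·(dwell_low + transfer) + H·(dwell_high + transfer) + processing` |

At the full operating point (n=10⁴, P≈1112, H≈12) the Three-Pass total is
~345 s against 50 000 s for the reference — two orders of magnitude — and
~4× faster than the Two-Pass scan. On tiny test grids (32×32) the fixed
120 s SEM pass can exceed the shrunken low-SNR raster, so Two-Pass is
legitimately faster *there*; timing dominance is a full-scale statement.

## What the phantoms do and do not show

The generator reproduces the *mechanisms* the protocol exploits — linear
mixing, dwell-limited SNR, spatial redundancy at the superpixel scale,
correlated-but-imperfect fast modality, class-dependent mineralization —
with effect sizes chosen once for realism. It does not model
autofluorescence drift between passes, photobleaching, cosmic rays,
wavenumber calibration drift, instrument line-shape functions, or the
biological variability of real patients (scenes within a class differ only
by geometry, not by systematic chemistry offsets). Passing tests therefore
demonstrate correctness of the pipeline and qualitative reproduction of the
protocol trade-offs, not clinical performance. The real-data headline
values (SNR pair, cross-covariance level, the relative ordering and rough
magnitude of the Bhattacharyya distances) are matched in kind; exact
real-data numbers depend on a clinical dataset that is not publicly
available.

Two scale-dependent caveats, both consequences of deliberate design:

* With lamella-scale structure (period 8 px) and 3×3 superpixels, the mean
  within-superpixel spectral variance on a noiseless phantom is ~4–6×
  smaller than the global variance, not arbitrarily small. That is the
  operating point of the method — superpixels *slightly smaller* than the
  structure of interest — and the homogeneity test asserts the qualitative
  reduction (>3×) rather than a stricter bound that only a blurred phantom
  could meet.
* The misregistration effect is small relative to acquisition-seed noise on
  any single scene; sweeps that test it average over phantom scenes, as a
  real study averages over samples.

## Problem sizes

Default generation is 100×100×940 (the processed size of real maps); the
test suite and the reproduction script run 32×32×128 phantoms with 10-seed
averages, 8 scene pairs for class separation, and a single full-size
phantom for the SEM-correlation and calibration checks. These sizes were
chosen so the entire suite runs in seconds while keeping every Monte-Carlo
comparison comfortably outside its own seed noise.
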