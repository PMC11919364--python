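# smartscan

Simulation and analysis toolkit for **dual-modality smart scanning** in
hyperspectral Raman micro-imaging, built around the bone-imaging use case
(SEM-guided Raman mapping of cortical bone).

## The problem

Raman micro-imaging acquires one spectrum per pixel by raster scanning. At
the dwell time needed for quantitative bone work (~5 s/point), a 100×100
map takes ~14 h. Smart scanning cuts this by measuring only where
information lives:

1. **First pass — fast modality.** A co-registered SEM image (seconds to
   acquire) is segmented into `P` superpixels with SLIC (compactness 0.1,
   sigma 0, ~3×3 px each); the member pixel nearest each superpixel's
   centroid becomes its *representative*.
2. **Second pass — low SNR Raman.** Spectra are acquired only at the `P`
   representatives, at short dwell (100 ms). Each spectrum is mapped to one
   harmonic of its DFT, L1-normalized: the phasor point
   `(G_r, Q_r) = (Re c_r, Im c_r) / ||s||_1`, with `r = 2` by default.
   Because linear mixtures map to convex combinations in the phasor plane,
   the vertices of the 2-D convex hull of the point cloud are the *essential
   spectra* — every other spectrum is (approximately) a mixture of them.
3. **Third pass — high SNR rescan.** Only the `H ≪ P` essential pixels are
   re-acquired at long dwell (5000 ms). Concentrations
   `c_p = (S S^T)^{-1} S I_p` (ordinary least squares of each representative
   spectrum on the essential spectra `S`) combine with the high-SNR rescan
   `S_high` to rebuild the full cube: every pixel of superpixel `p` receives
   `S_high^T c_p`.

The toolkit implements this Three-Pass protocol alongside three baselines
(full high-SNR *reference* raster, full low-SNR raster, and the single-
modality *Two-Pass* smart scan whose first pass is the low-SNR raster
itself), plus the evaluation suite: reconstruction RMSE, the bone
mineralization ratio image `R(x,y) = I(x,y,960 cm⁻¹)/I(x,y,1450 cm⁻¹)`
(ν₁PO₄ over CH₂), normalized cross-covariance between modalities, histogram
densities and the Bhattacharyya distance `D_B = −log Σ √(f̂_h f̂_d)` between
healthy and diabetic ratio distributions, and an acquisition-time model with
per-pass decomposition.

Because real clinical cubes are not redistributable, the package ships a
first-class synthetic phantom generator: bone-like endmembers (960/1450 cm⁻¹
bands on an autofluorescence pedestal), osteon-like lamellar abundance maps
on the linear-mixing simplex, dwell-dependent Poisson–Gaussian acquisition
noise calibrated to the study's SNR pair (8.7 dB at 100 ms, 23.3 dB at
5000 ms), and a co-registered SEM-like image whose correlation with the
ratio image matches the measured operating point (C ≈ 0.6). Real data can be
supplied as HDF5 cube containers or ENVI header+binary exports plus a
registered TIFF/PNG image.

## Worked example

```python
import numpy as np
from smartscan import phantom, acquisition, protocols

scene = phantom.make_scene(32, 32, L=128, seed=1)          # osteon phantom
cube  = phantom.render_cube(scene)                          # noiseless truth
noise = acquisition.calibrate_noise_model(cube, seed=7)     # hit 8.7/23.3 dB
sem   = phantom.make_sem(scene, seed=2)                     # fast modality

res = protocols.run_three_pass(scene, sem, noise, seed=0)
print(f"P={res.n_superpixels} H={res.n_essential} "
      f"rmse={res.metrics['rmse']:.4f} total={res.timings.total_s:.1f}s")

ref = protocols.run_reference(scene, noise, seed=0)
low = protocols.run_low_snr(scene, noise, seed=0)
print(f"reference rmse={ref.metrics['rmse']:.4f} total={ref.timings.total_s:.0f}s")
print(f"low-SNR   rmse={low.metrics['rmse']:.4f} total={low.timings.total_s:.0f}s")
```

prints

```
P=110 H=9 rmse=0.0357 total=179.6s
reference rmse=0.0360 total=5120s
low-SNR   rmse=0.2123 total=133s
```

Reading: the guided scan measures 110 + 9 points instead of 1024 and lands
within a hair of the reference raster's error (0.0357 vs 0.0360 on this
seed — the reference itself carries high-dwell noise; averaged over seeds the
reference stays slightly ahead) at 3.5% of its acquisition time, while the
equally fast low-SNR raster is ~6× worse. At the real operating
point (100×100 px, P≈1100) the timing model gives 50 000 s for the
reference raster and ~345 s for the Three-Pass protocol.

A CLI covers the same workflow from the shell:

```bash
smartscan simulate --x 100 --y 100 --seed 0 --out phantom.h5
smartscan run --protocol three_pass --scene phantom.h5 --out recon.h5
smartscan sweep shift --scene phantom.h5 --values 0,1,3 --out shifts.csv
smartscan metrics --cube recon.h5 --reference truth.h5
```

## Layout

| module | contents |
|---|---|
| `smartscan.phantom` | endmembers, scenes, linear mixing, SEM image, shifts |
| `smartscan.acquisition` | noise model, SNR estimator, calibration, timing model |
| `smartscan.superpixels` | SLIC segmentation, representative selection |
| `smartscan.essential` | phasor transform, convex-hull essential selection |
| `smartscan.unmix` | least-squares concentrations, reconstruction |
| `smartscan.metrics` | RMSE, ratio image, cross-covariance, histogram, D_B |
| `smartscan.protocols` | the four protocols, P and misalignment sweeps |
| `smartscan.io_formats` | HDF5 cube container, ENVI import, images, tables |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
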