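"""End-to-end acquisition protocols and parameter sweeps.

Four protocols are compared on a common scene:

* ``reference`` — full raster at high dwell: slow, accurate.
* ``low_snr``   — full raster at low dwell: fast, noisy.
* ``two_pass``  — full low-SNR raster; superpixels computed on its spectral
  average; essential pixels (phasor convex hull of the representatives'
  spectra) re-scanned at high dwell; least-squares reconstruction.
* ``three_pass`` — the dual-modality protocol: superpixels come from a fast
  co-registered (SEM) image, so the low-SNR Raman pass shrinks from the full
  grid to the P representatives only, followed by the same essential
  selection, high-SNR rescan and reconstruction.

Two sweeps mirror the method's operating-point studies: the number of
superpixels P (time/accuracy trade-off) and an integer misregistration shift
between the fast modality and the Raman frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import acquisition, essential, metrics, phantom, superpixels, unmix
from .acquisition import NoiseModel, ScanTimings, TimingParams
from .essential import SpectralMatrix
from .phantom import Scene, SEMImage

__all__ = [
    "ProtocolResult",
    "run_reference",
    "run_low_snr",
    "run_two_pass",
    "run_three_pass",
    "run_protocol",
    "sweep_P",
    "sweep_misalignment",
    "class_separation",
    "PROTOCOL_NAMES",
]

PROTOCOL_NAMES = ("reference", "low_snr", "two_pass", "three_pass")


@dataclass
class ProtocolResult:
    """One protocol run: output cube, timing decomposition, achieved sizes,
    metric bundle, and the seed record needed to reproduce it bit-exactly."""

    protocol: str
    cube: np.ndarray
    timings: ScanTimings
    n_superpixels: int
    n_essential: int
    seed: int
    metrics: dict = field(default_factory=dict)
    ratio: metrics.RatioImage = None
    superpixel_map: superpixels.SuperpixelMap = None


def _fan_seeds(seed, n=4):
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def _finish(protocol, scene, cube_out, timings, P, H, seed, spmap=None):
    truth = phantom.render_cube(scene)
    ratio = metrics.ratio_image(cube_out, scene.wavenumber_axis)
    bundle = {"rmse": metrics.rmse(cube_out, truth)}
    return ProtocolResult(
        protocol=protocol,
        cube=cube_out,
        timings=timings,
        n_superpixels=P,
        n_essential=H,
        seed=seed,
        metrics=bundle,
        ratio=ratio,
        superpixel_map=spmap,
    )


def run_reference(
    scene: Scene,
    noise: NoiseModel,
    seed: int = 0,
    timing_params: TimingParams | None = None,
) -> ProtocolResult:
    """Full high-SNR raster scan (the accuracy baseline)."""
    tp = timing_params or TimingParams()
    truth = phantom.render_cube(scene)
    X, Y, L = truth.shape
    (s_acq,) = _fan_seeds(seed, 1)
    spectra = acquisition.acquire(truth, "all", tp.dwell_high_ms, noise, s_acq)
    cube = spectra.reshape(X, Y, L)
    t = acquisition.timing("reference", X * Y, params=tp)
    return _finish("reference", scene, cube, t, 0, 0, seed)


def run_low_snr(
    scene: Scene,
    noise: NoiseModel,
    seed: int = 0,
    timing_params: TimingParams | None = None,
) -> ProtocolResult:
    """Full low-SNR raster scan (the fast, noisy baseline)."""
    tp = timing_params or TimingParams()
    truth = phantom.render_cube(scene)
    X, Y, L = truth.shape
    (s_acq,) = _fan_seeds(seed, 1)
    spectra = acquisition.acquire(truth, "all", tp.dwell_low_ms, noise, s_acq)
    cube = spectra.reshape(X, Y, L)
    t = acquisition.timing("low_snr", X * Y, params=tp)
    return _finish("low_snr", scene, cube, t, 0, 0, seed)


def _smart_core(scene, noise, tp, I_low, spmap, seed_rescan, harmonic_r):
    """Shared tail of the smart protocols: essential selection on the
    representatives' low-SNR spectra, high-SNR rescan, unmix, reconstruct."""
    truth = phantom.render_cube(scene)
    cloud = essential.phasor_transform(I_low, harmonic_r=harmonic_r)
    ess = essential.essential_select(cloud, I_low)
    S_high = essential.rescan_essential(ess, truth, tp.dwell_high_ms, noise, seed_rescan)
    cmap = unmix.concentrations(ess.spectra, I_low.spectra)
    recon = unmix.reconstruct(S_high, cmap, spmap)
    return recon.cube, ess.n_essential


def run_two_pass(
    scene: Scene,
    noise: NoiseModel,
    n_superpixels: int | None = None,
    seed: int = 0,
    timing_params: TimingParams | None = None,
    processing_s: float = 0.0,
    harmonic_r: int = essential.DEFAULT_HARMONIC,
    superpixel_map: superpixels.SuperpixelMap | None = None,
) -> ProtocolResult:
    """Single-modality smart scan: the low-SNR raster itself guides the scan.

    Superpixels are computed on the spectrally averaged low-SNR image; the
    representatives' spectra come for free from the raster already acquired.
    """
    tp = timing_params or TimingParams()
    truth = phantom.render_cube(scene)
    X, Y, L = truth.shape
    s_low, s_rescan, s_seg = _fan_seeds(seed, 3)
    low_raster = acquisition.acquire(truth, "all", tp.dwell_low_ms, noise, s_low)
    low_cube = low_raster.reshape(X, Y, L)
    if superpixel_map is None:
        mean_img = low_cube.mean(axis=2)
        superpixel_map = superpixels.segment(mean_img, n_superpixels)
    reps = superpixel_map.representatives
    I_low = SpectralMatrix(low_cube[reps[:, 0], reps[:, 1]], reps, snr_tag="low")
    cube, H = _smart_core(scene, noise, tp, I_low, superpixel_map, s_rescan, harmonic_r)
    P = superpixel_map.n_superpixels
    t = acquisition.timing("two_pass", X * Y, P, H, params=tp, processing_s=processing_s)
    return _finish("two_pass", scene, cube, t, P, H, seed, superpixel_map)


def run_three_pass(
    scene: Scene,
    sem_image: SEMImage,
    noise: NoiseModel,
    n_superpixels: int | None = None,
    seed: int = 0,
    timing_params: TimingParams | None = None,
    processing_s: float = 0.0,
    misalignment_shift=(0, 0),
    harmonic_r: int = essential.DEFAULT_HARMONIC,
    superpixel_map: superpixels.SuperpixelMap | None = None,
) -> ProtocolResult:
    """Dual-modality smart scan guided by the fast (SEM) image.

    ``misalignment_shift`` translates the SEM image (replicate padding)
    before segmentation, emulating a registration error of that many pixels
    between the two modalities.
    """
    tp = timing_params or TimingParams()
    truth = phantom.render_cube(scene)
    X, Y, L = truth.shape
    s_lowacq, s_rescan, s_seg = _fan_seeds(seed, 3)
    if superpixel_map is None:
        img = phantom.apply_shift(sem_image.pixels, misalignment_shift)
        superpixel_map = superpixels.segment(img, n_superpixels)
    reps = superpixel_map.representatives
    spectra = acquisition.acquire(truth, reps, tp.dwell_low_ms, noise, s_lowacq)
    I_low = SpectralMatrix(spectra, reps, snr_tag="low")
    cube, H = _smart_core(scene, noise, tp, I_low, superpixel_map, s_rescan, harmonic_r)
    P = superpixel_map.n_superpixels
    t = acquisition.timing(
        "three_pass", X * Y, P, H, params=tp, processing_s=processing_s
    )
    return _finish("three_pass", scene, cube, t, P, H, seed, superpixel_map)


def run_protocol(name, scene, sem_image, noise, seed=0, **kwargs):
    """Dispatch a protocol by name with shared arguments."""
    if name == "reference":
        return run_reference(scene, noise, seed, kwargs.get("timing_params"))
    if name == "low_snr":
        return run_low_snr(scene, noise, seed, kwargs.get("timing_params"))
    if name == "two_pass":
        kwargs.pop("misalignment_shift", None)
        return run_two_pass(scene, noise, seed=seed, **kwargs)
    if name == "three_pass":
        return run_three_pass(scene, sem_image, noise, seed=seed, **kwargs)
    raise ValueError(f"unknown protocol {name!r}")


def sweep_P(
    scene: Scene,
    sem_image: SEMImage,
    noise: NoiseModel,
    P_values,
    seeds,
    timing_params: TimingParams | None = None,
) -> pd.DataFrame:
    """Three-pass RMSE and total time as a function of the superpixel count.

    Returns one row per requested P: the achieved count (mean over seeds),
    mean RMSE with a 95% normal-approximation interval, and mean total time.
    """
    P_values = list(P_values)
    if any(b <= a for a, b in zip(P_values, P_values[1:])):
        raise ValueError("P_values must be ascending")
    rows = []
    for P in P_values:
        r_vals, t_vals, p_ach = [], [], []
        for s in seeds:
            res = run_three_pass(
                scene, sem_image, noise, n_superpixels=P, seed=s,
                timing_params=timing_params,
            )
            r_vals.append(res.metrics["rmse"])
            t_vals.append(res.timings.total_s)
            p_ach.append(res.n_superpixels)
        rows.append(
            {
                "P_requested": P,
                "P_achieved": float(np.mean(p_ach)),
                "mean_rmse": float(np.mean(r_vals)),
                "rmse_ci95": _ci95(r_vals),
                "mean_total_s": float(np.mean(t_vals)),
            }
        )
    return pd.DataFrame(rows)


def _ci95(vals):
    vals = np.asarray(vals, dtype=float)
    if vals.size < 2:
        return 0.0
    return float(1.96 * vals.std(ddof=1) / np.sqrt(vals.size))


def sweep_misalignment(
    scene: Scene,
    sem_image: SEMImage,
    noise: NoiseModel,
    shifts,
    seeds,
    n_superpixels: int | None = None,
    timing_params: TimingParams | None = None,
) -> pd.DataFrame:
    """Three-pass RMSE as a function of SEM/Raman misregistration.

    Each shift is an integer pixel count applied along the x axis (or a
    (dy, dx) pair); shifts must include 0 so the aligned case anchors the
    comparison. Returns mean RMSE and a 95% interval per shift.
    """
    def _norm(s):
        return (0, int(s)) if np.isscalar(s) else tuple(int(v) for v in s)

    shifts = [_norm(s) for s in shifts]
    if (0, 0) not in shifts:
        raise ValueError("shifts must include 0")
    rows = []
    for sh in shifts:
        vals = [
            run_three_pass(
                scene, sem_image, noise, n_superpixels=n_superpixels, seed=s,
                timing_params=timing_params, misalignment_shift=sh,
            ).metrics["rmse"]
            for s in seeds
        ]
        rows.append(
            {
                "shift": max(abs(sh[0]), abs(sh[1])),
                "shift_dy": sh[0],
                "shift_dx": sh[1],
                "mean_rmse": float(np.mean(vals)),
                "rmse_ci95": _ci95(vals),
            }
        )
    return pd.DataFrame(rows)


#: Window of physiologically plausible mineral-to-matrix ratio values used
#: when pooling ratio pixels for class histograms; low-SNR ratios can blow up
#: on near-zero denominators and would otherwise dictate the bin grid.
RATIO_WINDOW = (0.0, 10.0)


def class_separation(
    n_pairs: int = 6,
    shape=(32, 32),
    L: int = 128,
    noise: NoiseModel | None = None,
    seed: int = 0,
    protocols_to_run=PROTOCOL_NAMES,
    timing_params: TimingParams | None = None,
    structure: str = "osteon_rings",
) -> dict:
    """Bhattacharyya separation of healthy vs diabetic phantom classes.

    Generates ``n_pairs`` scenes per class, runs each requested protocol,
    pools the valid ratio-image pixels (restricted to RATIO_WINDOW) per
    class, and returns {protocol: D_B} computed on a shared Freedman-Diaconis
    grid per protocol.
    """
    rng = np.random.default_rng(seed)
    if noise is None:
        probe = phantom.make_scene(*shape, L=L, seed=int(rng.integers(2**31 - 1)))
        noise = acquisition.calibrate_noise_model(
            phantom.render_cube(probe), seed=int(rng.integers(2**31 - 1))
        )
    pools = {p: {"healthy": [], "diabetic": []} for p in protocols_to_run}
    for i in range(n_pairs):
        for label in ("healthy", "diabetic"):
            s_scene = int(rng.integers(2**31 - 1))
            s_sem = int(rng.integers(2**31 - 1))
            s_run = int(rng.integers(2**31 - 1))
            scene = phantom.make_scene(
                *shape, L=L, structure=structure, class_label=label, seed=s_scene
            )
            sem = phantom.make_sem(scene, seed=s_sem)
            for p in protocols_to_run:
                res = run_protocol(
                    p, scene, sem, noise, seed=s_run, timing_params=timing_params
                )
                vals = res.ratio.valid_values()
                lo, hi = RATIO_WINDOW
                pools[p][label].append(vals[(vals > lo) & (vals <= hi)])
    out = {}
    for p in protocols_to_run:
        h = np.concatenate(pools[p]["healthy"])
        d = np.concatenate(pools[p]["diabetic"])
        out[p] = metrics.bhattacharyya_from_samples(h, d)
    return out
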