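"""Synthetic bone-like phantoms for smart-scanning simulation.

Real cortical-bone Raman data are rarely shareable, so every downstream stage
of the pipeline is exercised on phantoms generated here: linear-mixing
hyperspectral cubes built from a small set of endmember spectra (a mineral
phase peaked at the nu1-PO4 band, 960 cm-1, and an organic phase peaked at the
CH2 band, 1450 cm-1), piecewise-smooth abundance maps with osteon-like ring
structure, and a co-registered SEM-like grayscale image whose contrast follows
the mineral abundance, as electron backscatter contrast follows the degree of
mineralization in real bone.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Endmember",
    "Scene",
    "SEMImage",
    "wavenumber_axis",
    "make_endmembers",
    "default_endmembers",
    "make_scene",
    "make_blockwise_scene",
    "render_cube",
    "make_sem",
    "apply_shift",
    "DEFAULT_SEM_NOISE_SD",
]

#: Default spectral axis, matching a typical fingerprint-region Raman window.
DEFAULT_WN_RANGE = (400.0, 1800.0)
DEFAULT_L = 940

#: Standard deviation of the smooth structured discrepancy between the SEM
#: gray level and the mineral abundance (units of the [0, 1]-normalized SEM
#: contrast). Chosen so that the normalized cross-covariance between the SEM
#: image and the noiseless 960/1450 ratio image of the default phantom sits
#: near 0.6, the regime measured for real backscatter-SEM vs Raman ratio
#: images.
DEFAULT_SEM_NOISE_SD = 0.28

#: Mean mineral-abundance shift applied to diabetic-class scenes
#: (type-2 diabetes presents as tissue hyper-mineralization).
DEFAULT_CLASS_SHIFT = 0.15


@dataclass
class Endmember:
    """A pure-component spectrum over the wavenumber axis."""

    name: str
    spectrum: np.ndarray  # length-L, non-negative, a.u.
    peak_centers: list = field(default_factory=list)  # cm-1

    def __post_init__(self):
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if self.spectrum.ndim != 1 or self.spectrum.size < 2:
            raise ValueError("endmember spectrum must be a vector of length >= 2")
        if np.any(self.spectrum < 0):
            raise ValueError("endmember intensities must be non-negative")


@dataclass
class Scene:
    """Ground-truth abundances + endmembers on a shared wavenumber axis.

    ``abundances`` is X x Y x K; per-pixel abundances are non-negative and sum
    to one (linear-mixing simplex). ``class_label`` is 'healthy' or 'diabetic'.
    """

    abundances: np.ndarray
    endmembers: list
    wavenumber_axis: np.ndarray
    class_label: str = "healthy"
    seed: int | None = None

    def __post_init__(self):
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 3:
            raise ValueError("abundances must be X x Y x K")
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        if not np.allclose(a.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("per-pixel abundances must sum to 1")
        wn = np.asarray(self.wavenumber_axis, dtype=float)
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        self.abundances = a
        self.wavenumber_axis = wn

    @property
    def shape(self):
        return self.abundances.shape[:2]

    @property
    def n_endmembers(self):
        return self.abundances.shape[2]

    def endmember_index(self, name: str) -> int:
        for k, e in enumerate(self.endmembers):
            if e.name == name:
                return k
        raise KeyError(f"no endmember named {name!r}")


@dataclass
class SEMImage:
    """Fast-modality grayscale image registered to the scene grid."""

    pixels: np.ndarray
    pixel_pitch: float = 10.0  # micrometres per pixel

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("SEM image must be 2-D")
        if not np.all(np.isfinite(p)):
            raise ValueError("SEM image must be finite")
        self.pixels = p


def wavenumber_axis(L: int = DEFAULT_L, wn_range=DEFAULT_WN_RANGE) -> np.ndarray:
    """Evenly sampled wavenumber axis (cm-1), strictly increasing."""
    if L < 2:
        raise ValueError("need at least 2 spectral bands")
    return np.linspace(wn_range[0], wn_range[1], L)


def _line(nu, center, width, amplitude, lineshape):
    if lineshape == "gaussian":
        return amplitude * np.exp(-0.5 * ((nu - center) / width) ** 2)
    if lineshape == "lorentzian":
        return amplitude * width**2 / ((nu - center) ** 2 + width**2)
    raise ValueError(f"unknown lineshape {lineshape!r}")


def make_endmembers(
    peak_specs,
    L: int = DEFAULT_L,
    wn_range=DEFAULT_WN_RANGE,
    names=None,
    lineshape: str = "gaussian",
    baseline: float = 0.0,
):
    """Build endmembers as sums of spectral lines on a common axis.

    Parameters
    ----------
    peak_specs : sequence of sequences of (center_cm1, width_cm1, amplitude)
        One inner sequence per endmember.
    baseline : float
        Constant non-negative offset added to every band (smooth background).

    Returns
    -------
    list of Endmember
    """
    nu = wavenumber_axis(L, wn_range)
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    out = []
    for k, peaks in enumerate(peak_specs):
        s = np.full(L, float(baseline))
        centers = []
        for center, width, amplitude in peaks:
            if not (wn_range[0] <= center <= wn_range[1]):
                raise ValueError(
                    f"peak center {center} cm-1 outside axis range {wn_range}"
                )
            if width <= 0:
                raise ValueError("peak width must be positive")
            if amplitude < 0:
                raise ValueError("peak amplitude must be non-negative")
            s += _line(nu, center, width, amplitude, lineshape)
            centers.append(center)
        name = names[k] if names is not None else f"endmember_{k}"
        out.append(Endmember(name=name, spectrum=s, peak_centers=centers))
    return out


# Peak tables for the default bone-like factory: a mineral (apatite) phase
# dominated by the nu1-PO4 stretch at 960 cm-1 and an organic (matrix) phase
# dominated by the CH2 deformation at 1450 cm-1, with secondary bands for
# spectral realism. Widths are Gaussian sigmas in cm-1.
_DEFAULT_PEAKS = {
    "mineral": [(430, 15, 0.30), (590, 16, 0.30), (960, 12, 1.00), (1070, 14, 0.25)],
    "organic": [(855, 12, 0.25), (1245, 28, 0.40), (1450, 16, 1.00), (1660, 24, 0.55)],
    "collagen": [(815, 12, 0.35), (920, 14, 0.45), (1660, 22, 1.00)],
    "carbonate": [(710, 10, 0.30), (1070, 12, 1.00)],
    "lipid": [(1300, 18, 0.60), (1435, 13, 1.00)],
    "phenylalanine": [(1002, 8, 1.00), (1030, 10, 0.40)],
}


#: Default fluorescence background level relative to the strongest peak.
#: Raw 785 nm bone spectra sit on a substantial autofluorescence pedestal
#: even after surface polishing; a constant pedestal of ~30% of the main
#: band is on the conservative side of what raw clinical spectra show.
DEFAULT_BASELINE = 0.3


def default_endmembers(
    K: int = 2,
    L: int = DEFAULT_L,
    wn_range=DEFAULT_WN_RANGE,
    baseline: float = DEFAULT_BASELINE,
):
    """Bone-like endmember factory: mineral (960 cm-1) and organic (1450 cm-1)
    first, then additional tissue components up to K = 6."""
    names = list(_DEFAULT_PEAKS)
    if not 1 <= K <= len(names):
        raise ValueError(f"K must be in [1, {len(names)}]")
    names = names[:K]
    return make_endmembers(
        [_DEFAULT_PEAKS[n] for n in names],
        L=L, wn_range=wn_range, names=names, baseline=baseline,
    )


def _smooth_noise(rng, X, Y, sigma):
    """Unit-variance smooth random field."""
    f = gaussian_filter(rng.standard_normal((X, Y)), sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _mineral_field(rng, X, Y, structure, ring_width=4.0):
    base = 0.45
    if structure == "osteon_rings":
        # Concentric lamellae of alternating mineral fraction around seeded
        # osteon centers; ring period 2*ring_width >= 8 px keeps features
        # larger than the ~3x3 px superpixels used downstream.
        n_centers = max(1, int(round(X * Y / 1200)))
        cx = rng.uniform(0, X, n_centers)
        cy = rng.uniform(0, Y, n_centers)
        yy, xx = np.meshgrid(np.arange(Y), np.arange(X))
        d = np.min(
            np.sqrt((xx[..., None] - cx) ** 2 + (yy[..., None] - cy) ** 2), axis=2
        )
        # discrete alternating lamellae (step-like mineral banding), with a
        # sub-pixel smoothing to avoid aliasing on the ring boundaries
        rings = np.sign(np.cos(np.pi * d / ring_width))
        rings = gaussian_filter(rings, sigma=0.7, mode="reflect")
        m = base + 0.12 * rings
        m += 0.05 * _smooth_noise(rng, X, Y, sigma=max(3.0, min(X, Y) / 12))
    elif structure == "blocks":
        b = max(4, min(X, Y) // 4)
        nbx, nby = -(-X // b), -(-Y // b)
        vals = rng.uniform(0.2, 0.8, size=(nbx, nby))
        m = np.kron(vals, np.ones((b, b)))[:X, :Y]
    elif structure == "random_smooth":
        m = base + 0.15 * _smooth_noise(rng, X, Y, sigma=max(3.0, min(X, Y) / 8))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return m


def make_scene(
    X: int,
    Y: int,
    K: int = 2,
    structure: str = "osteon_rings",
    class_label: str = "healthy",
    seed: int = 0,
    L: int = DEFAULT_L,
    wn_range=DEFAULT_WN_RANGE,
    class_shift: float = DEFAULT_CLASS_SHIFT,
    endmembers=None,
) -> Scene:
    """Generate a piecewise-smooth abundance scene with bone-like structure.

    The mineral-abundance field carries the spatial structure; the remaining
    mass is split among the organic endmembers by smooth random weights.
    Diabetic scenes have their mean mineral abundance shifted up by
    ``class_shift`` (hyper-mineralization). Deterministic for a fixed seed.
    """
    if X < 8 or Y < 8:
        raise ValueError("grid must be at least 8 x 8")
    if not 1 <= K <= 6:
        raise ValueError("K must be in [1, 6]")
    if class_label not in ("healthy", "diabetic"):
        raise ValueError("class_label must be 'healthy' or 'diabetic'")
    if endmembers is None:
        endmembers = default_endmembers(K, L=L, wn_range=wn_range)
    if len(endmembers) != K:
        raise ValueError("need exactly K endmembers")
    rng = np.random.default_rng(seed)

    if K == 1:
        abund = np.ones((X, Y, 1))
        return Scene(abund, endmembers, wavenumber_axis(L, wn_range), class_label, seed)

    m = _mineral_field(rng, X, Y, structure)
    if class_label == "diabetic":
        m = m + class_shift
    m = np.clip(m, 0.02, 0.98)

    abund = np.empty((X, Y, K))
    abund[..., 0] = m
    if K == 2:
        abund[..., 1] = 1.0 - m
    else:
        w = np.stack(
            [_smooth_noise(rng, X, Y, sigma=max(3.0, min(X, Y) / 8)) for _ in range(K - 1)],
            axis=-1,
        )
        w = np.exp(w)
        w /= w.sum(axis=-1, keepdims=True)
        abund[..., 1:] = (1.0 - m)[..., None] * w
    return Scene(abund, endmembers, wavenumber_axis(L, wn_range), class_label, seed)


def make_blockwise_scene(
    labels: np.ndarray,
    K: int = 2,
    seed: int = 0,
    L: int = DEFAULT_L,
    wn_range=DEFAULT_WN_RANGE,
    include_pure: bool = True,
    class_label: str = "healthy",
    endmembers=None,
) -> Scene:
    """Scene whose abundances are constant on the regions of a label image.

    Useful for exact-model studies: when the regions coincide with the
    superpixels used downstream, the superpixel-constant reconstruction is
    exact. With ``include_pure`` the first K regions are pure endmembers, so
    every endmember appears pure at some representative pixel.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if endmembers is None:
        endmembers = default_endmembers(K, L=L, wn_range=wn_range)
    rng = np.random.default_rng(seed)
    fr = rng.dirichlet(np.ones(K), size=ids.size)
    if include_pure:
        if ids.size < K:
            raise ValueError("need at least K regions for pure assignments")
        fr[:K] = np.eye(K)
    abund = np.empty(labels.shape + (K,))
    for i, lab in enumerate(ids):
        abund[labels == lab] = fr[i]
    return Scene(abund, endmembers, wavenumber_axis(L, wn_range), class_label, seed)


def render_cube(scene: Scene) -> np.ndarray:
    """Noiseless linear-mixing cube: cube(x,y,.) = sum_k a_k(x,y) * E_k."""
    E = np.stack([e.spectrum for e in scene.endmembers])  # K x L
    return np.einsum("xyk,kl->xyl", scene.abundances, E)


def make_sem(
    scene: Scene,
    contrast_map: str = "mineral",
    correlation_noise_sd: float = DEFAULT_SEM_NOISE_SD,
    seed: int = 0,
    pixel_pitch: float = 10.0,
    noise_correlation_length: float = 2.0,
) -> SEMImage:
    """SEM-like grayscale image: affine map of one abundance plus a smooth
    structured discrepancy.

    Electron micrographs at this magnification are essentially noise-free at
    the pixel level; what limits their correlation with the Raman ratio is
    that backscatter contrast is not chemistry. That discrepancy is spatially
    structured, so the additive term is a smooth random field (correlation
    length ``noise_correlation_length`` pixels) of standard deviation
    ``correlation_noise_sd``, not white pixel noise. With
    ``correlation_noise_sd = 0`` the image is an affine function of the
    chosen abundance, so its normalized cross-covariance with that abundance
    map is exactly 1.
    """
    k = scene.endmember_index(contrast_map)
    a = scene.abundances[..., k]
    lo, hi = a.min(), a.max()
    base = (a - lo) / (hi - lo) if hi > lo else a.copy()
    rng = np.random.default_rng(seed)
    if correlation_noise_sd > 0:
        noise = correlation_noise_sd * _smooth_noise(
            rng, *base.shape, sigma=noise_correlation_length
        )
        pixels = base + noise
    else:
        pixels = base.copy()
    return SEMImage(pixels=pixels, pixel_pitch=pixel_pitch)


def apply_shift(image: np.ndarray, n_pixels) -> np.ndarray:
    """Translate an image by an integer pixel vector with replicate padding.

    ``n_pixels`` may be an int (shift along the second/x axis) or a
    ``(dy, dx)`` pair. The output at (y, x) is the input at (y-dy, x-dx),
    clamped to the grid, i.e. content moves by (dy, dx) and edges replicate.
    """
    img = np.asarray(image)
    if np.isscalar(n_pixels):
        dy, dx = 0, int(n_pixels)
    else:
        dy, dx = (int(v) for v in n_pixels)
    X, Y = img.shape[:2]
    if abs(dy) >= X or abs(dx) >= Y:
        raise ValueError("shift magnitude must be smaller than the image")
    iy = np.clip(np.arange(X) - dy, 0, X - 1)
    ix = np.clip(np.arange(Y) - dx, 0, Y - 1)
    return img[np.ix_(iy, ix)]
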