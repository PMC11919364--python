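"""Evaluation metrics: reconstruction RMSE, mineralization ratio imaging,
normalized cross-covariance, histogram density estimation and the
Bhattacharyya distance between class distributions.

The ratio image R(x,y) = I(x,y,960 cm-1) / I(x,y,1450 cm-1) (nu1-PO4 over
CH2 band intensity) is the clinically meaningful readout for bone: it tracks
the degree of tissue mineralization. Healthy-vs-hypermineralized separation
is quantified by the Bhattacharyya distance between the two classes'
R-histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RatioImage",
    "Distribution",
    "rmse",
    "ratio_image",
    "cross_covariance",
    "histogram",
    "freedman_diaconis_delta",
    "bhattacharyya",
    "bhattacharyya_from_samples",
    "smoothed_density",
]

LAMBDA_MINERAL = 960.0  # cm-1, nu1-PO4 stretch
LAMBDA_ORGANIC = 1450.0  # cm-1, CH2 deformation

#: Relative magnitude (vs the cube's max absolute intensity) below which the
#: ratio denominator is considered numerically zero and the pixel masked.
DENOMINATOR_REL_THRESHOLD = 1e-12


@dataclass
class RatioImage:
    """Per-pixel band-intensity ratio with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the ratio is valid
    lambda1: float = LAMBDA_MINERAL
    lambda2: float = LAMBDA_ORGANIC
    band_indices: tuple = (None, None)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class Distribution:
    """Histogram density estimate: densities f(nu_i) on bins of width delta.

    Normalized so that delta * sum(densities) = 1 over the pixels counted.
    """

    bin_centers: np.ndarray
    delta: float
    densities: np.ndarray
    n: int

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")
        if abs(self.delta * self.densities.sum() - 1.0) > 1e-9:
            raise ValueError("densities must integrate to 1")

    @property
    def masses(self) -> np.ndarray:
        return self.densities * self.delta


def rmse(output_cube, reference_cube) -> float:
    """Root mean square spectral error between two cubes.

    The mean squared difference is taken per pixel over the spectral bands,
    then averaged over pixels, then rooted. With uniform weights this equals
    the RMS of the elementwise difference.
    """
    a = np.asarray(output_cube, dtype=float)
    b = np.asarray(reference_cube, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    per_pixel = np.mean((a - b) ** 2, axis=-1)
    return float(np.sqrt(np.mean(per_pixel)))


def ratio_image(
    cube,
    wavenumber_axis,
    lambda1: float = LAMBDA_MINERAL,
    lambda2: float = LAMBDA_ORGANIC,
) -> RatioImage:
    """Single-band intensity ratio at the bands nearest lambda1 and lambda2.

    Pixels whose denominator magnitude falls below a small fraction of the
    cube's maximum are masked rather than producing infinities (low-SNR or
    unconstrained-least-squares cubes can contain near-zero or negative
    intensities).
    """
    cube = np.asarray(cube, dtype=float)
    wn = np.asarray(wavenumber_axis, dtype=float)
    if not (wn[0] <= lambda1 <= wn[-1] and wn[0] <= lambda2 <= wn[-1]):
        raise ValueError("requested wavenumbers outside the axis")
    i1 = int(np.argmin(np.abs(wn - lambda1)))
    i2 = int(np.argmin(np.abs(wn - lambda2)))
    num = cube[..., i1]
    den = cube[..., i2]
    thresh = DENOMINATOR_REL_THRESHOLD * np.max(np.abs(cube))
    mask = np.abs(den) > thresh
    values = np.zeros_like(num)
    np.divide(num, den, out=values, where=mask)
    return RatioImage(
        values=values, mask=mask, lambda1=lambda1, lambda2=lambda2,
        band_indices=(i1, i2),
    )


def cross_covariance(A, B, mask=None) -> float:
    """Normalized cross-covariance C(A,B) = Cov(A,B)/sqrt(Var(A) Var(B)).

    1 for maximally correlated images, -1 for anti-correlated, ~0 for
    independent ones; invariant to positive affine rescaling of either image.
    RatioImage inputs contribute their own validity masks.
    """
    a, ma = _image_and_mask(A)
    b, mb = _image_and_mask(B)
    if a.shape != b.shape:
        raise ValueError("images must share a pixel grid")
    m = ma & mb
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    av, bv = a[m].ravel(), b[m].ravel()
    if av.size < 2:
        raise ValueError("not enough unmasked pixels")
    va, vb = av.var(), bv.var()
    if va == 0 or vb == 0:
        raise ValueError("zero-variance image: normalization undefined")
    cov = np.mean((av - av.mean()) * (bv - bv.mean()))
    return float(cov / np.sqrt(va * vb))


def _image_and_mask(A):
    if isinstance(A, RatioImage):
        return A.values, A.mask
    a = np.asarray(A, dtype=float)
    return a, np.ones(a.shape, dtype=bool)


def freedman_diaconis_delta(values) -> float:
    """Freedman-Diaconis bin width; falls back to Scott/range rules when the
    IQR degenerates."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr > 0:
        return float(2.0 * iqr / v.size ** (1.0 / 3.0))
    sd = v.std()
    if sd > 0:
        return float(3.49 * sd / v.size ** (1.0 / 3.0))
    return 1.0


def histogram(values, delta: float | None = None, value_range=None) -> Distribution:
    """Histogram density estimate with bin width delta.

    f(nu_i) counts the values within half a bin width of each bin center,
    scaled by 1/(n*delta) with n the number of values inside the range, so
    the densities integrate to one. ``delta`` defaults to Freedman-Diaconis.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if delta is None:
        delta = freedman_diaconis_delta(v)
    if delta <= 0:
        raise ValueError("delta must be positive")
    if value_range is None:
        value_range = (v.min(), v.max())
    lo, hi = value_range
    n_bins = max(1, int(np.ceil((hi - lo) / delta - 1e-12)))
    edges = lo + delta * np.arange(n_bins + 1)
    inside = v[(v >= lo) & (v <= edges[-1])]
    if inside.size == 0:
        raise ValueError("no values inside the requested range")
    counts, _ = np.histogram(inside, bins=edges)
    centers = edges[:-1] + delta / 2.0
    densities = counts / (inside.size * delta)
    return Distribution(bin_centers=centers, delta=delta, densities=densities, n=int(inside.size))


def _align_masses(f: Distribution, g: Distribution):
    """Place both distributions' probability masses on the union bin grid.

    Requires a common delta and bin centers offset by an integer number of
    bins; masses are renormalized to unit total on the shared grid.
    """
    if abs(f.delta - g.delta) > 1e-9 * max(f.delta, g.delta):
        raise ValueError("distributions must share a common bin width delta")
    d = f.delta
    off = (g.bin_centers[0] - f.bin_centers[0]) / d
    if abs(off - round(off)) > 1e-6:
        raise ValueError("bin grids are not aligned (centers differ by a non-integer number of bins)")
    start = min(f.bin_centers[0], g.bin_centers[0])
    end = max(f.bin_centers[-1], g.bin_centers[-1])
    n = int(round((end - start) / d)) + 1
    grid = start + d * np.arange(n)

    def place(dist):
        p = np.zeros(n)
        i0 = int(round((dist.bin_centers[0] - start) / d))
        p[i0 : i0 + len(dist.bin_centers)] = dist.masses
        s = p.sum()
        return p / s if s > 0 else p

    return grid, place(f), place(g)


def bhattacharyya(f: Distribution, g: Distribution) -> float:
    """Bhattacharyya distance D_B = -log sum_i sqrt(p_i q_i) on a shared grid.

    Zero iff the two distributions coincide bin-by-bin; +inf for disjoint
    supports (zero overlap). The higher D_B, the more distinguishable the
    two populations. Symmetric in its arguments.
    """
    _, p, q = _align_masses(f, g)
    bc = float(np.sum(np.sqrt(p * q)))
    if bc <= 0.0:
        return np.inf
    return float(-np.log(min(bc, 1.0)))


def bhattacharyya_from_samples(a, b, delta: float | None = None, value_range=None) -> float:
    """D_B between two sample sets, histogrammed on a shared grid.

    The bin width defaults to Freedman-Diaconis on the pooled samples; the
    range defaults to the pooled min/max.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    pooled = np.concatenate([a, b])
    if delta is None:
        delta = freedman_diaconis_delta(pooled)
    if value_range is None:
        value_range = (pooled.min(), pooled.max())
    fa = histogram(a, delta=delta, value_range=value_range)
    fb = histogram(b, delta=delta, value_range=value_range)
    return bhattacharyya(fa, fb)


def smoothed_density(dist: Distribution, bandwidth_bins: float = 2.0):
    """Gaussian-kernel smoothed copy of a density for display purposes only;
    never feeds the Bhattacharyya distance."""
    sm = gaussian_filter1d(dist.densities, sigma=bandwidth_bins, mode="constant")
    s = sm.sum() * dist.delta
    if s > 0:
        sm = sm / s
    return Distribution(
        bin_centers=dist.bin_centers, delta=dist.delta, densities=sm, n=dist.n
    )
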