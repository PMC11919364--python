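"""Fourier-phasor mapping and convex-hull selection of essential spectra.

Each low-SNR spectrum is summarized by one harmonic of its discrete Fourier
transform, normalized by the spectrum's L1 norm, giving a 2-D point
(G_r, Q_r). Spectra that are convex mixtures of a few pure components map to
convex mixtures of the pure components' phasor points, so the whole cloud
lies inside the polygon spanned by the "purest" spectra: the vertices of the
cloud's 2-D convex hull. Those hull-vertex pixels are the essential spectra —
the only positions worth re-scanning at high SNR.

DFT convention (pinned for reproducibility): the analysis coefficient
c_r = sum_{lambda=1..L} s(lambda) * exp(-i*2*pi*(r-1)(lambda-1)/L), i.e.
numpy's forward FFT bin r-1, without a 1/L factor. Harmonic r=1 is the DC
term; the first informative harmonic is r=2 (the default). Only the relative
geometry of the cloud matters for hull selection, so the sign/scale
convention does not affect which pixels are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import acquisition

__all__ = [
    "SpectralMatrix",
    "PhasorCloud",
    "EssentialSet",
    "phasor_transform",
    "essential_select",
    "essential_table",
    "rescan_essential",
]

DEFAULT_HARMONIC = 2

_DEGENERACY_RTOL = 1e-12


@dataclass
class SpectralMatrix:
    """P spectra (one per row) with their pixel positions."""

    spectra: np.ndarray  # P x L
    positions: np.ndarray  # P x 2 (x, y)
    snr_tag: str = "low"

    def __post_init__(self):
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.positions = np.asarray(self.positions, dtype=int).reshape(-1, 2)
        if np.any(~np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite (no NaN)")
        if len(self.positions) != len(self.spectra):
            raise ValueError("positions length must match spectra count")

    @property
    def n_spectra(self):
        return self.spectra.shape[0]


@dataclass
class PhasorCloud:
    """L1-normalized real/imaginary Fourier coordinates at one harmonic."""

    g: np.ndarray
    q: np.ndarray
    harmonic_r: int
    positions: np.ndarray = field(default=None)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.harmonic_r < 2:
            raise ValueError("harmonic_r must be >= 2 (r=1 is the DC term)")
        if not (np.all(np.isfinite(self.g)) and np.all(np.isfinite(self.q))):
            raise ValueError("phasor coordinates must be finite")

    @property
    def points(self):
        return np.column_stack([self.g, self.q])


@dataclass
class EssentialSet:
    """Hull-vertex pixels: indices into the source cloud, positions, spectra."""

    indices: np.ndarray
    positions: np.ndarray = None
    spectra: np.ndarray = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("essential indices must be distinct")

    @property
    def n_essential(self):
        return len(self.indices)


def phasor_transform(spectral_matrix, harmonic_r: int = DEFAULT_HARMONIC) -> PhasorCloud:
    """Map spectra to (G_r, Q_r) phasor coordinates at one harmonic.

    Accepts a SpectralMatrix or a bare P x L array. Each spectrum's Fourier
    coefficient at the chosen harmonic is divided by the spectrum's L1 norm,
    which removes overall intensity: scaling a spectrum by any c > 0 leaves
    its phasor point unchanged. A spectrum with zero L1 norm is rejected
    (its normalization is undefined) with its position in the message.
    """
    if isinstance(spectral_matrix, SpectralMatrix):
        spectra, positions = spectral_matrix.spectra, spectral_matrix.positions
    else:
        spectra = np.atleast_2d(np.asarray(spectral_matrix, dtype=float))
        positions = None
    L = spectra.shape[1]
    if not 2 <= harmonic_r <= L:
        raise ValueError("harmonic_r must lie in [2, L]")
    l1 = np.sum(np.abs(spectra), axis=1)
    zero = np.flatnonzero(l1 == 0)
    if zero.size:
        where = positions[zero].tolist() if positions is not None else zero.tolist()
        raise ValueError(f"zero-L1-norm spectra at {where}")
    c = np.fft.fft(spectra, axis=1)[:, harmonic_r - 1]
    return PhasorCloud(
        g=c.real / l1, q=c.imag / l1, harmonic_r=harmonic_r, positions=positions
    )


def _collinear_extremes(pts):
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= _DEGENERACY_RTOL:
        return np.array([0])  # all points coincident
    if s[1] > _DEGENERACY_RTOL * s[0]:
        return None  # genuinely 2-D
    t = centered @ vt[0]
    return np.unique([int(np.argmin(t)), int(np.argmax(t))])


def essential_select(phasor_cloud: PhasorCloud, spectral_matrix=None) -> EssentialSet:
    """Vertices of the 2-D convex hull of the phasor cloud.

    Degenerate clouds are handled rather than rejected: a fully coincident
    cloud yields H=1 (its first point); a collinear cloud yields its two
    extreme points. Duplicate coordinates are deduplicated before the hull
    (first occurrence kept) so downstream unmixing sees distinct spectra.
    Returned indices are sorted ascending.
    """
    pts = phasor_cloud.points
    if len(pts) == 0:
        raise ValueError("empty phasor cloud")
    uniq, first = np.unique(pts, axis=0, return_index=True)
    upts = pts[np.sort(first)]
    umap = np.sort(first)

    if len(upts) == 1:
        idx = umap[:1]
    else:
        deg = _collinear_extremes(upts)
        if deg is not None:
            idx = umap[deg]
        else:
            try:
                hull = ConvexHull(upts)
                idx = umap[hull.vertices]
            except QhullError:
                # near-degenerate cloud below qhull's tolerance
                idx = umap[_collinear_extremes_forced(upts)]
    idx = np.sort(idx)

    positions = spectra = None
    if phasor_cloud.positions is not None:
        positions = np.asarray(phasor_cloud.positions)[idx]
    if spectral_matrix is not None:
        sm = (
            spectral_matrix.spectra
            if isinstance(spectral_matrix, SpectralMatrix)
            else np.atleast_2d(np.asarray(spectral_matrix, dtype=float))
        )
        spectra = sm[idx]
        if positions is None and isinstance(spectral_matrix, SpectralMatrix):
            positions = spectral_matrix.positions[idx]
    return EssentialSet(indices=idx, positions=positions, spectra=spectra)


def _collinear_extremes_forced(pts):
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    return np.unique([int(np.argmin(t)), int(np.argmax(t))])


def essential_table(essential_set: EssentialSet, phasor_cloud: PhasorCloud):
    """Tabulate the essential set for CSV export: index, x, y, g, q per row
    (0-based, row-major coordinates)."""
    import pandas as pd

    idx = essential_set.indices
    pos = essential_set.positions
    if pos is None:
        pos = np.full((len(idx), 2), -1)
    return pd.DataFrame(
        {
            "index": idx,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "g": phasor_cloud.g[idx],
            "q": phasor_cloud.q[idx],
        }
    )


def rescan_essential(
    essential_set: EssentialSet, cube_noiseless, dwell_high_ms, noise_model, seed
) -> SpectralMatrix:
    """High-SNR re-acquisition at the essential pixel positions.

    Row order matches the essential set; delegates to acquisition.acquire.
    """
    if essential_set.positions is None:
        raise ValueError("essential set carries no pixel positions")
    spectra = acquisition.acquire(
        cube_noiseless, essential_set.positions, dwell_high_ms, noise_model, seed
    )
    return SpectralMatrix(
        spectra=spectra, positions=essential_set.positions, snr_tag="high"
    )
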