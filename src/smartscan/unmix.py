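"""Least-squares unmixing against essential spectra and superpixel-constant
reconstruction of the output hyperspectral image.

Each representative's low-SNR spectrum I_p is decomposed on the H essential
low-SNR spectra S (rows of an H x L matrix) by ordinary least squares,
c_p = (S S^T)^(-1) S I_p — unconstrained, so concentrations may come out
negative under noise; an optional non-negative mode is available. The output
image then assigns to every pixel of superpixel p the high-SNR synthesis
S_high^T c_p, i.e. one spectrum per superpixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = ["ConcentrationMap", "ReconstructedCube", "concentrations", "reconstruct"]

#: Reciprocal-condition-number threshold below which the Gram solve falls
#: back to the minimum-norm pseudo-inverse (near-duplicate hull vertices
#: from noise must not crash the pipeline).
RCOND_THRESHOLD = 1e-10


@dataclass
class ConcentrationMap:
    """H x P concentrations: column p reconstructs representative p's
    spectrum with least-squares optimality."""

    c: np.ndarray
    essential_ref: object = None
    superpixel_ref: object = None

    def __post_init__(self):
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        if not np.all(np.isfinite(self.c)):
            raise ValueError("concentrations must be finite")


@dataclass
class ReconstructedCube:
    """Superpixel-constant output cube with a provenance record."""

    cube: np.ndarray
    provenance: dict = field(default_factory=dict)


def concentrations(S, I, nonnegative: bool = False) -> ConcentrationMap:
    """Least-squares concentrations of essential spectra in each spectrum.

    Parameters
    ----------
    S : H x L array
        Essential spectra, one per row.
    I : P x L array
        Spectra to decompose, one per row.
    nonnegative : bool
        Solve each column with a non-negativity constraint instead of the
        plain (possibly negative) least-squares estimator.

    Returns
    -------
    ConcentrationMap with c of shape H x P; when S has full row rank each
    column equals the pseudo-inverse solution of S^T c ~= I_p.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    I = np.atleast_2d(np.asarray(I, dtype=float))
    if S.shape[1] != I.shape[1]:
        raise ValueError("S and I must share the spectral axis length")
    if nonnegative:
        c = np.column_stack([nnls(S.T, I[p])[0] for p in range(I.shape[0])])
        return ConcentrationMap(c=c)
    gram = S @ S.T
    sv = np.linalg.svd(gram, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if rcond < RCOND_THRESHOLD:
        warnings.warn(
            f"essential spectra nearly rank-deficient (rcond={rcond:.2e}); "
            "using minimum-norm pseudo-inverse"
        )
        c = np.linalg.pinv(S.T) @ I.T
    else:
        c = np.linalg.solve(gram, S @ I.T)
    return ConcentrationMap(c=c)


def reconstruct(S_high, concentration_map, superpixel_map) -> ReconstructedCube:
    """Assemble the output cube: pixel with label p gets S_high^T c(:, p).

    Every pixel of a superpixel receives the identical spectrum, so the
    within-superpixel spectral variance of the output is exactly zero.
    """
    S = np.atleast_2d(np.asarray(getattr(S_high, "spectra", S_high), dtype=float))
    c = concentration_map.c if isinstance(concentration_map, ConcentrationMap) else np.atleast_2d(concentration_map)
    labels = superpixel_map.labels
    P = superpixel_map.n_superpixels
    if c.shape[0] != S.shape[0]:
        raise ValueError("concentration rows must match essential spectra count")
    if c.shape[1] != P:
        raise ValueError(
            f"superpixel map has {P} labels but concentrations cover {c.shape[1]}"
        )
    per_label = c.T @ S  # P x L
    cube = per_label[labels - 1]
    return ReconstructedCube(cube=cube, provenance={"P": P, "H": S.shape[0]})
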