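"""Superpixel segmentation of the fast-modality image and representative
pixel selection.

The fast (SEM) image is segmented with SLIC into roughly P compact,
connected superpixels; the member pixel closest to each superpixel's centroid
becomes its representative, the only position scanned in the low-SNR Raman
pass. Downstream code always consumes the achieved superpixel count read from
the map — SLIC treats the requested P as a target, not a contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.segmentation import slic

__all__ = ["SuperpixelMap", "segment", "representatives", "target_superpixels"]

#: Default superpixel area (pixels): ~3x3 blocks, small enough that the
#: chemical content within one superpixel can be assumed homogeneous at the
#: bone-lamella scale.
DEFAULT_SUPERPIXEL_AREA = 9

DEFAULT_COMPACTNESS = 0.1
DEFAULT_SIGMA = 0.0


@dataclass
class SuperpixelMap:
    """Label image (values 1..P, every label non-empty) plus one
    representative pixel per label; representative p carries label p."""

    labels: np.ndarray
    representatives: np.ndarray  # P x 2 array of (x, y)
    source_shape: tuple

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.representatives = np.asarray(self.representatives, dtype=int)
        P = self.n_superpixels
        if self.labels.min() != 1 or self.labels.max() != P:
            raise ValueError("labels must cover 1..P")
        if len(np.unique(self.labels)) != P:
            raise ValueError("every label in 1..P must be non-empty")
        rx, ry = self.representatives[:, 0], self.representatives[:, 1]
        if not np.array_equal(self.labels[rx, ry], np.arange(1, P + 1)):
            raise ValueError("representative p must carry label p")
        if len(np.unique(rx * self.labels.shape[1] + ry)) != P:
            raise ValueError("representatives must be distinct")

    @property
    def n_superpixels(self) -> int:
        return len(self.representatives)


def target_superpixels(shape, area: int = DEFAULT_SUPERPIXEL_AREA) -> int:
    """Requested P giving superpixels of approximately ``area`` pixels."""
    return max(1, -(-shape[0] * shape[1] // area))


def representatives(labels: np.ndarray) -> np.ndarray:
    """Representative pixel per label: the member nearest (Euclidean) to the
    label's center of mass; ties broken by smaller row-major index.

    The result always lies inside its superpixel, even for non-convex
    regions whose geometric centroid falls outside.
    """
    labels = np.asarray(labels)
    Y = labels.shape[1]
    ids = np.unique(labels)
    reps = np.empty((len(ids), 2), dtype=int)
    for i, lab in enumerate(ids):
        xs, ys = np.nonzero(labels == lab)
        cx, cy = xs.mean(), ys.mean()
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        best = np.flatnonzero(d2 == d2.min())
        j = best[np.argmin(xs[best] * Y + ys[best])]
        reps[i] = xs[j], ys[j]
    return reps


def segment(
    image: np.ndarray,
    n_superpixels: int | None = None,
    compactness: float = DEFAULT_COMPACTNESS,
    sigma: float = DEFAULT_SIGMA,
    seed: int | None = None,
) -> SuperpixelMap:
    """SLIC segmentation of a grayscale image into ~P connected superpixels.

    The image is min-max normalized before clustering so the compactness
    parameter has a consistent meaning across inputs. ``n_superpixels``
    defaults to one superpixel per ~3x3 pixel block. The achieved count (read
    from the map) may differ from the request.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment expects a single-channel image")
    X, Y = img.shape
    if n_superpixels is None:
        n_superpixels = target_superpixels(img.shape)
    if not 1 <= n_superpixels <= X * Y:
        raise ValueError("need 1 <= P <= number of pixels")
    if compactness <= 0:
        raise ValueError("compactness must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")

    if n_superpixels == 1:
        labels = np.ones((X, Y), dtype=int)
    else:
        lo, hi = img.min(), img.max()
        norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        labels = slic(
            norm,
            n_segments=n_superpixels,
            compactness=compactness,
            sigma=sigma,
            channel_axis=None,
            start_label=1,
            enforce_connectivity=True,
        )
        # relabel to a contiguous 1..P range
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(X, Y) + 1
    reps = representatives(labels)
    return SuperpixelMap(labels=labels, representatives=reps, source_shape=(X, Y))
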