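"""Gaussian-pyramid multiresolution schedule for coarse-to-fine registration.

Each pyramid level is produced by a REDUCE step

    g_k(i, j) = sum_m sum_n W(m, n) * g_{k-1}(2i + m, 2j + n)

with a normalized, separable, symmetric window W and border replication,
halving the image (output size ceil(n/2), pixel spacing doubled).  An
extra same-size smoothing pass with the same window precedes each reduce
and is applied once at the finest level, improving noise suppression at
every scale.  Registration then proceeds coarse level first, each level's
optimum seeding the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .volume_io import Image2D


@dataclass
class PyramidWindow:
    """Normalized separable smoothing window of radius r."""

    weights: np.ndarray
    radius: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (2 * self.radius + 1, 2 * self.radius + 1):
            raise ValueError(f"weights shape {w.shape} inconsistent with radius {self.radius}")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"window weights must sum to 1, got {w.sum()}")
        if np.any(w < 0):
            raise ValueError("window weights must be nonnegative")
        self.weights = w


def binomial_window(radius: int = 2) -> PyramidWindow:
    """Separable binomial window; radius 2 gives the classic (1,4,6,4,1)/16."""
    k = np.array([1.0])
    for _ in range(2 * radius):
        k = np.convolve(k, [0.5, 0.5])
    return PyramidWindow(weights=np.outer(k, k), radius=radius)


@dataclass
class PyramidLevel:
    image: Image2D
    scale: int  # downsampling factor relative to the original (1, 2, 4, ...)


@dataclass
class PyramidSchedule:
    """Ordered pyramid levels, coarsest first."""

    levels: list  # of PyramidLevel


def pre_smooth(img: Image2D, w: PyramidWindow | None = None, repeats: int = 1) -> Image2D:
    """Same-size convolution with the window, border replicated."""
    w = w or binomial_window()
    px = img.pixels
    if px.shape[0] < 4 or px.shape[1] < 4:
        raise ValueError(f"image too small to smooth: {px.shape}")
    for _ in range(repeats):
        px = correlate(px, w.weights, mode="nearest")
    return Image2D(pixels=px, spacing=img.spacing)


def gaussian_reduce(img: Image2D, w: PyramidWindow | None = None) -> Image2D:
    """One REDUCE step: window-weighted 2x downsampling, size ceil(n/2)."""
    w = w or binomial_window()
    px = img.pixels
    if px.shape[0] < 4 or px.shape[1] < 4:
        raise ValueError(f"image too small to reduce: {px.shape}")
    sm = correlate(px, w.weights, mode="nearest")
    out = sm[::2, ::2]
    return Image2D(pixels=out, spacing=(img.spacing[0] * 2, img.spacing[1] * 2))


def build_schedule(
    fixed: Image2D,
    levels: int = 2,
    w: PyramidWindow | None = None,
    presmooth: int = 1,
) -> PyramidSchedule:
    """Coarse-to-fine schedule of the fixed image.

    The finest level is the pre-smoothed original; each coarser level
    applies `presmooth` smoothing passes then a REDUCE.  `presmooth=0`
    disables smoothing entirely (levels are raw reductions).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    w = w or binomial_window()
    min_dim = min(fixed.pixels.shape)
    if min_dim // (2 ** (levels - 1)) < 4:
        raise ValueError(f"image of shape {fixed.pixels.shape} too small for {levels} levels")
    img = pre_smooth(fixed, w, repeats=presmooth) if presmooth > 0 else fixed
    lvls = [PyramidLevel(image=img, scale=1)]
    for k in range(1, levels):
        prev = lvls[-1].image
        nxt = pre_smooth(prev, w, repeats=presmooth) if presmooth > 0 else prev
        lvls.append(PyramidLevel(image=gaussian_reduce(nxt, w), scale=2**k))
    lvls.reverse()  # coarsest first
    return PyramidSchedule(levels=lvls)
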