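"""Multilevel 2D Haar discrete wavelet transform.

One analysis level splits an image into four half-resolution sub-bands: the
approximation LL (a smoothed, downscaled copy) and the three detail bands
LH, HL, HH. Repeating the split on LL gives a pyramid; after ``k`` levels the
approximation has ``1/2^k`` the side length of the input. A 512x512 slice
therefore reduces to a 64x64 approximate image at level 3, which is what the
classifier consumes — the detail bands are discarded.

The orthonormal convention (filter taps ``1/sqrt(2)``) is used throughout, so
a single level maps each disjoint 2x2 block ``[[a, b], [c, d]]`` to

    LL = (a + b + c + d) / 2      LH = (a - b + c - d) / 2
    HL = (a + b - c - d) / 2      HH = (a - b - c + d) / 2

and the total energy (sum of squared coefficients) is conserved exactly.
Consequently the level-``k`` LL equals ``2^k`` times the mean over each
disjoint ``2^k x 2^k`` block — a useful closed form for testing. LH carries
horizontal (column-difference) detail, HL vertical detail, HH diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError
from .io import save_gray
from .preprocess import validate_rgb


@dataclass(frozen=True)
class SubBandSet:
    """The four coefficient planes of one analysis level, all equal shape."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def energy(self) -> float:
        """Sum of squared coefficients over all four planes."""
        return float(
            sum(np.sum(np.square(p)) for p in (self.LL, self.LH, self.HL, self.HH))
        )


@dataclass(frozen=True)
class WaveletPyramid:
    """Multilevel decomposition: ``bands[k]`` is built from ``bands[k-1].LL``."""

    levels: int
    bands: tuple[SubBandSet, ...]
    approx: np.ndarray


def haar_step_2d(img: np.ndarray) -> SubBandSet:
    """One level of orthonormal 2D Haar analysis.

    Both dimensions must be even; each disjoint 2x2 block contributes one
    coefficient to each sub-band, so every plane is half the input's size.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise DimensionError(f"expected a 2D plane, got shape {img.shape}")
    h, w = img.shape
    if h % 2 or w % 2 or h == 0 or w == 0:
        raise DimensionError(f"dimensions must be even and nonzero, got {h}x{w}")
    a = img[0::2, 0::2]
    b = img[0::2, 1::2]
    c = img[1::2, 0::2]
    d = img[1::2, 1::2]
    return SubBandSet(
        LL=(a + b + c + d) / 2.0,
        LH=(a - b + c - d) / 2.0,
        HL=(a + b - c - d) / 2.0,
        HH=(a - b - c + d) / 2.0,
    )


def decompose(img: np.ndarray, levels: int) -> WaveletPyramid:
    """Multilevel Haar decomposition of a single plane.

    Level ``k`` re-decomposes level ``k-1``'s LL; ``approx`` is the final LL.
    Dimensions must be divisible by ``2**levels`` (no silent padding — the
    canonical 512x512 input reduces to 64x64 at level 3).
    """
    img = np.asarray(img, dtype=np.float64)
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if img.ndim != 2:
        raise DimensionError(f"expected a 2D plane, got shape {img.shape}")
    div = 2**levels
    if img.shape[0] % div or img.shape[1] % div:
        raise DimensionError(
            f"shape {img.shape} not divisible by 2^{levels} = {div} in both dimensions"
        )
    bands: list[SubBandSet] = []
    current = img
    for _ in range(levels):
        sb = haar_step_2d(current)
        bands.append(sb)
        current = sb.LL
    return WaveletPyramid(levels=levels, bands=tuple(bands), approx=current)


def decompose_rgb(img: np.ndarray, levels: int = 3) -> np.ndarray:
    """Channel-wise multilevel Haar approximation of an RGB image.

    Returns an ``(H/2^levels, W/2^levels, 3)`` float array rescaled to [0, 1]
    for network input: the orthonormal LL gain of ``2^levels`` and the 8-bit
    range are divided out. ``levels=0`` is an identity pass-through (only the
    [0, 1] rescale is applied).
    """
    img = validate_rgb(img)
    if levels < 0:
        raise ValueError(f"levels must be >= 0, got {levels}")
    if levels == 0:
        return np.asarray(img, dtype=np.float64) / 255.0
    channels = [decompose(img[..., c], levels).approx for c in range(3)]
    scale = (2.0**levels) * 255.0
    return np.stack(channels, axis=-1) / scale


def approx_to_png(approx: np.ndarray, path: str) -> None:
    """Export an approximation plane as an 8-bit PNG for visual inspection.

    Coefficients are affinely rescaled so min maps to 0 and max to 255 (a
    constant plane maps to mid-gray).
    """
    plane = np.asarray(approx, dtype=np.float64)
    lo, hi = float(plane.min()), float(plane.max())
    if hi > lo:
        scaled = (plane - lo) / (hi - lo) * 255.0
    else:
        scaled = np.full_like(plane, 127.0)
    save_gray(np.round(scaled), path)
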