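"""Preprocessing for 2D brain MR slices.

MR magnitude images are classically corrupted by impulsive (salt-and-pepper)
noise; a small median filter removes it while preserving tissue edges. The
pipeline works on 8-bit grayscale slices and converts them to 3-channel RGB
(by channel replication) before wavelet reduction, so the downstream network
always sees a fixed ``H x W x 3`` input.

Images are plain numpy arrays: grayscale is a 2D array, RGB an ``(H, W, 3)``
array, both with intensities in [0, 255].
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid 2D grayscale image; return it as an array.

    Raises ``ValueError`` if the array is not 2D with at least one pixel or
    has intensities outside [0, 255].
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ValueError("intensities must lie in [0, 255]")
    return img


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is an ``(H, W, 3)`` image with values in [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ValueError("intensities must lie in [0, 255]")
    return img


def add_salt_pepper(img: np.ndarray, density: float, seed: int) -> np.ndarray:
    """Corrupt a grayscale image with salt-and-pepper (impulse) noise.

    Exactly ``round(density * n_pixels)`` distinct pixels are replaced, half
    with 255 (salt) and half with 0 (pepper), rounding the split; all other
    pixels are untouched. Deterministic given ``seed``.

    Parameters
    ----------
    img : 2D array
        Clean grayscale image, intensities in [0, 255].
    density : float
        Fraction of pixels to corrupt, in [0, 1].
    seed : int
        Seed for the corruption pattern.
    """
    img = validate_gray(img)
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    out = img.copy()
    n = int(round(density * img.size))
    if n == 0:
        return out
    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(img.size, size=n, replace=False)
    n_salt = n // 2
    flat = out.reshape(-1)
    flat[flat_idx[:n_salt]] = 255
    flat[flat_idx[n_salt:]] = 0
    return out


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter a grayscale image with a ``window x window`` mask.

    Each output pixel is the median of its neighborhood; borders are handled
    by edge replication, so the output has the input's shape. A 3x3 mask is
    the standard choice for impulse noise — larger masks blur edges.
    """
    img = validate_gray(img)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    return ndimage.median_filter(img, size=window, mode="nearest")


def gray_to_rgb(img: np.ndarray) -> np.ndarray:
    """Convert grayscale to 3-channel RGB by replicating the intensity plane.

    Replication is information-preserving: every output channel equals the
    input, so ``out[..., 0] == out[..., 1] == out[..., 2] == img``.
    """
    img = validate_gray(img)
    return np.stack([img, img, img], axis=-1)
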