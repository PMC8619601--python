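"""Seeded synthetic brain-slice phantoms.

Stands in for a clinical T2-weighted axial MR dataset: each phantom is a
512x512 8-bit slice with an elliptical "brain" over a dark background,
smooth spatially-correlated tissue texture inside, optionally one bright
focal lesion (the abnormal class), and salt-and-pepper corruption. The
texture is white noise blurred at an anatomy-like scale, so a level-3
wavelet approximation retains the structure that separates the classes
while discarding pixel noise.

These phantoms emulate the statistical structure the pipeline exploits —
smooth tissue, a bright focal abnormality, impulse noise — not anatomy:
no skull, bias field, partial-volume effects or disease-specific lesion
morphology. A classifier that is perfect here has only been shown to
detect a bright disc on correlated texture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocess import add_salt_pepper


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters for one dataset of synthetic slices.

    Defaults mirror the target acquisition: 512x512 slices (divisible by
    2^3 for the level-3 transform), a brain ellipse filling most of the
    field of view, tissue texture correlated over ~12 px, a 30 px lesion
    radius (a few-cm focal lesion at this resolution), lesion contrast 80
    gray levels, 2% impulse noise, balanced classes.
    """

    size: int = 512
    brain_axes: tuple[float, float] = (0.42, 0.34)  # semi-axes, fraction of size
    tissue_mean: float = 120.0
    tissue_amplitude: float = 35.0
    tissue_smoothness: float = 12.0  # gaussian blur sigma, px
    lesion_radius: float = 30.0
    lesion_contrast: float = 80.0
    noise_density: float = 0.02
    abnormal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if not (0.0 < self.brain_axes[0] <= 0.5 and 0.0 < self.brain_axes[1] <= 0.5):
            raise ValueError("brain semi-axes must be fractions in (0, 0.5]")
        if not 0.0 <= self.noise_density <= 1.0:
            raise ValueError("noise_density must be in [0, 1]")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must be in [0, 1]")
        if self.lesion_radius >= min(self.brain_axes) * self.size:
            raise ValueError(
                f"lesion_radius {self.lesion_radius} does not fit inside brain "
                f"semi-axes {tuple(a * self.size for a in self.brain_axes)}"
            )


def _brain_mask(params: PhantomParams) -> np.ndarray:
    s = params.size
    yy, xx = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2.0
    ay = params.brain_axes[1] * s  # rows: the shorter axis by default
    ax = params.brain_axes[0] * s
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(params: PhantomParams, label: int, seed: int) -> np.ndarray:
    """Generate one synthetic slice; ``label`` 0 = normal, 1 = abnormal.

    Abnormal slices carry a single bright disc of ``lesion_radius`` at a
    uniformly random fully-in-brain location, offset by ``lesion_contrast``
    gray levels. Bit-identical for identical ``(params, label, seed)``.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 (normal) or 1 (abnormal), got {label}")
    params.__post_init__()  # re-validate in case of replace() misuse
    rng = np.random.default_rng(seed)
    s = params.size
    mask = _brain_mask(params)

    noise = rng.standard_normal((s, s))
    texture = ndimage.gaussian_filter(noise, sigma=params.tissue_smoothness)
    std = texture.std()
    if std > 0:
        texture *= params.tissue_amplitude / (3.0 * std)  # ~99.7% within amplitude
    img = np.zeros((s, s), dtype=np.float64)
    img[mask] = params.tissue_mean + texture[mask]

    # at zero contrast the abnormal branch is skipped entirely, so the
    # "abnormal" slice is bit-identical to its normal twin: the strongest
    # possible null for leak checks
    if label == 1 and params.lesion_contrast != 0:
        cy, cx = _lesion_center(params, rng)
        yy, xx = np.mgrid[0:s, 0:s]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.lesion_radius**2
        img[disc] += params.lesion_contrast

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if params.noise_density > 0:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        img = add_salt_pepper(img, params.noise_density, seed=noise_seed)
    return img


def _lesion_center(params: PhantomParams, rng: np.random.Generator) -> tuple[int, int]:
    """Rejection-sample a center whose whole disc lies inside the ellipse."""
    s = params.size
    cy0 = cx0 = (s - 1) / 2.0
    ay = params.brain_axes[1] * s - params.lesion_radius
    ax = params.brain_axes[0] * s - params.lesion_radius
    for _ in range(1000):
        y = rng.uniform(cy0 - ay, cy0 + ay)
        x = rng.uniform(cx0 - ax, cx0 + ax)
        if ((y - cy0) / ay) ** 2 + ((x - cx0) / ax) ** 2 <= 1.0:
            return int(round(y)), int(round(x))
    raise RuntimeError("failed to place lesion inside brain ellipse")


def plan_labels(n: int, abnormal_fraction: float, seed: int) -> np.ndarray:
    """Deterministically shuffled label vector: round(n*fraction) abnormal."""
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    n_abnormal = int(round(n * abnormal_fraction))
    labels = np.array([1] * n_abnormal + [0] * (n - n_abnormal), dtype=np.int64)
    np.random.default_rng(seed).shuffle(labels)
    return labels


def sample_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-sample seeds derived from the master seed, stable in the index."""
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [int(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,)).generate_state(1)[0] % (2**31 - 1))
         for i in range(n)],
        dtype=np.int64,
    )


def make_dataset(
    n: int, params: PhantomParams
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Generate a labeled phantom dataset.

    Returns ``(images, labels, seeds)``: ``round(n * abnormal_fraction)``
    abnormal slices and the remainder normal, deterministically shuffled;
    each slice generated from a per-sample seed derived from ``params.seed``
    so datasets are reproducible and extensible.
    """
    labels = plan_labels(n, params.abnormal_fraction, params.seed)
    seeds = sample_seeds(params.seed, n)
    images = [
        make_phantom(params, int(lab), int(sd)) for lab, sd in zip(labels, seeds)
    ]
    return images, labels, seeds


def with_contrast(params: PhantomParams, lesion_contrast: float) -> PhantomParams:
    """Convenience copy with a different lesion contrast (for ablations)."""
    return replace(params, lesion_contrast=lesion_contrast)
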