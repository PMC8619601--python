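"""PNG image and dataset-directory I/O.

A dataset on disk is a directory of 8-bit PNG slices plus a ``manifest.csv``
with columns ``filename,label,seed`` (label is ``normal`` or ``abnormal``).
The synthetic generator writes this layout and the loader consumes the same
layout for real data.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

LABEL_NAMES = {0: "normal", 1: "abnormal"}
LABEL_CODES = {"normal": 0, "abnormal": 1}

MANIFEST = "manifest.csv"


def load_gray(path: str) -> np.ndarray:
    """Read a PNG/JPEG as an 8-bit grayscale 2D array (RGB is converted)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_gray(img: np.ndarray, path: str) -> None:
    """Write a 2D array with values in [0, 255] as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_rgb(img: np.ndarray, path: str) -> None:
    """Write an (H, W, 3) array with values in [0, 255] as an 8-bit PNG."""
    arr = np.clip(np.asarray(img), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def write_dataset(
    out_dir: str,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    seeds: Sequence[int] | None = None,
) -> str:
    """Write slices as PNGs with a CSV manifest; returns the manifest path."""
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        name = f"slice_{i:05d}.png"
        save_gray(img, os.path.join(out_dir, name))
        rows.append(
            {
                "filename": name,
                "label": LABEL_NAMES[int(lab)],
                "seed": int(seeds[i]) if seeds is not None else -1,
            }
        )
    manifest = os.path.join(out_dir, MANIFEST)
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(data_dir: str) -> tuple[list[np.ndarray], np.ndarray]:
    """Load a manifest-described dataset directory.

    Returns (images, labels) with labels coded 0=normal, 1=abnormal.
    """
    manifest = os.path.join(data_dir, MANIFEST)
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"no {MANIFEST} in {data_dir}")
    table = pd.read_csv(manifest)
    images = [load_gray(os.path.join(data_dir, fn)) for fn in table["filename"]]
    labels = np.array([LABEL_CODES[str(lab)] for lab in table["label"]], dtype=np.int64)
    return images, labels
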