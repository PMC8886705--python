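"""Image preprocessing: intensity normalization, foreground cropping,
bilinear resizing, channel handling, and dataset readers/writers.

Raw clinical-style images vary widely in acquisition intensity; the
pipeline here brings each image to a coherent [0, 1] range (per-image
min-max normalization), optionally crops to the dominant foreground
object (thresholded largest connected component, as a stand-in for
contour-based extreme-point cropping), resizes to the network input
size, and triplicates single-channel data when a 3-channel input is
required.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImageRecord",
    "minmax_normalize",
    "crop_to_foreground",
    "resize",
    "triplicate_channels",
    "load_image",
    "load_image_dataset",
    "save_image_dataset",
    "save_packed_dataset",
    "load_packed_dataset",
]


@dataclass
class ImageRecord:
    """A single image with its task-dependent label and identifier."""

    pixels: np.ndarray
    label: object
    identifier: str = ""


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Rescale intensities to [0, 1]: y = (x - min(x)) / (max(x) - min(x)).

    Minimum and maximum are taken over the entire image.  A constant
    image (zero range) maps to all zeros.  Idempotent, and invariant to
    positive affine rescaling of the input.
    """
    x = np.asarray(image, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo = x.min()
    span = x.max() - lo
    if span == 0.0:
        return np.zeros_like(x)
    return (x - lo) / span


def crop_to_foreground(image: np.ndarray, threshold_fraction: float = 0.1) -> np.ndarray:
    """Tight bounding box of the largest bright connected component.

    The image is binarized at ``threshold_fraction`` of its maximum
    intensity; the largest 8-connected foreground component is located
    and its extreme points define the returned crop.  An image with no
    foreground is returned unchanged.  Single-channel 2-D input only.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError(f"threshold_fraction must lie in (0, 1), got {threshold_fraction}")
    x = np.asarray(image, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {x.shape}")
    mask = x >= threshold_fraction * x.max()
    if not mask.any():
        return x
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    else:
        mask = labels == 1
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return x[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _axis_coords(n_out: int, n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # half-pixel (center-aligned) sampling grid
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0.0, n_in - 1)
    i0 = np.floor(coords).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = coords - i0
    return i0, i1, frac


def resize(image: np.ndarray, target_height: int, target_width: int) -> np.ndarray:
    """Bilinear resize with half-pixel centers; identity when sizes match.

    Works on 2-D images or channels-last 3-D stacks.  Interpolation is
    separable: rows first, then columns, each output sample blending its
    two nearest input samples.
    """
    if target_height < 1 or target_width < 1:
        raise ValueError("target sizes must be positive")
    x = np.asarray(image, dtype=float)
    if x.ndim not in (2, 3):
        raise ValueError(f"expected 2-D or 3-D image, got shape {x.shape}")
    h, w = x.shape[:2]
    if (h, w) == (target_height, target_width):
        return x.copy()
    r0, r1, rf = _axis_coords(target_height, h)
    rf = rf.reshape(-1, *([1] * (x.ndim - 1)))
    rows = x[r0] * (1.0 - rf) + x[r1] * rf
    c0, c1, cf = _axis_coords(target_width, w)
    cf = cf.reshape(1, -1, *([1] * (x.ndim - 2)))
    return rows[:, c0] * (1.0 - cf) + rows[:, c1] * cf


def triplicate_channels(image: np.ndarray) -> np.ndarray:
    """Stack a single-channel image into three identical channels (h, w, 3)."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        if x.shape[2] != 1:
            raise ValueError(f"image already has {x.shape[2]} channels")
        x = x[:, :, 0]
    elif x.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {x.shape}")
    return np.repeat(x[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# readers / writers


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG (8/16-bit gray or RGB) as float in [0, 1]."""
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return arr


def load_image_dataset(directory, labels_csv) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Read an image directory plus a delimited label table.

    The table must have a ``filename`` column; remaining columns are the
    labels (one column for binary/multiclass, one 0/1 column per label
    for multilabel).  Rows are returned in table order.
    """
    table = pd.read_csv(labels_csv)
    if "filename" not in table.columns:
        raise ValueError("label table must contain a 'filename' column")
    images = [load_image(os.path.join(directory, fn)) for fn in table["filename"]]
    return images, table


def save_image_dataset(images, labels: pd.DataFrame, directory) -> None:
    """Write images as 8-bit PNGs plus a labels.csv index."""
    os.makedirs(directory, exist_ok=True)
    for fn, img in zip(labels["filename"], images):
        arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
        iio.imwrite(os.path.join(directory, fn), (arr * 255).round().astype(np.uint8))
    labels.to_csv(os.path.join(directory, "labels.csv"), index=False)


def save_packed_dataset(path, images: np.ndarray, labels: np.ndarray, task: str) -> None:
    """Single packed array file (``.npz``) holding images, labels and task."""
    np.savez_compressed(path, images=np.asarray(images), labels=np.asarray(labels), task=np.asarray(task))


def load_packed_dataset(path) -> tuple[np.ndarray, np.ndarray, str]:
    with np.load(path) as data:
        return data["images"], data["labels"], str(data["task"])
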