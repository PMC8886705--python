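"""Seeded synthetic image-classification tasks.

Generators for the three task families used throughout the package:

* multiclass — one elliptical "tumor-like" blob per image whose radius,
  eccentricity and intensity band are class-specific;
* multilabel — a fixed spatial pattern per finding, each independently
  present with its own prevalence, patterns superimposed additively;
* binary — lesion present vs. absent.

All generators are pure functions of a :class:`TaskSpec` (including its
seed): the same spec yields a bit-identical dataset.  Rendered
intensities lie in [0, 1] before noise and are clipped back to [0, 1]
after additive Gaussian pixel noise.  The families are deliberately
simple parametric renderings — controllable difficulty, known Bayes
structure — not simulations of real anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split as _sk_split

__all__ = [
    "TaskSpec",
    "SyntheticDataset",
    "make_multiclass_images",
    "make_multilabel_images",
    "make_binary_images",
    "make_dataset",
    "train_test_split",
    "compute_class_weights",
]


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of a synthetic classification task.

    ``class_proportions`` is a simplex vector over classes (binary /
    multiclass) or a per-label prevalence vector in (0, 1) (multilabel).
    ``noise_sd`` is the standard deviation of additive Gaussian pixel
    noise on the unit intensity scale.
    """

    task: str
    n_classes: int = 4
    image_size: int = 16
    n_samples: int = 400
    class_proportions: tuple | None = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.task == "binary":
            object.__setattr__(self, "n_classes", 2)
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes:
                raise ValueError("class_proportions length must equal n_classes")
            if self.task == "multilabel":
                if not ((p >= 0) & (p <= 1)).all():
                    raise ValueError("multilabel prevalences must lie in [0, 1]")
            else:
                if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError("class_proportions must be a simplex vector")
            object.__setattr__(self, "class_proportions", tuple(float(x) for x in p))


@dataclass
class SyntheticDataset:
    """Images (n, h, w) in [0, 1] plus labels and task metadata.

    Labels are integer class indices for binary/multiclass and an
    (n, n_labels) 0/1 bitmask for multilabel.
    """

    images: np.ndarray
    labels: np.ndarray
    task: str
    n_classes: int

    def __len__(self) -> int:
        return self.images.shape[0]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.arange(size, dtype=float)
    return np.meshgrid(c, c, indexing="ij")


def _render_ellipse(size, cy, cx, a, b, angle, intensity) -> np.ndarray:
    """Hard elliptical disc of the given intensity on a zero background."""
    yy, xx = _grid(size)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, intensity, 0.0)


def _class_blob_params(k: int, n_classes: int, size: int) -> dict:
    """Deterministic per-class shape family: radius, eccentricity, intensity."""
    frac = k / max(n_classes - 1, 1)
    return {
        "radius": size * (0.12 + 0.14 * frac),
        "eccentricity": 1.0 - 0.5 * frac,  # axis ratio b/a
        "intensity": 0.45 + 0.5 * frac,
    }


def _render_class_image(rng, size: int, k: int, n_classes: int, noise_sd: float) -> np.ndarray:
    par = _class_blob_params(k, n_classes, size)
    margin = par["radius"] + 1.0
    cy = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    cx = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    angle = rng.uniform(0.0, np.pi)
    a = par["radius"]
    b = max(par["radius"] * par["eccentricity"], 1.0)
    img = _render_ellipse(size, cy, cx, a, b, angle, par["intensity"])
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    return img


def make_multiclass_images(spec: TaskSpec) -> SyntheticDataset:
    """One class-specific blob per image; labels drawn per proportions."""
    if spec.task != "multiclass":
        raise ValueError("spec.task must be 'multiclass'")
    rng = np.random.default_rng(spec.seed)
    p = spec.class_proportions
    props = np.full(spec.n_classes, 1.0 / spec.n_classes) if p is None else np.asarray(p)
    labels = rng.choice(spec.n_classes, size=spec.n_samples, p=props)
    images = np.stack(
        [_render_class_image(rng, spec.image_size, int(k), spec.n_classes, spec.noise_sd) for k in labels]
    )
    return SyntheticDataset(images=images, labels=labels, task="multiclass", n_classes=spec.n_classes)


def _label_pattern(size: int, lab: int, n_labels: int) -> np.ndarray:
    """Fixed pattern for finding ``lab``: a blob on a ring around center."""
    angle = 2.0 * np.pi * lab / n_labels
    r = 0.30 * size
    cy = size / 2 + r * np.sin(angle)
    cx = size / 2 + r * np.cos(angle)
    rad = max(0.10 * size, 1.5)
    return _render_ellipse(size, cy, cx, rad, rad, 0.0, 0.8)


def make_multilabel_images(spec: TaskSpec) -> SyntheticDataset:
    """Independent findings: label l present with prevalence p_l."""
    if spec.task != "multilabel":
        raise ValueError("spec.task must be 'multilabel'")
    rng = np.random.default_rng(spec.seed)
    p = spec.class_proportions
    prev = np.full(spec.n_classes, 0.3) if p is None else np.asarray(p)
    bitmask = (rng.random((spec.n_samples, spec.n_classes)) < prev).astype(np.int8)
    patterns = np.stack([_label_pattern(spec.image_size, l, spec.n_classes) for l in range(spec.n_classes)])
    images = np.clip(np.tensordot(bitmask.astype(float), patterns, axes=(1, 0)), 0.0, 1.0)
    if spec.noise_sd > 0:
        images = np.clip(images + rng.normal(0.0, spec.noise_sd, images.shape), 0.0, 1.0)
    return SyntheticDataset(images=images, labels=bitmask, task="multilabel", n_classes=spec.n_classes)


def make_binary_images(spec: TaskSpec) -> SyntheticDataset:
    """Lesion (class 1) vs. clean background (class 0)."""
    if spec.task != "binary":
        raise ValueError("spec.task must be 'binary'")
    rng = np.random.default_rng(spec.seed)
    p = spec.class_proportions
    props = np.asarray(p) if p is not None else np.array([0.5, 0.5])
    labels = rng.choice(2, size=spec.n_samples, p=props)
    size = spec.image_size
    images = np.empty((spec.n_samples, size, size))
    for i, k in enumerate(labels):
        if k == 1:
            images[i] = _render_class_image(rng, size, 1, 2, 0.0)
        else:
            images[i] = np.zeros((size, size))
        if spec.noise_sd > 0:
            images[i] = np.clip(images[i] + rng.normal(0.0, spec.noise_sd, (size, size)), 0.0, 1.0)
    return SyntheticDataset(images=images, labels=labels, task="binary", n_classes=2)


def make_dataset(spec: TaskSpec) -> SyntheticDataset:
    """Dispatch on ``spec.task``."""
    return {
        "multiclass": make_multiclass_images,
        "multilabel": make_multilabel_images,
        "binary": make_binary_images,
    }[spec.task](spec)


def train_test_split(
    dataset: SyntheticDataset,
    test_fraction: float,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Disjoint, exhaustive, seeded partition; stratified by class when
    labels are single class indices (multilabel splits are plain random)."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    idx = np.arange(len(dataset))
    strat = dataset.labels if (stratify and dataset.task != "multilabel") else None
    train_idx, test_idx = _sk_split(
        idx, test_size=test_fraction, random_state=seed, stratify=strat
    )
    def subset(ids):
        return SyntheticDataset(
            images=dataset.images[ids],
            labels=dataset.labels[ids],
            task=dataset.task,
            n_classes=dataset.n_classes,
        )
    return subset(np.sort(train_idx)), subset(np.sort(test_idx))


def compute_class_weights(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights: w_c = n_total / (K * n_c).

    Balanced labels give all-ones; the weights are invariant to
    duplicating the dataset.  A class with zero examples is an error.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if labels.ndim == 2:  # multilabel bitmask: per-label positive frequency
        n = labels.shape[0]
        counts = labels.sum(axis=0).astype(float)
        if (counts == 0).any():
            raise ValueError("every label needs at least one positive example")
        return n / (labels.shape[1] * counts)
    k = int(n_classes) if n_classes is not None else int(labels.max()) + 1
    counts = np.bincount(labels.astype(int), minlength=k).astype(float)
    if (counts == 0).any():
        raise ValueError("every class needs at least one example")
    return labels.size / (k * counts)
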