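"""Seeded synthetic-data generators emulating the study inputs at desk scale.

The real benchmark is a balanced two-class set of 150 nucleus patches
(75 mitosis / 75 nonmitosis) that is not publicly deposited, so these
generators stand in for it:

* **patch images** — nonmitotic nuclei are drawn as one compact round blob
  (low eccentricity); mitotic figures as a darker, irregular dumbbell of two
  overlapping elongated blobs with chromatin-like speckle texture (high
  eccentricity).  Dark blobs on a light background, additive Gaussian noise.
* **image + mask pairs** — multi-blob images with the exact pre-noise blob
  mask, to exercise the segmentation stage end to end.
* **feature tables** — two unit-variance Gaussian classes separated by
  ``shift`` along the first coordinate, standing in for deep embeddings.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse

BACKGROUND = 0.85  # light (eosin-like) background intensity
NUCLEUS = 0.45  # plain nucleus intensity; mitotic chromatin is darker


@dataclass(frozen=True)
class PatchSpec:
    size: int = 64
    radius_range: tuple = (6.0, 11.0)
    round_ecc_range: tuple = (0.0, 0.3)  # nonmitosis: compact
    mitotic_ecc_range: tuple = (0.75, 0.95)  # mitosis: elongated lobes
    chromatin_factor: float = 0.55  # multiplies nucleus darkness toward black
    noise_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("patch size must be at least 16 pixels")
        for r in (self.radius_range, self.round_ecc_range, self.mitotic_ecc_range):
            if not (0 <= r[0] <= r[1]):
                raise ValueError("invalid range")
        if not 0 < self.chromatin_factor <= 1 or self.noise_sd < 0:
            raise ValueError("invalid spec")


def _ellipse_axes(radius: float, ecc: float) -> tuple:
    # keep area ~= pi r^2 while stretching to the requested eccentricity
    ratio = np.sqrt(1.0 - ecc**2)  # minor/major
    major = radius / np.sqrt(ratio)
    return major, major * ratio


def _draw_round_blob(mask, center, radius, ecc, angle, rng) -> None:
    a, b = _ellipse_axes(radius, ecc)
    rr, cc = ellipse(center[0], center[1], a, b, shape=mask.shape, rotation=angle)
    mask[rr, cc] = True


def _draw_mitotic_blob(mask, center, radius, ecc, angle, rng) -> None:
    # dumbbell: two elongated lobes straddling the center along one axis
    a, b = _ellipse_axes(radius * 0.8, ecc)
    off = radius * 0.7
    dy, dx = off * np.cos(angle), off * np.sin(angle)
    for s in (-1.0, 1.0):
        rr, cc = ellipse(center[0] + s * dy, center[1] + s * dx, a, b,
                         shape=mask.shape, rotation=angle + rng.normal(0, 0.2))
        mask[rr, cc] = True


def render_patch(label: int, spec: PatchSpec, rng: np.random.Generator):
    """One patch and its pre-noise blob mask; label 1 = mitosis."""
    size = spec.size
    mask = np.zeros((size, size), dtype=bool)
    center = (size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2))
    radius = rng.uniform(*spec.radius_range)
    angle = rng.uniform(0, np.pi)
    if label == 1:
        ecc = rng.uniform(*spec.mitotic_ecc_range)
        _draw_mitotic_blob(mask, center, radius, ecc, angle, rng)
        value = NUCLEUS * spec.chromatin_factor  # hyperchromatic: darker
    else:
        ecc = rng.uniform(*spec.round_ecc_range)
        _draw_round_blob(mask, center, radius, ecc, angle, rng)
        value = NUCLEUS
    img = np.full((size, size), BACKGROUND)
    img[mask] = value
    if label == 1:
        # chromatin speckle inside the mitotic figure
        texture = rng.uniform(-0.12, 0.12, size=mask.sum())
        img[mask] += texture
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def generate_patch_dataset(n_per_class: int, spec: PatchSpec = PatchSpec(),
                           seed: int = 0):
    """Balanced labeled patch images: (images, labels, masks)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, masks = [], [], []
    for label in (1, 0):
        for _ in range(n_per_class):
            img, mask = render_patch(label, spec, rng)
            images.append(img)
            labels.append(label)
            masks.append(mask)
    return np.stack(images), np.array(labels), np.stack(masks)


def generate_segmentation_pair(spec: PatchSpec = PatchSpec(), n_blobs: int = 3,
                               image_size: int = 192, seed: int = 0):
    """A larger image with n well-separated blobs and its exact blob mask."""
    rng = np.random.default_rng(seed)
    img = np.full((image_size, image_size), BACKGROUND)
    mask = np.zeros((image_size, image_size), dtype=bool)
    # place blobs on a coarse grid so components never merge
    cells = int(np.ceil(np.sqrt(n_blobs)))
    pitch = image_size / cells
    slots = [(r, c) for r in range(cells) for c in range(cells)]
    rng.shuffle(slots)
    for (r, c) in slots[:n_blobs]:
        cy = (r + 0.5) * pitch + rng.uniform(-pitch * 0.1, pitch * 0.1)
        cx = (c + 0.5) * pitch + rng.uniform(-pitch * 0.1, pitch * 0.1)
        radius = rng.uniform(*spec.radius_range)
        if radius <= 0:
            continue
        blob = np.zeros_like(mask)
        _draw_round_blob(blob, (cy, cx), radius,
                         rng.uniform(*spec.round_ecc_range), rng.uniform(0, np.pi), rng)
        mask |= blob
    img[mask] = NUCLEUS
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, size=img.shape), 0.0, 1.0)
    return img, mask


def probability_map(image: np.ndarray) -> np.ndarray:
    """Foreground probability of a dark-on-light image.

    Linear in inverted intensity, scaled so a plain nucleus maps to 1 and the
    clean background to 0; darker (hyperchromatic) pixels saturate at 1.
    """
    image = np.asarray(image, dtype=float)
    return np.clip((BACKGROUND - image) / (BACKGROUND - NUCLEUS), 0.0, 1.0)


def generate_feature_table(n_per_class: int, dim: int = 5, shift: float = 2.0,
                           seed: int = 0) -> pd.DataFrame:
    """Two unit-variance Gaussian classes, means ``shift`` apart on axis 0."""
    if dim < 1 or shift < 0 or n_per_class < 1:
        raise ValueError("invalid table parameters")
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, dim))
    X1 = rng.normal(0.0, 1.0, size=(n_per_class, dim))
    X1[:, 0] += shift
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(dim)])
    df["label"] = y
    return df


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    #: optional {class label: train count}; overrides the fraction when given
    train_counts: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0,1)")


def split_dataset(items, labels, split: SplitSpec):
    """(train_idx, test_idx); unstratified uniform split unless explicit
    per-class train counts are given."""
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(split.seed)
    if split.train_counts is not None:
        train = []
        for cls, count in split.train_counts.items():
            cls_idx = np.flatnonzero(labels == cls)
            if count > cls_idx.size:
                raise ValueError(f"requested {count} train items of class {cls}, "
                                 f"only {cls_idx.size} available")
            train.append(rng.permutation(cls_idx)[:count])
        train_idx = np.sort(np.concatenate(train))
    else:
        n_train = int(round(n * split.train_fraction))
        train_idx = np.sort(rng.permutation(n)[:n_train])
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return train_idx, test_idx
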