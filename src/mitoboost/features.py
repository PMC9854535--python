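"""Patch descriptors for candidate nuclei, plus an embedding-import hook.

``extract_descriptor`` is a deterministic handcrafted descriptor behind the
feature-extractor contract: a 16-bin normalized intensity histogram, the
first three intensity moments, the mean gradient magnitude, and two shape
statistics (foreground area fraction and eccentricity) of the dominant blob
after Otsu thresholding.  Nuclei are dark on a light background, so the
foreground is the below-threshold side.

``load_external_embeddings`` accepts user-supplied feature tables (e.g. deep
network embeddings) in CSV form so they can flow into the classifier and
tuner unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

N_HIST_BINS = 16

FEATURE_NAMES = tuple(
    [f"hist_{i}" for i in range(N_HIST_BINS)]
    + ["intensity_mean", "intensity_var", "intensity_skew",
       "gradient_mag_mean", "blob_area_fraction", "blob_eccentricity"]
)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple = FEATURE_NAMES


def _to_gray(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty image")
    if patch.ndim == 3:
        patch = patch.mean(axis=2)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D grayscale or H x W x C")
    return patch


def extract_descriptor(patch: np.ndarray) -> FeatureVector:
    gray = _to_gray(patch)
    lo, hi = float(gray.min()), float(gray.max())
    if hi > lo:
        hist, _ = np.histogram(gray, bins=N_HIST_BINS, range=(lo, hi))
    else:  # constant image: all mass in the first bin
        hist = np.zeros(N_HIST_BINS)
        hist[0] = gray.size
    hist = hist / gray.size

    mean = float(gray.mean())
    var = float(gray.var()) if hi > lo else 0.0
    skew = float(stats.skew(gray, axis=None)) if hi > lo else 0.0

    gy, gx = np.gradient(gray)
    grad_mean = float(np.hypot(gy, gx).mean())

    if hi > lo:
        thr = threshold_otsu(gray)
        fg = gray < thr  # nuclei are darker than background
    else:
        fg = np.zeros_like(gray, dtype=bool)
    area_fraction = float(fg.mean())
    eccentricity = 0.0
    if fg.any():
        regions = regionprops(cc_label(fg, connectivity=2))
        biggest = max(regions, key=lambda r: r.area)
        eccentricity = float(biggest.eccentricity)

    values = np.concatenate([hist, [mean, var, skew, grad_mean, area_fraction, eccentricity]])
    return FeatureVector(values=values)


def descriptor_table(patches, labels) -> pd.DataFrame:
    """Descriptor per patch, assembled into a classifier-ready table."""
    rows = [extract_descriptor(p).values for p in patches]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["label"] = np.asarray(labels, dtype=int)
    return df


def load_external_embeddings(path) -> pd.DataFrame:
    """Validated CSV feature table with a ``label`` column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen, dupes = set(), []
    for name in header:
        if name in seen:
            dupes.append(name)
        seen.add(name)
    if dupes:
        raise ValueError(f"duplicated header names: {sorted(set(dupes))}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature table: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError("feature table must contain a 'label' column")
    feats = df.drop(columns="label")
    non_numeric = [c for c in feats.columns
                   if not np.issubdtype(feats[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad = feats[c].map(lambda v: not isinstance(v, (int, float))).to_numpy().nonzero()[0]
            line = int(bad[0]) + 2 if bad.size else "?"  # +2: header + 1-based
            raise ValueError(f"non-numeric cell in column {c!r} near line {line}")
    if feats.isna().any().any():
        raise ValueError("feature table contains missing values")
    return df


def split_table(df: pd.DataFrame):
    """(X, y) view of a validated feature table."""
    y = df["label"].to_numpy(dtype=int)
    X = df.drop(columns="label").to_numpy(dtype=float)
    return X, y
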