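"""Forward operators of a pyramid pooling module (PPM) and multilevel decoder.

A PPM aggregates context at several spatial resolutions: the input feature
map is max-pooled down to each pyramid output size, passed through a 1x1
convolution, bilinearly resized back to the input size, and the resized maps
are concatenated with the untouched input before a final channel-reducing 1x1
convolution.  Attention gates modulate encoder maps with a sigmoid of summed
1x1 convolutions, and the multilevel decoder concatenates the (upsampled) PPM
output with each gated map.

All operators are forward-only with pluggable weights; feature maps are
H x W x C float arrays.  Bilinear resizing uses the align-corners convention
(endpoints map to endpoints).  Spatial sizes that a pooling stride does not
divide exactly are an error, never silently padded.

``extract_candidate_patches`` turns a segmentation probability map into
square candidate patches centered on connected foreground components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from skimage.measure import label as cc_label, regionprops


class IndivisibleSizeError(ValueError):
    """Pooling stride does not divide the spatial size; pad the input first."""


@dataclass(frozen=True)
class PPMConfig:
    #: pyramid output sizes produced by max pooling, ascending
    pooled_scales: tuple = (1, 2, 6)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.pooled_scales):
            raise ValueError("pyramid scales must be positive")
        if list(self.pooled_scales) != sorted(self.pooled_scales):
            raise ValueError("pyramid scales must be ascending")


@dataclass(frozen=True)
class ConvParams:
    """1x1 convolution: out = W.T applied per pixel, plus bias."""

    W: np.ndarray  # (C_in, C_out)
    b: np.ndarray  # (C_out,)


def _as_map(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim == 2:
        F = F[:, :, None]
    if F.ndim != 3:
        raise ValueError("feature map must be H x W x C")
    return F


def pool_stride(w: int, o: int) -> int:
    """Max-pooling stride taking spatial size w down to o: lambda = w / o."""
    if w < 1 or o < 1:
        raise ValueError("sizes must be positive integers")
    if w % o:
        raise IndivisibleSizeError(
            f"output size {o} does not divide input size {w}; pad the input")
    return w // o


def max_pool_downsample(F: np.ndarray, stride: int) -> np.ndarray:
    """Per-channel maxima over non-overlapping stride x stride windows."""
    F = _as_map(F)
    H, W, C = F.shape
    if H % stride or W % stride:
        raise IndivisibleSizeError(f"stride {stride} does not divide {H}x{W}")
    view = F.reshape(H // stride, stride, W // stride, stride, C)
    return view.max(axis=(1, 3))


def conv1x1(F: np.ndarray, params: ConvParams) -> np.ndarray:
    F = _as_map(F)
    W = np.atleast_2d(np.asarray(params.W, dtype=float))
    b = np.atleast_1d(np.asarray(params.b, dtype=float))
    if F.shape[2] != W.shape[0] or b.shape[0] != W.shape[1]:
        raise ValueError("1x1 convolution weight/bias shapes do not match the map")
    return F @ W + b


def bilinear_resize(F: np.ndarray, target: tuple) -> np.ndarray:
    """Per-channel bilinear interpolation, align-corners convention."""
    F = _as_map(F)
    H, W, _ = F.shape
    Ho, Wo = target
    if Ho < 1 or Wo < 1:
        raise ValueError("target size must be positive")

    def grid(n_in: int, n_out: int) -> np.ndarray:
        if n_out == 1 or n_in == 1:
            return np.zeros(n_out)
        return np.arange(n_out) * (n_in - 1) / (n_out - 1)

    ys, xs = grid(H, Ho), grid(W, Wo)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    tl = F[np.ix_(y0, x0)]
    tr = F[np.ix_(y0, x1)]
    bl = F[np.ix_(y1, x0)]
    br = F[np.ix_(y1, x1)]
    top = tl * (1 - fx) + tr * fx
    bot = bl * (1 - fx) + br * fx
    return top * (1 - fy) + bot * fy


def ppm_forward(F: np.ndarray, config: PPMConfig, conv_params: list,
                reduce_params: ConvParams) -> np.ndarray:
    """Pool -> 1x1 conv -> resize per scale, concat with input, reduce channels."""
    F = _as_map(F)
    H, W, _ = F.shape
    if len(conv_params) != len(config.pooled_scales):
        raise ValueError("one ConvParams per pooled scale required")
    branches = [F]
    for o, params in zip(config.pooled_scales, conv_params):
        lam_h = pool_stride(H, o)
        lam_w = pool_stride(W, o)
        if lam_h != lam_w:
            raise IndivisibleSizeError("non-square pooling is not supported")
        pooled = max_pool_downsample(F, lam_h)
        conved = conv1x1(pooled, params)
        branches.append(bilinear_resize(conved, (H, W)))
    stacked = np.concatenate(branches, axis=2)
    return conv1x1(stacked, reduce_params)


@dataclass(frozen=True)
class GateParams:
    x_conv: ConvParams
    g_conv: ConvParams


def attention_gate(x: np.ndarray, g: np.ndarray, params: GateParams) -> np.ndarray:
    """out = x * sigmoid(conv1x1(x) + conv1x1(g)); gate values in (0,1)."""
    x = _as_map(x)
    g = _as_map(g)
    if x.shape[:2] != g.shape[:2]:
        raise ValueError("encoder and gating maps must share spatial size")
    pre = conv1x1(x, params.x_conv) + conv1x1(g, params.g_conv)
    if pre.shape[2] not in (1, x.shape[2]):
        raise ValueError("gate channels must be 1 or match the encoder map")
    return x * expit(pre)


def multilevel_concat(ppm_output: np.ndarray, gated_maps: list) -> list:
    """Y_j = concat(upsample(PPM output to level-j size), gated map j)."""
    ppm_output = _as_map(ppm_output)
    outs = []
    for gm in gated_maps:
        gm = _as_map(gm)
        up = bilinear_resize(ppm_output, gm.shape[:2])
        outs.append(np.concatenate([up, gm], axis=2))
    return outs


@dataclass(frozen=True)
class CandidatePatch:
    x: int  # top-left column of the square patch
    y: int  # top-left row
    width: int
    height: int
    area: int
    centroid: tuple


def extract_candidate_patches(prob_map: np.ndarray, threshold: float = 0.5,
                              min_area: int = 1, patch_size: int = 64,
                              margin: int = 0) -> list:
    """Candidate nucleus patches from a segmentation probability map.

    Binarizes at ``threshold``, labels 8-connected components, drops those
    smaller than ``min_area`` pixels, and emits one square ``patch_size``
    window centered on each surviving component centroid, clamped to the
    image (``margin`` shrinks the allowed placement area).
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 2:
        raise ValueError("probability map must be 2-D")
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0,1]")
    mask = prob_map > threshold
    labeled = cc_label(mask, connectivity=2)
    H, W = prob_map.shape
    out = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        y = int(round(cy)) - patch_size // 2
        x = int(round(cx)) - patch_size // 2
        y = min(max(y, margin), max(H - patch_size - margin, 0))
        x = min(max(x, margin), max(W - patch_size - margin, 0))
        out.append(CandidatePatch(x=x, y=y,
                                  width=min(patch_size, W), height=min(patch_size, H),
                                  area=int(region.area), centroid=(cy, cx)))
    return out


def crop_patch(image: np.ndarray, patch: CandidatePatch) -> np.ndarray:
    return np.asarray(image)[patch.y:patch.y + patch.height,
                             patch.x:patch.x + patch.width]
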