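"""Grad-CAM++ activation maps, binarized food-area masks and mask unions.

Grad-CAM++ weights each channel of the last convolutional layer by combining
first-, second- and third-order gradient terms of a class logit, keeping only
positive pixel gradients, and ReLUs the weighted channel sum.  Maps are
bilinearly upsampled to the input resolution so they align with ground-truth
object masks.  Binarization min-max normalizes a map to [0, 1] and keeps
pixels strictly above the threshold T1 (default 0.5); a constant map
binarizes to all zeros.  All of this is detached from the training graph —
CAM masks act as constants within an iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image

from ._nn import bilinear_resize_matrix

__all__ = [
    "ActivationMap",
    "BinaryFoodMask",
    "gradcampp_from_grads",
    "gradcampp_map",
    "binarize_cam",
    "union_masks",
    "save_cam_overlay",
]

DEFAULT_T1 = 0.5


@dataclass
class ActivationMap:
    """Nonnegative class activation map at input resolution."""

    values: np.ndarray
    label: int
    image_index: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation map contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("activation map must be nonnegative")


@dataclass
class BinaryFoodMask:
    """Thresholded food-area mask, values in {0, 1}."""

    mask: np.ndarray
    label: int = -1

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = self.mask.astype(np.uint8)


@lru_cache(maxsize=32)
def _resize_ops(src: tuple[int, int], dst: tuple[int, int]):
    return (bilinear_resize_matrix(src[0], dst[0]),
            bilinear_resize_matrix(src[1], dst[1]))


def _upsample(values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    if values.shape == tuple(out_shape):
        return values
    ph, pw = _resize_ops(values.shape, tuple(out_shape))
    return ph @ values @ pw.T


def gradcampp_from_grads(activations: np.ndarray, grads: np.ndarray,
                         out_shape: tuple[int, int]) -> np.ndarray:
    """Grad-CAM++ from last-conv activations and d(logit)/d(activations).

    Channel weights: w_k = sum_xy alpha_k(x,y) * relu(g_k(x,y)) with
    alpha = g^2 / (2 g^2 + S_k g^3), S_k the spatial sum of channel k
    (positions where the denominator vanishes contribute nothing).  The map
    is relu(sum_k w_k A_k) bilinearly upsampled to ``out_shape``.
    """
    a = activations.astype(np.float64)
    g = grads.astype(np.float64)
    s = a.sum(axis=(1, 2), keepdims=True)
    denom = 2.0 * g ** 2 + s * g ** 3
    alpha = np.divide(g ** 2, denom, out=np.zeros_like(g), where=denom != 0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    return _upsample(cam, out_shape)


def gradcampp_map(model, image: np.ndarray, target_label: int,
                  image_index: int = 0) -> ActivationMap:
    """Grad-CAM++ map for one image and one target class.

    ``model`` must expose ``forward_backbone`` (retaining last-conv
    activations) and ``conv_logit_grad`` giving d(target logit)/d(activations)
    — the backprop stops at the last conv layer, so nothing here feeds back
    into training.  ``image`` is a preprocessed (3, H, W) array or a raw
    (H, W, 3) uint8 image.
    """
    from .model_core import preprocess_images

    if image.ndim == 3 and image.shape[-1] == 3 and image.dtype == np.uint8:
        x = preprocess_images(image)
    else:
        x = image[None] if image.ndim == 3 else image
    out = model.forward_backbone(x)
    act = out.conv_activations[0]
    grads = model.conv_logit_grad(act.shape, target_label)
    if not np.any(grads):
        warnings.warn(
            f"target logit for label {target_label} has zero gradient "
            "everywhere; returning an all-zero map", stacklevel=2)
        return ActivationMap(np.zeros(x.shape[2:]), target_label, image_index)
    cam = gradcampp_from_grads(act, grads, x.shape[2:])
    return ActivationMap(cam, target_label, image_index)


def binarize_cam(cam: ActivationMap, t1: float = DEFAULT_T1) -> BinaryFoodMask:
    """Min-max normalize to [0,1], keep values strictly greater than t1.

    A constant map (max == min) carries no localization signal and yields an
    all-zero mask.  Ties at exactly t1 go to 0 (strict inequality).
    """
    if not 0.0 < t1 < 1.0:
        raise ValueError("t1 must lie in (0, 1)")
    v = np.asarray(cam.values, dtype=np.float64)
    if np.isnan(v).any():
        raise ValueError("activation map contains NaN")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return BinaryFoodMask(np.zeros(v.shape, dtype=np.uint8), cam.label)
    norm = (v - lo) / (hi - lo)
    return BinaryFoodMask((norm > t1).astype(np.uint8), cam.label)


def union_masks(masks: list[BinaryFoodMask | np.ndarray],
                shape: tuple[int, int] | None = None) -> BinaryFoodMask:
    """Elementwise OR over masks; an empty list gives an all-zero mask of
    ``shape`` (which is then required)."""
    arrays = [m.mask if isinstance(m, BinaryFoodMask) else np.asarray(m)
              for m in masks]
    if not arrays:
        if shape is None:
            raise ValueError("shape is required to union an empty mask list")
        return BinaryFoodMask(np.zeros(shape, dtype=np.uint8))
    out = arrays[0].astype(bool)
    for m in arrays[1:]:
        if m.shape != out.shape:
            raise ValueError("masks must share one grid shape")
        out = out | m.astype(bool)
    return BinaryFoodMask(out.astype(np.uint8))


def save_cam_overlay(image: np.ndarray, cam: ActivationMap, path) -> None:
    """Debug dump: blend the (normalized) CAM as red heat over the image."""
    v = cam.values
    rng_ = v.max() - v.min()
    heat = (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)
    base = image.astype(np.float64)
    over = base.copy()
    over[..., 0] = np.clip(base[..., 0] * (1 - 0.6 * heat) + 255 * 0.6 * heat, 0, 255)
    over[..., 1] = base[..., 1] * (1 - 0.6 * heat)
    over[..., 2] = base[..., 2] * (1 - 0.6 * heat)
    Image.fromarray(over.astype(np.uint8)).save(path)
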