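"""CAM-driven MixUp: per-ingredient refinement of the scalar attention weight.

The core idea: when two images are mixed, an ingredient that lands on the
other image's *background* stays recognizable, while one landing on the other
image's *food* does not.  Each positive label n of image i therefore gets an
overlap ratio

    r_in = sum(CAM_in & union(CAM_j)) / sum(CAM_in)

measured between binarized activation maps, and its label weight is boosted
away from the scalar mixing weight a toward 1 in proportion to how much of
it sits over background:

    a_il = a + (1 - a) * (1 - r_in) * T2
    a_ir = (1 - a) + a * (1 - r_jm) * T2

Features are always mixed with the unrefined scalar a; only the soft labels
use the per-ingredient weights.  With T2 = 0 everything reduces exactly to
plain scalar MixUp of features and labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cam_localization import (ActivationMap, BinaryFoodMask, binarize_cam,
                               gradcampp_from_grads, union_masks)

__all__ = [
    "OverlapRatios",
    "RefinedWeights",
    "MixedSample",
    "overlap_ratio",
    "refine_weights",
    "mix_features",
    "mix_labels",
    "afm_mix_labels",
    "image_label_masks",
    "build_mix_batch",
]

DEFAULT_T2 = 0.8


@dataclass
class OverlapRatios:
    """Per-positive-label overlap ratios for both members of a pair."""

    r_i: np.ndarray
    r_j: np.ndarray

    def __post_init__(self):
        for r in (self.r_i, self.r_j):
            if ((np.asarray(r) < 0) | (np.asarray(r) > 1)).any():
                raise ValueError("overlap ratios must lie in [0, 1]")


@dataclass
class RefinedWeights:
    """Per-label mixing weights for the two members, plus the threshold used.

    ``a_il``/``a_ir`` align with the positive labels of image i / image j.
    """

    a_il: np.ndarray
    a_ir: np.ndarray
    t2: float


@dataclass
class MixedSample:
    """A virtual sample: mixed feature vector and per-class soft labels."""

    feature: np.ndarray
    soft_labels: np.ndarray
    index_i: int = -1
    index_j: int = -1
    a_i: float = np.nan


def overlap_ratio(mask_n: BinaryFoodMask | np.ndarray,
                  other_union: BinaryFoodMask | np.ndarray) -> float:
    """Fraction of mask_n's area covered by the other image's food union.

    An empty ``mask_n`` (localization failed for that ingredient) returns 1.0
    — the conservative choice: no weight boost when we cannot tell where the
    ingredient is.
    """
    m = mask_n.mask if isinstance(mask_n, BinaryFoodMask) else np.asarray(mask_n)
    u = other_union.mask if isinstance(other_union, BinaryFoodMask) else np.asarray(other_union)
    if m.shape != u.shape:
        raise ValueError(f"mask shapes differ: {m.shape} vs {u.shape}")
    area = float(np.count_nonzero(m))
    if area == 0.0:
        return 1.0
    return float(np.count_nonzero(m.astype(bool) & u.astype(bool))) / area


def refine_weights(a_i: float, r_i: np.ndarray, r_j: np.ndarray,
                   t2: float) -> RefinedWeights:
    """Per-ingredient weights a_il = a + (1-a)(1-r)T2, a_ir = (1-a) + a(1-r)T2."""
    if not 0.0 <= a_i <= 1.0:
        raise ValueError("a_i must lie in [0, 1]")
    if not 0.0 <= t2 <= 1.0:
        raise ValueError("t2 must lie in [0, 1]")
    r_i = np.asarray(r_i, dtype=np.float64)
    r_j = np.asarray(r_j, dtype=np.float64)
    if ((r_i < 0) | (r_i > 1)).any() or ((r_j < 0) | (r_j > 1)).any():
        raise ValueError("overlap ratios must lie in [0, 1]")
    a = float(a_i)
    a_il = a + (1.0 - a) * (1.0 - r_i) * t2
    a_ir = (1.0 - a) + a * (1.0 - r_j) * t2
    return RefinedWeights(a_il=a_il, a_ir=a_ir, t2=t2)


def mix_features(x_i: np.ndarray, x_j: np.ndarray, a_i: float) -> np.ndarray:
    """Scalar convex combination a * x_i + (1 - a) * x_j (the unrefined a)."""
    x_i = np.asarray(x_i)
    x_j = np.asarray(x_j)
    if x_i.shape != x_j.shape:
        raise ValueError("feature shapes differ")
    a = x_i.dtype.type(a_i) if np.issubdtype(x_i.dtype, np.floating) else a_i
    return a * x_i + (1 - a) * x_j


def _expand(weights: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Scatter per-positive-label weights to the full class dimension
    (zeros at the image's negative classes, where the target is 0 anyway)."""
    full = np.zeros(labels.shape, dtype=np.float64)
    full[np.flatnonzero(labels)] = weights
    return full


def mix_labels(y_i: np.ndarray, y_j: np.ndarray,
               weights: RefinedWeights) -> np.ndarray:
    """Soft labels y_c = a_il,c * y_i,c + a_ir,c * y_j,c, clamped to [0, 1].

    The clamp only matters for classes positive in both parents, where the
    two boosted weights can sum above 1; clamping keeps the targets valid
    Bernoulli probabilities.
    """
    y_i = np.asarray(y_i, dtype=np.float64)
    y_j = np.asarray(y_j, dtype=np.float64)
    if y_i.shape != y_j.shape:
        raise ValueError("label vectors differ in length")
    w_il = _expand(np.asarray(weights.a_il, dtype=np.float64), y_i)
    w_ir = _expand(np.asarray(weights.a_ir, dtype=np.float64), y_j)
    soft = w_il * y_i + w_ir * y_j
    return np.minimum(soft, 1.0)


def afm_mix_labels(y_i: np.ndarray, y_j: np.ndarray, a_i: float) -> np.ndarray:
    """Plain scalar MixUp of labels, y = a * y_i + (1 - a) * y_j.

    Routed through the same arithmetic as :func:`mix_labels` with all
    per-label weights equal to a / (1 - a), which is what T2 = 0 produces —
    so the CAM-driven path reduces to this bit for bit.
    """
    y_i = np.asarray(y_i, dtype=np.float64)
    n_i, n_j = int(np.count_nonzero(y_i)), int(np.count_nonzero(y_j))
    w = RefinedWeights(a_il=np.full(n_i, float(a_i)),
                       a_ir=np.full(n_j, 1.0 - float(a_i)), t2=0.0)
    return mix_labels(y_i, y_j, w)


def image_label_masks(model, conv_activations: np.ndarray, labels: np.ndarray,
                      out_shape: tuple[int, int],
                      t1: float) -> dict[int, BinaryFoodMask]:
    """Binarized Grad-CAM++ masks for every positive label of one image."""
    masks: dict[int, BinaryFoodMask] = {}
    for label in np.flatnonzero(labels):
        grads = model.conv_logit_grad(conv_activations.shape, int(label))
        cam = gradcampp_from_grads(conv_activations, grads, out_shape)
        masks[int(label)] = binarize_cam(
            ActivationMap(cam, int(label)), t1=t1)
    return masks


def pair_soft_labels(y_i: np.ndarray, y_j: np.ndarray, a: float,
                     masks_i: dict[int, BinaryFoodMask],
                     masks_j: dict[int, BinaryFoodMask],
                     grid_shape: tuple[int, int],
                     t2: float) -> tuple[np.ndarray, RefinedWeights, OverlapRatios]:
    """Overlap ratios -> refined weights -> soft labels for one pair."""
    union_i = union_masks(list(masks_i.values()), shape=grid_shape)
    union_j = union_masks(list(masks_j.values()), shape=grid_shape)
    r_i = np.array([overlap_ratio(masks_i[c], union_j)
                    for c in np.flatnonzero(y_i)], dtype=np.float64)
    r_j = np.array([overlap_ratio(masks_j[c], union_i)
                    for c in np.flatnonzero(y_j)], dtype=np.float64)
    ratios = OverlapRatios(r_i=r_i, r_j=r_j)
    weights = refine_weights(a, r_i, r_j, t2)
    return mix_labels(y_i, y_j, weights), weights, ratios


def build_mix_batch(images: np.ndarray, labels: np.ndarray, model,
                    t1: float = 0.5, t2: float = DEFAULT_T2,
                    num_groups: int | None = None,
                    seed: int = 0) -> list[MixedSample]:
    """Full mixing pipeline on a batch of raw uint8 images.

    GA pairing -> per-label Grad-CAM++ masks for both members -> unions ->
    overlap ratios -> refined weights -> mixed features (unrefined scalar a)
    and soft labels.  CAM masks are computed per image once and shared by
    every pair the image joins.
    """
    from .model_core import preprocess_images

    if len(images) < 2:
        raise ValueError("need a batch of at least 2 samples to form groups")
    x = preprocess_images(images)
    out = model.forward_backbone(x)
    rng = np.random.default_rng(seed)
    pairs = model.ga.sample_pairs(len(images), num_groups=num_groups, rng=rng)
    a_vec = model.ga.forward(out.features, pairs)
    grid = x.shape[2:]

    masks_cache: dict[int, dict[int, BinaryFoodMask]] = {}

    def masks_for(idx: int):
        if idx not in masks_cache:
            masks_cache[idx] = image_label_masks(
                model, out.conv_activations[idx], labels[idx], grid, t1)
        return masks_cache[idx]

    mixed = []
    for (i, j), a in zip(pairs, a_vec):
        soft, _, _ = pair_soft_labels(labels[i], labels[j], float(a),
                                      masks_for(i), masks_for(j), grid, t2)
        feat = mix_features(out.features[i], out.features[j], float(a))
        mixed.append(MixedSample(feature=feat, soft_labels=soft,
                                 index_i=i, index_j=j, a_i=float(a)))
    return mixed
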