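"""Synthetic multi-label "ingredient" scenes with ground-truth masks.

Each scene is a near-uniform tray-like background carrying one or more flat
colored shapes.  Every ingredient class has a fixed (shape, color) identity
with mild per-instance jitter, so a small CNN can learn the vocabulary in
minutes while the pixel-accurate masks let CAM-based localization be scored
against ground truth.  A controllable noise process corrupts the label lists
the way annotation errors would (substituting, dropping or adding labels)
while keeping the clean labels around for memorization analyses, and a small
perturbation suite (rotations and color adjustments) produces the shifted
test variants used in robustness sweeps.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "SceneSpec",
    "LabeledScene",
    "NoiseSpec",
    "generate_dataset",
    "inject_label_noise",
    "perturb_image",
    "PERTURBATION_GRID",
    "write_dataset",
]

# shape identities cycled over class IDs; polygons are orientation-bearing on
# purpose so that rotation perturbations genuinely shift the test distribution
_SHAPES = ("disk", "square", "triangle", "ellipse", "bar", "diamond", "cross", "ring")

_COLORS = (
    (220, 40, 40), (40, 170, 60), (50, 90, 220), (235, 200, 40),
    (160, 60, 200), (240, 130, 30), (40, 200, 200), (230, 90, 160),
    (120, 80, 30), (100, 220, 120), (90, 110, 140), (250, 240, 200),
)

# The perturbation grid used for robustness evaluation: four rotations plus
# brightness/saturation/hue/gamma adjustments.
PERTURBATION_GRID: tuple[tuple[str, float], ...] = (
    ("rotation", 45), ("rotation", 135), ("rotation", 225), ("rotation", 315),
    ("brightness", 0.9), ("saturation", 0.9), ("hue", 0.1), ("gamma", 0.9),
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the scene generator.

    ``objects_per_image`` is an inclusive (min, max) range; each class appears
    at most once per scene, so ``max`` may not exceed ``num_classes``.
    """

    image_size: int = 64
    num_classes: int = 6
    objects_per_image: tuple[int, int] = (1, 3)
    background_color: tuple[int, int, int] = (200, 200, 200)
    overlap_policy: str = "disjoint"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.objects_per_image
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if lo < 1 or hi > self.num_classes or lo > hi:
            raise ValueError("objects_per_image range must satisfy "
                             "1 <= min <= max <= num_classes")
        if self.overlap_policy not in ("disjoint", "allow-overlap"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


@dataclass
class LabeledScene:
    """An RGB image with its multi-hot labels and per-label object masks.

    ``labels`` is the (possibly noise-corrupted) training annotation;
    ``clean_labels`` the ground truth retained through noise injection.
    Masks are keyed by class ID and always describe the rendered (clean)
    objects.
    """

    image: np.ndarray                       # (H, W, 3) uint8
    labels: np.ndarray                      # (C,) {0,1}
    clean_labels: np.ndarray                # (C,) {0,1}
    masks: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def positive_labels(self) -> list[int]:
        return [int(c) for c in np.flatnonzero(self.labels)]


@dataclass(frozen=True)
class NoiseSpec:
    rate: float = 0.2
    mode: str = "substitute"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("noise rate must be in [0, 1]")
        if self.mode not in ("substitute", "drop", "add"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


def class_style(label: int) -> tuple[str, tuple[int, int, int]]:
    """Fixed (shape, base color) identity of a class."""
    return _SHAPES[label % len(_SHAPES)], _COLORS[label % len(_COLORS)]


def _shape_mask(shape: str, size: int, radius: float, cy: float, cx: float,
                angle: float) -> np.ndarray:
    """Rasterize one shape as a boolean mask on a size x size grid."""
    m = np.zeros((size, size), dtype=bool)
    if shape == "disk":
        rr, cc = skdraw.disk((cy, cx), radius, shape=m.shape)
        m[rr, cc] = True
    elif shape == "ellipse":
        rr, cc = skdraw.ellipse(cy, cx, radius, 0.6 * radius,
                                shape=m.shape, rotation=angle)
        m[rr, cc] = True
    elif shape == "ring":
        rr, cc = skdraw.disk((cy, cx), radius, shape=m.shape)
        m[rr, cc] = True
        rr, cc = skdraw.disk((cy, cx), 0.5 * radius, shape=m.shape)
        m[rr, cc] = False
    else:
        if shape == "square":
            base = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]]) * radius * 0.78
        elif shape == "triangle":
            th = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
            base = np.stack([np.sin(th), np.cos(th)], axis=1) * radius
        elif shape == "bar":
            base = np.array([[0.45, 1.2], [0.45, -1.2], [-0.45, -1.2], [-0.45, 1.2]]) * radius
        elif shape == "diamond":
            base = np.array([[1.15, 0], [0, 0.62], [-1.15, 0], [0, -0.62]]) * radius
        elif shape == "cross":
            a, b = 0.38 * radius, 1.05 * radius
            base = np.array([
                [a, a], [a, b], [-a, b], [-a, a], [-b, a], [-b, -a],
                [-a, -a], [-a, -b], [a, -b], [a, -a], [b, -a], [b, a]])
        else:  # pragma: no cover - guarded by _SHAPES
            raise ValueError(f"unknown shape {shape!r}")
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        pts = base @ rot.T + np.array([cy, cx])
        rr, cc = skdraw.polygon(pts[:, 0], pts[:, 1], shape=m.shape)
        m[rr, cc] = True
    return m


def _render_scene(spec: SceneSpec, rng: np.random.Generator,
                  scene_index: int, max_tries: int = 200) -> LabeledScene:
    size = spec.image_size
    img = np.empty((size, size, 3), dtype=np.float32)
    img[...] = np.asarray(spec.background_color, dtype=np.float32)
    img += rng.normal(0.0, 2.0, size=img.shape).astype(np.float32)

    lo, hi = spec.objects_per_image
    n_obj = int(rng.integers(lo, hi + 1))
    classes = rng.choice(spec.num_classes, size=n_obj, replace=False)

    occupied = np.zeros((size, size), dtype=bool)
    masks: dict[int, np.ndarray] = {}
    for label in classes:
        shape, color = class_style(int(label))
        placed = False
        for _ in range(max_tries):
            radius = size * rng.uniform(0.11, 0.17)
            cy = rng.uniform(radius + 2, size - radius - 2)
            cx = rng.uniform(radius + 2, size - radius - 2)
            angle = rng.uniform(-0.18, 0.18)  # mild orientation jitter (rad)
            m = _shape_mask(shape, size, radius, cy, cx, angle)
            if not m.any():
                continue
            if spec.overlap_policy == "disjoint" and (m & occupied).any():
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place object of class {int(label)} in scene "
                f"{scene_index} under the {spec.overlap_policy!r} policy "
                f"after {max_tries} tries")
        occupied |= m
        jitter = rng.normal(0.0, 8.0, size=3)
        col = np.clip(np.asarray(color, dtype=np.float32) + jitter, 0, 255)
        img[m] = col
        masks[int(label)] = m

    labels = np.zeros(spec.num_classes, dtype=np.int8)
    labels[list(masks)] = 1
    return LabeledScene(
        image=np.clip(img, 0, 255).astype(np.uint8),
        labels=labels,
        clean_labels=labels.copy(),
        masks=masks,
    )


def generate_dataset(spec: SceneSpec, n: int) -> list[LabeledScene]:
    """Render ``n`` scenes deterministically from ``spec.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return [_render_scene(spec, rng, i) for i in range(n)]


def inject_label_noise(scenes: list[LabeledScene],
                       noise: NoiseSpec) -> list[LabeledScene]:
    """Corrupt exactly ``round(rate * total positive instances)`` labels.

    Instances are pooled over the whole set and sampled without replacement
    (noise is applied per label instance, not per image).  ``substitute``
    swaps a positive label for a uniformly drawn absent class; ``drop``
    removes it (unless it is the image's last positive); ``add`` turns the
    drawn instance's image into a carrier of one extra uniformly drawn absent
    class.  ``clean_labels`` and masks are never touched.
    """
    if not scenes:
        raise ValueError("scenes must be nonempty")
    num_classes = len(scenes[0].labels)
    if noise.mode == "substitute" and num_classes < 2:
        raise ValueError("substitute mode needs at least 2 classes")

    out = [LabeledScene(image=s.image, labels=s.labels.copy(),
                        clean_labels=s.clean_labels.copy(), masks=s.masks)
           for s in scenes]

    pool = [(i, int(c)) for i, s in enumerate(out)
            for c in np.flatnonzero(s.labels)]
    k = int(round(noise.rate * len(pool)))
    if k == 0:
        return out

    rng = np.random.default_rng(noise.seed)
    order = rng.permutation(len(pool))
    altered = 0
    for idx in order:
        if altered >= k:
            break
        i, c = pool[idx]
        labels = out[i].labels
        if noise.mode == "substitute":
            # draw among classes absent from both the current and the clean
            # annotation: substituting toward a truly present class would not
            # corrupt anything, and this keeps the labels-vs-clean_labels diff
            # an exact count of altered instances
            absent = np.flatnonzero((labels == 0) & (out[i].clean_labels == 0))
            if absent.size == 0:
                warnings.warn(
                    f"image {i} carries every class; skipping one substitution "
                    "draw and sampling another instance", stacklevel=2)
                continue
            new = int(rng.choice(absent))
            labels[c] = 0
            labels[new] = 1
        elif noise.mode == "drop":
            if labels.sum() <= 1:
                warnings.warn(
                    f"image {i} has a single label; skipping drop to keep at "
                    "least one positive", stacklevel=2)
                continue
            labels[c] = 0
        else:  # add
            absent = np.flatnonzero(labels == 0)
            if absent.size == 0:
                warnings.warn(
                    f"image {i} carries every class; cannot add", stacklevel=2)
                continue
            labels[int(rng.choice(absent))] = 1
        altered += 1
    return out


def _as_float(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float32)


def perturb_image(image: np.ndarray, kind: str, magnitude: float) -> np.ndarray:
    """Apply one test-time perturbation; spatial size and uint8 range preserved.

    Rotation spins about the image center with reflect padding (no reshape);
    brightness/saturation multiply, hue shifts additively on the [0,1) hue
    circle, and gamma maps normalized intensity v to v**(1/magnitude).
    """
    img = _as_float(image)
    if kind == "rotation":
        out = ndimage.rotate(img, magnitude, axes=(1, 0), reshape=False,
                             mode="reflect", order=1)
    elif kind == "brightness":
        out = img * magnitude
    elif kind == "saturation":
        hsv = rgb2hsv(img / 255.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * magnitude, 0, 1)
        out = hsv2rgb(hsv) * 255.0
    elif kind == "hue":
        hsv = rgb2hsv(img / 255.0)
        hsv[..., 0] = np.mod(hsv[..., 0] + magnitude, 1.0)
        out = hsv2rgb(hsv) * 255.0
    elif kind == "gamma":
        out = np.power(np.clip(img / 255.0, 0, 1), 1.0 / magnitude) * 255.0
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return np.clip(out, 0, 255).astype(np.uint8)


def write_dataset(scenes: list[LabeledScene], out_dir: str | Path,
                  class_names: list[str] | None = None,
                  write_masks: bool = True) -> Path:
    """Write PNG images, CSV + JSON annotations, masks and labels.txt.

    CSV rows are ``image_path,label_ids`` with ``;``-separated 0-based IDs;
    paths are relative to the annotation file's directory.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    num_classes = len(scenes[0].labels)
    if class_names is None:
        class_names = [f"ingredient_{c:02d}" for c in range(num_classes)]
    if len(class_names) != num_classes:
        raise ValueError("class_names length must match the label dimension")

    rows = []
    for i, s in enumerate(scenes):
        rel = f"images/scene_{i:05d}.png"
        Image.fromarray(s.image).save(out_dir / rel)
        ids = ";".join(str(c) for c in s.positive_labels)
        rows.append({"image_path": rel, "label_ids": ids})
        if write_masks and s.masks:
            mdir = out_dir / "masks" / f"scene_{i:05d}"
            mdir.mkdir(parents=True, exist_ok=True)
            for c, m in s.masks.items():
                Image.fromarray((m.astype(np.uint8)) * 255).save(
                    mdir / f"label_{c:02d}.png")

    with open(out_dir / "annotations.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["image_path", "label_ids"])
        w.writeheader()
        w.writerows(rows)
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump([{"image_path": r["image_path"],
                    "label_ids": [int(x) for x in r["label_ids"].split(";")]}
                   for r in rows], fh, indent=1)
    (out_dir / "labels.txt").write_text("\n".join(class_names) + "\n")
    return out_dir
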