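"""Backbone, dual sigmoid classification heads, and the group-to-attend module.

The default backbone is a four-block CNN (3x3 conv + ReLU + 2x2 max-pool for
the first three blocks) sized for 64x64 scenes; its last convolutional
activations are retained so class activation maps can be computed from them.
Two independent fully connected heads share the backbone: the *original* head
scores pooled features of real samples, the *mixed* head scores interpolated
features.  The group-to-attend (GA) module randomly pairs samples, projects
each member through its own linear layer, and maps the combined projection
through a final linear layer and a sigmoid to a scalar attention weight
``a`` in (0, 1); the pair is mixed as ``a * x_i + (1 - a) * x_j``.

Because every head is linear on globally average-pooled features, the
gradient of a class logit with respect to the last-conv activations is
spatially constant and available in closed form — the CAM machinery exploits
this instead of re-running backprop through the convolutional stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (F32, SGD, Conv2d, Dropout, Linear, MaxPool2, Param, ReLU,
                  global_avg_pool, global_avg_pool_backward, sigmoid)

__all__ = [
    "BackboneOutput",
    "MixGroup",
    "SmallCNNBackbone",
    "GroupToAttend",
    "AFCMModel",
    "preprocess_images",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=F32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=F32)


def preprocess_images(images: np.ndarray) -> np.ndarray:
    """uint8 (N,H,W,3) -> normalized float32 (N,3,H,W).

    Pixels are scaled to [0,1] then standardized with the usual ImageNet
    channel statistics (mean [0.485, 0.456, 0.406], std [0.229, 0.224, 0.225]).
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    x = x.astype(F32) / F32(255.0)
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


@dataclass
class BackboneOutput:
    """Pooled per-sample features plus retained last-conv activations."""

    features: np.ndarray          # (N, F)
    conv_activations: np.ndarray  # (N, C, h, w)


@dataclass
class MixGroup:
    """A 2-member group with its scalar attention weight."""

    index_i: int
    index_j: int
    a_i: float
    group_size: int = 2

    def __post_init__(self):
        if self.index_i == self.index_j:
            raise ValueError("group members must be distinct samples")
        if not 0.0 <= self.a_i <= 1.0:
            raise ValueError("attention weight must lie in [0, 1]")


class SmallCNNBackbone:
    """Four conv blocks; pooling after the first three keeps an 8x8 last-conv
    grid on 64x64 input (stride 8), which is coarse but sufficient for CAMs."""

    MIN_INPUT = 32  # three 2x2 pools need at least this much signal

    def __init__(self, channels=(8, 16, 32, 64), dropout_p: float = 0.0,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.dropout_p = float(dropout_p)
        self.layers: list = []
        c_in = 3
        for k, c_out in enumerate(self.channels):
            self.layers.append(Conv2d(c_in, c_out, rng=rng))
            self.layers.append(ReLU())
            if self.dropout_p > 0:
                self.layers.append(Dropout(self.dropout_p))
            if k < len(self.channels) - 1:
                self.layers.append(MaxPool2())
            c_in = c_out

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Return last-conv activations (post-ReLU).  A train-mode rng
        activates dropout; in eval mode the pass is deterministic."""
        if x.shape[2] < self.MIN_INPUT or x.shape[3] < self.MIN_INPUT:
            raise ValueError(
                f"input spatial size {x.shape[2:]} below backbone minimum "
                f"{self.MIN_INPUT}")
        a = x
        for layer in self.layers:
            if isinstance(layer, Dropout):
                a = layer.forward(a, rng=rng)
            else:
                a = layer.forward(a)
        return a

    def backward(self, d_act: np.ndarray) -> np.ndarray:
        g = d_act
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class GroupToAttend:
    """Random 2-member grouping with a learned scalar attention weight.

    Each member passes through its own linear projection (to ``proj_dim``);
    the concatenated projections feed one linear layer whose single logit is
    squashed by a sigmoid into ``a in (0, 1)``.  The combining layer starts
    at zero so an untrained module outputs a = 0.5 (plain average mixing).
    """

    def __init__(self, feature_dim: int, proj_dim: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.proj_i = Linear(feature_dim, proj_dim, rng=rng)
        self.proj_j = Linear(feature_dim, proj_dim, rng=rng)
        self.combine = Linear(2 * proj_dim, 1, zero_init=True)
        self._cache = None

    def params(self) -> list[Param]:
        return self.proj_i.params() + self.proj_j.params() + self.combine.params()

    def sample_pairs(self, batch_size: int, num_groups: int | None = None,
                     rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
        if batch_size < 2:
            raise ValueError("group-to-attend needs a batch of at least 2")
        rng = rng or np.random.default_rng(0)
        num_groups = num_groups or batch_size
        pairs = []
        for _ in range(num_groups):
            i, j = rng.choice(batch_size, size=2, replace=False)
            pairs.append((int(i), int(j)))
        return pairs

    def forward(self, features: np.ndarray,
                pairs: list[tuple[int, int]]) -> np.ndarray:
        """Attention weights a (one per pair), caching for backward."""
        idx_i = np.array([p[0] for p in pairs])
        idx_j = np.array([p[1] for p in pairs])
        hi = self.proj_i.forward(features[idx_i])
        hj = self.proj_j.forward(features[idx_j])
        z = self.combine.forward(np.concatenate([hi, hj], axis=1))[:, 0]
        a = sigmoid(z).astype(F32)
        self._cache = (features.shape, idx_i, idx_j, a)
        return a

    def backward(self, d_a: np.ndarray) -> np.ndarray:
        """Backprop d(loss)/d(a) to the member features; returns (N, F) grads."""
        fshape, idx_i, idx_j, a = self._cache
        dz = (d_a * a * (1.0 - a)).astype(F32)[:, None]
        dh = self.combine.backward(dz)
        half = dh.shape[1] // 2
        dfi = self.proj_i.backward(dh[:, :half])
        dfj = self.proj_j.backward(dh[:, half:])
        d_features = np.zeros(fshape, dtype=F32)
        np.add.at(d_features, idx_i, dfi)
        np.add.at(d_features, idx_j, dfj)
        return d_features


class AFCMModel:
    """Backbone + original/mixed heads + GA module.

    The two heads are separate linear maps from pooled features to per-class
    logits; predictions are independent sigmoids thresholded at 0.5.
    """

    def __init__(self, num_classes: int, channels=(8, 16, 32, 64),
                 dropout_p: float = 0.0, ga_proj_dim: int = 128, seed: int = 0):
        self.num_classes = int(num_classes)
        self.config = {
            "num_classes": self.num_classes,
            "channels": list(channels),
            "dropout_p": float(dropout_p),
            "ga_proj_dim": int(ga_proj_dim),
            "seed": int(seed),
        }
        self.backbone = SmallCNNBackbone(channels, dropout_p, seed=seed)
        rng = np.random.default_rng(seed + 1)
        f = self.backbone.feature_dim
        self.head_org = Linear(f, num_classes, rng=rng)
        self.head_afm = Linear(f, num_classes, rng=rng)
        self.ga = GroupToAttend(f, proj_dim=ga_proj_dim, seed=seed + 2)

    # ---- inference -------------------------------------------------------

    def params(self) -> list[Param]:
        return (self.backbone.params() + self.head_org.params()
                + self.head_afm.params() + self.ga.params())

    def forward_backbone(self, x: np.ndarray,
                         rng: np.random.Generator | None = None) -> BackboneOutput:
        act = self.backbone.forward(x, rng=rng)
        return BackboneOutput(features=global_avg_pool(act), conv_activations=act)

    def logits(self, features: np.ndarray, head: str = "original") -> np.ndarray:
        layer = self._head(head)
        if features.shape[1] != layer.W.value.shape[0]:
            raise ValueError("feature length does not match head weights")
        return features @ layer.W.value + layer.b.value

    def predict_multilabel(self, features: np.ndarray,
                           head: str = "original") -> np.ndarray:
        """Independent per-class sigmoid probabilities."""
        return sigmoid(self.logits(features, head))

    def predict_images(self, images: np.ndarray,
                       threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """uint8 images -> (hard multi-hot predictions, probabilities)."""
        x = preprocess_images(images)
        probs = self.predict_multilabel(self.forward_backbone(x).features)
        return (probs > threshold).astype(np.int8), probs

    def _head(self, head: str) -> Linear:
        if head in ("original", "org"):
            return self.head_org
        if head in ("mixed", "afm"):
            return self.head_afm
        raise ValueError(f"unknown head {head!r}")

    # ---- CAM support -----------------------------------------------------

    def conv_logit_grad(self, conv_shape: tuple, label: int,
                        head: str = "original") -> np.ndarray:
        """d(logit_label)/d(conv activations) for one sample.

        The head is linear on the spatial mean, so the gradient is the head
        weight divided by the number of spatial positions, constant over the
        grid.  Shape (C, h, w).
        """
        if not 0 <= label < self.num_classes:
            raise ValueError(f"label {label} out of range")
        c, h, w = conv_shape
        wvec = self._head(head).W.value[:, label].astype(np.float64)
        g = np.broadcast_to((wvec / (h * w))[:, None, None], (c, h, w))
        return np.ascontiguousarray(g)

    # ---- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: config JSON + all weights in one .npz."""
        path = Path(path)
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        arrays["__config__"] = np.frombuffer(
            json.dumps({"format": 1, **self.config}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AFCMModel":
        with np.load(Path(path)) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            if cfg.pop("format") != 1:
                raise ValueError("unsupported checkpoint format")
            model = cls(cfg["num_classes"], channels=cfg["channels"],
                        dropout_p=cfg["dropout_p"], ga_proj_dim=cfg["ga_proj_dim"],
                        seed=cfg["seed"])
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"param_{i}"]
        return model
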