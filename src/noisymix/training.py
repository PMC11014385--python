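"""Training loops: plain BCE baseline, AFM (scalar MixUp) and CAM-driven AFCM.

The dual-head objective is

    L_total = lam * L_afm + (1 - lam) * L_org

where L_org is mean binary cross-entropy of the original head on the whole
batch's (possibly noisy) hard labels and L_afm is mean BCE of the mixed head
on the virtual samples' soft labels (lam defaults to 0.75).  Optimization is
SGD with momentum 0.9 and weight decay 1e-4, starting at lr 0.01 and dropped
x0.1 at 50% and 75% of the epoch budget; the only training augmentation is a
random horizontal flip.  Gradient flows through the mixed-feature path into
the GA projections (attention weights are optimized jointly with the
classifiers) while CAM masks are constants within an iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (F32, SGD, bce_with_logits, global_avg_pool,
                  global_avg_pool_backward)
from .cam_mixup import afm_mix_labels, image_label_masks, pair_soft_labels
from .model_core import AFCMModel, preprocess_images
from .synthetic_scenes import LabeledScene

__all__ = ["LossWeights", "TrainConfig", "total_loss", "train", "train_baseline"]


@dataclass(frozen=True)
class LossWeights:
    lam: float = 0.75

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_milestones: tuple[float, float] = (0.5, 0.75)  # fractions of epochs
    lr_gamma: float = 0.1
    lam: float = 0.75
    augment_hflip: bool = True
    dropout_p: float = 0.0
    num_groups: int | None = None  # defaults to batch size
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs must be >= 1 and batch_size >= 2")
        if sorted(self.lr_milestones) != list(self.lr_milestones):
            raise ValueError("lr_milestones must be sorted ascending")

    def milestone_epochs(self) -> list[int]:
        return [int(round(m * self.epochs)) for m in self.lr_milestones]


def total_loss(logits_org: np.ndarray, labels: np.ndarray,
               logits_afm: np.ndarray, soft_labels: np.ndarray,
               lw: LossWeights = LossWeights()):
    """Eq-style dual loss; returns (L_total, L_org, L_afm, d_org, d_afm).

    The gradients returned are with respect to the two logit arrays and
    already carry the lam / (1 - lam) factors.
    """
    soft = np.asarray(soft_labels)
    if ((soft < 0) | (soft > 1)).any():
        raise ValueError("soft labels must lie in [0, 1]")
    l_org, d_org = bce_with_logits(logits_org, labels)
    l_afm, d_afm = bce_with_logits(logits_afm, soft)
    lam = lw.lam
    return (lam * l_afm + (1.0 - lam) * l_org, l_org, l_afm,
            (1.0 - lam) * d_org, lam * d_afm)


def _stack_scenes(scenes: list[LabeledScene]):
    images = np.stack([s.image for s in scenes])
    labels = np.stack([s.labels for s in scenes]).astype(F32)
    return images, labels


def _hflip(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flip = rng.random(len(images)) < 0.5
    out = images.copy()
    out[flip] = out[flip][:, :, ::-1]
    return out


def train(model: AFCMModel, scenes: list[LabeledScene], cfg: TrainConfig,
          t1: float = 0.5, t2: float = 0.8, method: str = "afcm",
          eval_fn=None) -> list[dict]:
    """Train in place; returns the per-epoch history.

    ``method``: "baseline" uses only the original head's BCE; "afm" is the
    scalar-MixUp arm (identical to afcm with t2 = 0); "afcm" refines the
    label weights from CAM overlap.  ``eval_fn(model) -> dict`` is called
    after each epoch and merged into the history row if given.
    """
    if method not in ("baseline", "afm", "afcm"):
        raise ValueError(f"unknown method {method!r}")
    if method == "afm":
        t2 = 0.0
    images_all, labels_all = _stack_scenes(scenes)
    n = len(scenes)
    rng = np.random.default_rng(cfg.seed)
    if method == "baseline":
        # plain BCE arm: the mixing machinery does not exist for the
        # optimizer (weight decay must not touch unused parameters)
        opt_params = model.backbone.params() + model.head_org.params()
    else:
        opt_params = model.params()
    opt = SGD(opt_params, lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    lw = LossWeights(cfg.lam)
    milestones = set(cfg.milestone_epochs())
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        if epoch in milestones:
            opt.lr *= cfg.lr_gamma
        order = rng.permutation(n)
        ep_tot = ep_org = ep_afm = 0.0
        n_batches = 0
        for start in range(0, n - 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            images = images_all[idx]
            if cfg.augment_hflip:
                images = _hflip(images, rng)
            labels = labels_all[idx]
            x = preprocess_images(images)

            opt.zero_grad()
            act = model.backbone.forward(x, rng=rng if cfg.dropout_p > 0 else None)
            feats = global_avg_pool(act)
            logits_org = model.head_org.forward(feats)

            if method == "baseline":
                loss, d_org = bce_with_logits(logits_org, labels)
                l_org, l_afm = loss, 0.0
                d_feats = model.head_org.backward(d_org)
            else:
                pairs = model.ga.sample_pairs(len(idx), cfg.num_groups, rng)
                a_vec = model.ga.forward(feats, pairs)
                soft = _soft_labels(model, act, labels, pairs, a_vec,
                                    x.shape[2:], t1, t2)
                ii = np.array([p[0] for p in pairs])
                jj = np.array([p[1] for p in pairs])
                a_col = a_vec[:, None]
                x_mix = a_col * feats[ii] + (1 - a_col) * feats[jj]
                logits_afm = model.head_afm.forward(x_mix)
                loss, l_org, l_afm, d_org, d_afm = total_loss(
                    logits_org, labels, logits_afm, soft, lw)
                d_feats = model.head_org.backward(d_org)
                d_xmix = model.head_afm.backward(d_afm)
                # mixed-feature path: grads to members and to the GA weight
                np.add.at(d_feats, ii, a_col * d_xmix)
                np.add.at(d_feats, jj, (1 - a_col) * d_xmix)
                d_a = (d_xmix * (feats[ii] - feats[jj])).sum(axis=1)
                d_feats += model.ga.backward(d_a)

            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"loss={loss}, lr={opt.lr}")
            d_act = global_avg_pool_backward(d_feats, act.shape[2:])
            model.backbone.backward(np.ascontiguousarray(d_act))
            opt.step()
            ep_tot += loss
            ep_org += l_org
            ep_afm += l_afm
            n_batches += 1

        row = {"epoch": epoch, "loss": ep_tot / n_batches,
               "loss_org": ep_org / n_batches, "loss_afm": ep_afm / n_batches,
               "lr": opt.lr}
        if eval_fn is not None:
            row.update(eval_fn(model))
        history.append(row)
    return history


def _soft_labels(model, act, labels, pairs, a_vec, grid, t1, t2):
    """Soft labels for every pair (no gradient flows through this)."""
    if t2 == 0.0:
        # exact scalar-MixUp reduction, skipping CAM work entirely
        return np.stack([afm_mix_labels(labels[i], labels[j], float(a))
                         for (i, j), a in zip(pairs, a_vec)])
    masks_cache: dict[int, dict] = {}

    def masks_for(idx):
        if idx not in masks_cache:
            masks_cache[idx] = image_label_masks(model, act[idx], labels[idx],
                                                 grid, t1)
        return masks_cache[idx]

    soft = []
    for (i, j), a in zip(pairs, a_vec):
        s, _, _ = pair_soft_labels(labels[i], labels[j], float(a),
                                   masks_for(i), masks_for(j), grid, t2)
        soft.append(s)
    return np.stack(soft)


def train_baseline(model: AFCMModel, scenes: list[LabeledScene],
                   cfg: TrainConfig, eval_fn=None) -> list[dict]:
    """Plain BCE comparison arm (no mixing; lam is irrelevant)."""
    return train(model, scenes, cfg, method="baseline", eval_fn=eval_fn)
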