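"""Multi-label metrics and the evaluation protocols.

Metrics are precision, recall, F1 and Jaccard index computed from pooled
TP/FP/FN counts (micro averaging) or per sample then averaged (sample
averaging).  The Jaccard index TP/(TP+FP+FN) never exceeds F1.  The module
also provides the clean-vs-noisy training-subset split used to measure
memorization of corrupted labels, the perturbation-robustness sweep over
rotations and color adjustments, and the T2 sweep that retrains the model
across the refinement-threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_scenes import PERTURBATION_GRID, LabeledScene, perturb_image

__all__ = [
    "EvalReport",
    "SubsetSplit",
    "multilabel_metrics",
    "per_label_confusion",
    "eval_clean_noisy",
    "robustness_sweep",
    "sweep_t2",
    "per_sample_f1",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    jaccard: float
    averaging: str
    n_samples: int
    per_label_confusion: dict[int, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "jaccard": self.jaccard,
                "averaging": self.averaging, "n_samples": self.n_samples}


@dataclass
class SubsetSplit:
    clean_indices: np.ndarray
    noisy_indices: np.ndarray


def _check(predictions, truths):
    p = np.asarray(predictions)
    t = np.asarray(truths)
    if p.shape != t.shape or p.ndim != 2:
        raise ValueError(f"prediction/truth shapes differ: {p.shape} vs {t.shape}")
    if p.shape[0] < 1:
        raise ValueError("need at least one sample")
    return p.astype(bool), t.astype(bool)


def _prfj(tp: float, fp: float, fn: float) -> tuple[float, float, float, float]:
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    ji = tp / (tp + fp + fn) if tp + fp + fn > 0 else 0.0
    return prec, rec, f1, ji


def multilabel_metrics(predictions: np.ndarray, truths: np.ndarray,
                       averaging: str = "micro") -> EvalReport:
    """P/R/F1/JI under micro or sample averaging, with per-label confusion.

    Sample averaging scores each sample's label set separately; a sample
    with no predicted and no true labels counts as perfect, while an empty
    prediction against a nonempty truth scores zero on all four metrics.
    """
    p, t = _check(predictions, truths)
    n, c = p.shape
    tp_s = (p & t).sum(axis=1).astype(np.float64)
    fp_s = (p & ~t).sum(axis=1).astype(np.float64)
    fn_s = (~p & t).sum(axis=1).astype(np.float64)

    if averaging == "micro":
        prec, rec, f1, ji = _prfj(tp_s.sum(), fp_s.sum(), fn_s.sum())
    elif averaging == "sample":
        rows = np.array([_prfj(a, b, d) for a, b, d in zip(tp_s, fp_s, fn_s)])
        empty_both = (tp_s + fp_s + fn_s) == 0
        rows[empty_both] = 1.0
        prec, rec, f1, ji = rows.mean(axis=0)
    else:
        raise ValueError(f"unknown averaging {averaging!r}")

    conf = {lab: per_label_confusion(p, t, lab) for lab in range(c)}
    return EvalReport(precision=float(prec), recall=float(rec), f1=float(f1),
                      jaccard=float(ji), averaging=averaging, n_samples=n,
                      per_label_confusion=conf)


def per_label_confusion(predictions: np.ndarray, truths: np.ndarray,
                        label: int) -> dict[str, int]:
    """One-vs-rest TP/FP/FN/TN counts for a single class."""
    p, t = _check(predictions, truths)
    if not 0 <= label < p.shape[1]:
        raise ValueError(f"unknown label {label}")
    pc, tc = p[:, label], t[:, label]
    return {"tp": int((pc & tc).sum()), "fp": int((pc & ~tc).sum()),
            "fn": int((~pc & tc).sum()), "tn": int((~pc & ~tc).sum())}


def per_sample_f1(predictions: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Per-sample F1 vector (exported for external significance testing)."""
    p, t = _check(predictions, truths)
    tp = (p & t).sum(axis=1).astype(np.float64)
    fp = (p & ~t).sum(axis=1).astype(np.float64)
    fn = (~p & t).sum(axis=1).astype(np.float64)
    out = np.ones(len(p))
    nz = (tp + fp + fn) > 0
    denom = 2 * tp[nz] + fp[nz] + fn[nz]
    out[nz] = 2 * tp[nz] / denom
    return out


def split_clean_noisy(scenes: list[LabeledScene]) -> SubsetSplit:
    """Clean = labels identical to clean_labels; noisy = at least one differs."""
    noisy = np.array([not np.array_equal(s.labels, s.clean_labels)
                      for s in scenes])
    idx = np.arange(len(scenes))
    return SubsetSplit(clean_indices=idx[~noisy], noisy_indices=idx[noisy])


def eval_clean_noisy(model, scenes: list[LabeledScene],
                     averaging: str = "micro") -> dict[str, EvalReport | None]:
    """Memorization probe: score predictions against the *noisy* training
    labels on the clean and noisy training subsets separately.

    A model that memorizes corrupted annotations scores high on the noisy
    subset; robustness shows up as a low noisy-subset score.  An empty
    subset yields ``None`` for that side.
    """
    split = split_clean_noisy(scenes)
    images = np.stack([s.image for s in scenes])
    labels = np.stack([s.labels for s in scenes])
    preds, _ = model.predict_images(images)
    out: dict[str, EvalReport | None] = {}
    for name, idx in (("clean", split.clean_indices),
                      ("noisy", split.noisy_indices)):
        out[name] = (multilabel_metrics(preds[idx], labels[idx], averaging)
                     if len(idx) else None)
    return out


def robustness_sweep(model, scenes: list[LabeledScene], posthoc=None,
                     grid=PERTURBATION_GRID,
                     averaging: str = "micro") -> list[dict]:
    """Score the model on the unperturbed test set and on each perturbation.

    ``posthoc`` may be a callable ``(model, images) -> probabilities`` (e.g.
    a Laplace or MC-Dropout predictor); otherwise the plain forward pass is
    used.  Returns one row per grid entry, identity first.
    """
    truths = np.stack([s.clean_labels for s in scenes])
    rows = []
    for kind, magnitude in ((None, None),) + tuple(grid):
        if kind is None:
            images = np.stack([s.image for s in scenes])
        else:
            images = np.stack([perturb_image(s.image, kind, magnitude)
                               for s in scenes])
        if posthoc is None:
            preds, _ = model.predict_images(images)
        else:
            probs = posthoc(model, images)
            preds = (probs > 0.5).astype(np.int8)
        rep = multilabel_metrics(preds, truths, averaging)
        rows.append({"perturbation": kind or "none", "magnitude": magnitude,
                     **rep.as_dict()})
    return rows


def sweep_t2(train_scenes: list[LabeledScene], test_scenes: list[LabeledScene],
             cfg, grid=None, t1: float = 0.5, seeds=(0,),
             model_factory=None) -> list[dict]:
    """Retrain and evaluate across the T2 grid (default 0.0 to 1.0 step 0.1).

    Each grid point is trained once per seed; the row reports mean and std
    of test F1/JI over seeds.  T2 = 0 is the scalar-MixUp arm.
    """
    from dataclasses import replace

    from .model_core import AFCMModel
    from .training import train

    if grid is None:
        grid = [round(0.1 * k, 1) for k in range(11)]
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("t2 grid must lie in [0, 1]")
    if model_factory is None:
        num_classes = len(train_scenes[0].labels)
        model_factory = lambda seed: AFCMModel(num_classes, seed=seed)

    test_images = np.stack([s.image for s in test_scenes])
    test_truth = np.stack([s.clean_labels for s in test_scenes])
    rows = []
    for t2 in grid:
        f1s, jis = [], []
        for seed in seeds:
            model = model_factory(seed)
            train(model, train_scenes, replace(cfg, seed=seed), t1=t1, t2=t2,
                  method="afcm")
            preds, _ = model.predict_images(test_images)
            rep = multilabel_metrics(preds, test_truth)
            f1s.append(rep.f1)
            jis.append(rep.jaccard)
        rows.append({"t2": t2,
                     "f1_mean": float(np.mean(f1s)), "f1_std": float(np.std(f1s)),
                     "ji_mean": float(np.mean(jis)), "ji_std": float(np.std(jis))})
    return rows
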