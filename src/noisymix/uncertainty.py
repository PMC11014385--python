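"""Post-hoc probabilistic prediction for the trained classifier.

Last-layer Laplace approximation: the posterior over the original head's
weights (including bias) is approximated as a Gaussian centered at the
trained (MAP) weights with covariance the inverse of a Kronecker-factored
curvature.  Under the per-class Bernoulli likelihood the generalized
Gauss-Newton of the last linear layer factorizes into an input factor
A = mean(phi phi^T) over augmented features phi = [f; 1] and an output
factor B = mean(diag(p(1-p))); the curvature is approximated as
N * (B kron A).  A scalar prior precision tau is added to the eigenvalues
(the standard Kronecker-preserving trick) and tuned by maximizing the
Laplace evidence over log tau with a coarse grid plus golden-section
refinement.  Prediction draws K weight samples (shared across the inputs of
an evaluation run) and averages the K sigmoid outputs; as tau grows the
posterior collapses onto the MAP model.

An MC-Dropout predictor is included for comparison: it averages stochastic
forward passes with the backbone's dropout layers kept active at inference.
Both predictors are strictly post hoc — the checkpoint is never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._nn import sigmoid
from .model_core import AFCMModel, preprocess_images

__all__ = [
    "LaplacePosterior",
    "PredictiveConfig",
    "fit_laplace_last_layer",
    "predictive_posterior",
    "laplace_predict",
    "mc_dropout_predict",
]


@dataclass(frozen=True)
class PredictiveConfig:
    k_samples: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k_samples < 1:
            raise ValueError("k_samples must be >= 1")


@dataclass
class LaplacePosterior:
    """MAP last-layer weights plus KFAC curvature and tuned prior precision.

    ``theta_map`` is (D, C) with D = feature_dim + 1 (bias row last);
    ``kron_a`` is the (D, D) input factor, ``kron_b`` the (C, C) output
    factor, and ``n_data`` the dataset size scaling the curvature.
    """

    theta_map: np.ndarray
    kron_a: np.ndarray
    kron_b: np.ndarray
    n_data: int
    prior_precision: float
    log_evidence: float = np.nan

    def __post_init__(self):
        if self.prior_precision <= 0:
            raise ValueError("prior precision must be positive")
        self._eig()

    def _eig(self):
        la, qa = np.linalg.eigh(self.kron_a)
        lb, qb = np.linalg.eigh(self.kron_b)
        self._la, self._qa = np.maximum(la, 0.0), qa
        self._lb, self._qb = np.maximum(lb, 0.0), qb

    @property
    def class_count(self) -> int:
        return self.theta_map.shape[1]

    def posterior_eigvals(self, tau: float | None = None) -> np.ndarray:
        """Eigenvalues of the posterior precision, shape (D, C)."""
        tau = self.prior_precision if tau is None else tau
        return self.n_data * np.outer(self._la, self._lb) + tau

    def sample_weights(self, rng: np.random.Generator, k: int) -> np.ndarray:
        """Draw k weight matrices from N(theta_map, precision^-1); (k, D, C)."""
        d, c = self.theta_map.shape
        scale = 1.0 / np.sqrt(self.posterior_eigvals())
        eps = rng.standard_normal((k, d, c))
        # map white noise through the Kronecker eigenbasis
        return self.theta_map + np.einsum(
            "de,kec,fc->kdf", self._qa, eps * scale, self._qb)

    def save(self, path) -> None:
        np.savez(path, theta_map=self.theta_map, kron_a=self.kron_a,
                 kron_b=self.kron_b, n_data=self.n_data,
                 prior_precision=self.prior_precision,
                 log_evidence=self.log_evidence)

    @classmethod
    def load(cls, path) -> "LaplacePosterior":
        with np.load(path) as d:
            return cls(theta_map=d["theta_map"], kron_a=d["kron_a"],
                       kron_b=d["kron_b"], n_data=int(d["n_data"]),
                       prior_precision=float(d["prior_precision"]),
                       log_evidence=float(d["log_evidence"]))


def _augment(features: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [features, np.ones((len(features), 1), features.dtype)], axis=1)


def _bce_total(probs: np.ndarray, targets: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    return float(-(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum())


def fit_laplace_last_layer(model: AFCMModel, scenes_or_features,
                           labels: np.ndarray | None = None,
                           tune_prior: bool = True,
                           jitter: float = 1e-8) -> LaplacePosterior:
    """Accumulate KFAC factors over the training set and tune the prior.

    Accepts either a list of LabeledScene (images are run through the
    backbone) or a precomputed (features, labels) pair via
    ``(features, labels)`` arguments.
    """
    if labels is None:
        scenes = scenes_or_features
        images = np.stack([s.image for s in scenes])
        labels = np.stack([s.labels for s in scenes]).astype(np.float64)
        features = model.forward_backbone(preprocess_images(images)).features
    else:
        features = np.asarray(scenes_or_features)
        labels = np.asarray(labels, dtype=np.float64)

    phi = _augment(features.astype(np.float64))
    n, d = phi.shape
    theta_map = np.concatenate(
        [model.head_org.W.value, model.head_org.b.value[None, :]],
        axis=0).astype(np.float64)
    probs = sigmoid(phi @ theta_map)
    lam = probs * (1.0 - probs)  # per-class Bernoulli GGN output curvature

    kron_a = phi.T @ phi / n
    kron_b = np.diag(lam.mean(axis=0))
    # symmetrize + jitter against numerically singular factors
    kron_a = 0.5 * (kron_a + kron_a.T)
    if np.linalg.eigvalsh(kron_a).min() < jitter:
        warnings.warn("near-singular KFAC input factor; adding jitter",
                      stacklevel=2)
        kron_a += jitter * np.eye(d)

    post = LaplacePosterior(theta_map=theta_map, kron_a=kron_a, kron_b=kron_b,
                            n_data=n, prior_precision=1.0)
    nll_map = _bce_total(probs, labels)
    map_sq = float((theta_map ** 2).sum())
    n_params = theta_map.size

    def neg_log_evidence(log_tau: float) -> float:
        tau = float(np.exp(log_tau))
        eig = post.posterior_eigvals(tau)
        return -(-nll_map - 0.5 * tau * map_sq
                 + 0.5 * n_params * np.log(tau)
                 - 0.5 * float(np.log(eig).sum()))

    if tune_prior:
        grid = np.linspace(-4.0, 8.0, 25)
        vals = [neg_log_evidence(g) for g in grid]
        best = int(np.argmin(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(neg_log_evidence, bracket=None,
                              bounds=(lo, hi), method="bounded")
        log_tau = float(res.x)
    else:
        log_tau = 0.0
    post.prior_precision = float(np.exp(log_tau))
    post.log_evidence = -neg_log_evidence(log_tau)
    return post


def predictive_posterior(post: LaplacePosterior, features: np.ndarray,
                         cfg: PredictiveConfig = PredictiveConfig()) -> np.ndarray:
    """Monte-Carlo predictive: mean sigmoid over K posterior weight samples.

    The K weight samples are drawn once and shared across all inputs of the
    call; with a fixed seed the result is deterministic.
    """
    rng = np.random.default_rng(cfg.seed)
    thetas = post.sample_weights(rng, cfg.k_samples)
    phi = _augment(np.asarray(features, dtype=np.float64))
    probs = sigmoid(np.einsum("nd,kdc->knc", phi, thetas))
    return probs.mean(axis=0)


def laplace_predict(post: LaplacePosterior,
                    cfg: PredictiveConfig = PredictiveConfig()):
    """Adapter with the ``(model, images) -> probabilities`` post-hoc shape."""

    def _predict(model: AFCMModel, images: np.ndarray) -> np.ndarray:
        feats = model.forward_backbone(preprocess_images(images)).features
        return predictive_posterior(post, feats, cfg)

    return _predict


def mc_dropout_predict(model: AFCMModel, images: np.ndarray, passes: int = 10,
                       dropout_p: float | None = None,
                       seed: int = 0) -> np.ndarray:
    """Average of stochastic forward passes with dropout active at inference.

    ``dropout_p`` overrides the backbone's dropout probability for the call
    (restored afterwards); p = 0 reduces to the deterministic forward pass.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    from ._nn import Dropout

    drops = [l for l in model.backbone.layers if isinstance(l, Dropout)]
    old = [l.p for l in drops]
    if dropout_p is not None:
        for l in drops:
            l.p = dropout_p
    try:
        rng = np.random.default_rng(seed)
        x = preprocess_images(images)
        acc = None
        for _ in range(passes):
            feats = model.forward_backbone(x, rng=rng).features
            probs = model.predict_multilabel(feats)
            acc = probs if acc is None else acc + probs
        return acc / passes
    finally:
        for l, p in zip(drops, old):
            l.p = p
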