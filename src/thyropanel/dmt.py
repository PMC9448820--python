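"""Manifold-regularized neural classifier.

A two-part multilayer perceptron — a feature-extraction sub-model mapping
panel vectors to a latent space and a classification head — trained with a
composite loss

    L = L_div + alpha1 * L_ce + alpha2 * L_l2

where ``L_div`` is a cross-layer two-way (Bernoulli KL) divergence between
pairwise similarity matrices built in the input space (P) and the latent
space (Q), ``L_ce`` is a class-weighted cross-entropy and ``L_l2`` an L2
penalty on the weight matrices.  Similarities come from a Student-t kernel
of pairwise Euclidean distances followed by a symmetrization map.

Gradients are exact (reverse-mode autodiff via ``autograd``); optimization
is plain minibatch SGD with global-norm gradient clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import grad
from autograd.misc.flatten import flatten
from scipy.special import gammaln
from sklearn.model_selection import StratifiedKFold

from .metrics import roc_auc
from .preprocess import NormalizationModel

__all__ = [
    "NetConfig",
    "TrainedClassifier",
    "Prediction",
    "t_kernel",
    "symmetrize",
    "pairwise_similarities",
    "dmt_loss",
    "weighted_cross_entropy",
    "l2_penalty",
    "total_loss",
    "loss_components",
    "init_params",
    "train",
    "predict",
    "embed",
    "labels_to_y",
]


@dataclass
class NetConfig:
    """Architecture and training hyperparameters."""

    layer_widths: tuple[int, ...] = (64, 32)  # hidden widths of the extractor
    latent_dim: int = 8
    head_widths: tuple[int, ...] = ()  # hidden widths of the classifier head
    alpha1: float = 1e3
    alpha2: float = 50.0
    beta: float = 1.6
    nu_x: float = 100.0
    nu_z: float = 1.0
    learning_rate: float = 2e-2
    batch_size: int = 256
    epochs: int = 100
    eps_clamp: float = 1e-6
    clip_norm: float = 10.0
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha1 and alpha2 must be >= 0")
        if not (0.0 < self.beta < 2.0):
            raise ValueError("beta must lie in (0, 2)")
        if self.nu_x <= 0 or self.nu_z <= 0:
            raise ValueError("degrees of freedom must be > 0")
        if not (0.0 < self.eps_clamp < 0.5):
            raise ValueError("eps_clamp must lie in (0, 0.5)")
        if self.latent_dim < 1 or self.batch_size < 2:
            raise ValueError("latent_dim >= 1 and batch_size >= 2 required")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


# ----------------------------------------------------------------------
# similarity machinery
# ----------------------------------------------------------------------

def _t_const(nu: float) -> float:
    # Gamma((nu+1)/2) / (sqrt(nu*pi) * Gamma(nu/2)), via log-gamma
    return float(np.exp(gammaln((nu + 1) / 2) - gammaln(nu / 2)) / np.sqrt(nu * np.pi))


def _kernel_from_sq(D2, nu: float):
    """Student-t kernel expressed in squared distances (autodiff-smooth)."""
    return _t_const(nu) * (1.0 + D2 / nu) ** (-(nu + 1.0) / 2.0)


def t_kernel(D, nu: float):
    """Elementwise Student-t density kernel of a distance matrix.

    ``kappa(D, nu) = Gamma((nu+1)/2) / (sqrt(nu pi) Gamma(nu/2))
    * (1 + D*D/nu)^(-(nu+1)/2)``.
    """
    if nu <= 0:
        raise ValueError("nu must be > 0")
    if isinstance(D, np.ndarray) and not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    return _kernel_from_sq(anp.asarray(D) ** 2, nu)


def symmetrize(A):
    """S(A) = A + A^T - 2 A o A^T (o = elementwise product)."""
    return A + A.T - 2.0 * A * A.T


def _pairwise_sq_dists(X):
    s = anp.sum(X * X, axis=1)
    D2 = s[:, None] + s[None, :] - 2.0 * anp.dot(X, X.T)
    return anp.maximum(D2, 0.0)


def pairwise_similarities(X, nu: float, eps_clamp: float = 1e-6):
    """Similarity matrix S(2 pi kappa(D, nu)^2) of a batch of vectors.

    Euclidean distances -> t-kernel -> square and scale by 2 pi ->
    symmetrize -> clamp into [eps, 1 - eps].  The diagonal is never used
    downstream (divergence sums run over i != j).
    """
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    A = _kernel_from_sq(_pairwise_sq_dists(X), nu)
    S = symmetrize(2.0 * anp.pi * A**2)
    return anp.clip(S, eps_clamp, 1.0 - eps_clamp)


def dmt_loss(P, Q):
    """Two-way divergence: sum over i != j of Bernoulli KL(P_ij || Q_ij).

    Entries must be pre-clamped into (0, 1); natural logarithm.
    """
    n = P.shape[0]
    mask = 1.0 - anp.eye(n)
    terms = P * anp.log(P / Q) + (1.0 - P) * anp.log((1.0 - P) / (1.0 - Q))
    return anp.sum(mask * terms)


def weighted_cross_entropy(y, p_benign, beta: float, eps_clamp: float = 1e-6):
    """Class-weighted binary cross-entropy (y = 1 denotes benign).

    ``-sum(beta * y * log(p) + (2 - beta) * (1 - y) * log(1 - p))``; at
    beta = 1 this is standard binary cross-entropy.
    """
    y = np.asarray(y, dtype=float)
    p = anp.clip(p_benign, eps_clamp, 1.0 - eps_clamp)
    return -anp.sum(beta * y * anp.log(p) + (2.0 - beta) * (1.0 - y) * anp.log(1.0 - p))


def l2_penalty(params):
    """Sum of squared entries of every weight matrix (biases excluded)."""
    total = 0.0
    for part in ("fe", "head"):
        for W, _b in params[part]:
            total = total + anp.sum(W * W)
    return total


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------

def init_params(n_features: int, config: NetConfig, rng: np.random.Generator) -> dict:
    """He-initialized weights for extractor and head."""

    def make(dims):
        layers = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
            layers.append((W, np.zeros(d_out)))
        return layers

    fe_dims = [n_features, *config.layer_widths, config.latent_dim]
    head_dims = [config.latent_dim, *config.head_widths, 2]
    return {"fe": make(fe_dims), "head": make(head_dims)}


def _relu(x):
    return anp.maximum(x, 0.0)


def forward_latent(params, X):
    h = X
    layers = params["fe"]
    for W, b in layers[:-1]:
        h = _relu(anp.dot(h, W) + b)
    W, b = layers[-1]
    return anp.dot(h, W) + b


def forward_probs(params, X):
    """Class probabilities; column 0 = malignant, column 1 = benign."""
    h = forward_latent(params, X)
    layers = params["head"]
    for W, b in layers[:-1]:
        h = _relu(anp.dot(h, W) + b)
    W, b = layers[-1]
    logits = anp.dot(h, W) + b
    z = logits - anp.max(logits, axis=1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=1, keepdims=True)


def total_loss(params, X, y, config: NetConfig, P=None):
    """Composite training loss on one batch (y = 1 benign, y = 0 malignant).

    P (input-space similarities) depends only on the data and may be
    precomputed; Q is recomputed from the current latent coordinates.
    """
    if P is None:
        P = pairwise_similarities(X, config.nu_x, config.eps_clamp)
    V = forward_latent(params, X)
    Q = pairwise_similarities(V, config.nu_z, config.eps_clamp)
    probs = forward_probs(params, X)
    l_div = dmt_loss(P, Q)
    l_ce = weighted_cross_entropy(y, probs[:, 1], config.beta, config.eps_clamp)
    l_l2 = l2_penalty(params)
    return l_div + config.alpha1 * l_ce + config.alpha2 * l_l2


def loss_components(params, X, y, config: NetConfig) -> dict:
    """The three loss terms and their weighted total, for logging."""
    P = pairwise_similarities(X, config.nu_x, config.eps_clamp)
    V = forward_latent(params, X)
    Q = pairwise_similarities(V, config.nu_z, config.eps_clamp)
    probs = forward_probs(params, X)
    l_div = float(dmt_loss(P, Q))
    l_ce = float(weighted_cross_entropy(y, probs[:, 1], config.beta, config.eps_clamp))
    l_l2 = float(l2_penalty(params))
    return {
        "divergence": l_div,
        "cross_entropy": l_ce,
        "l2": l_l2,
        "total": l_div + config.alpha1 * l_ce + config.alpha2 * l_l2,
    }


# ----------------------------------------------------------------------
# training / inference
# ----------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Trained weights plus everything needed to reproduce predictions."""

    params: dict
    config: NetConfig
    n_features: int
    fold_aucs: list[float]
    best_fold: int
    panel: Optional[list[str]] = None
    normalizer: Optional[NormalizationModel] = None

    def save_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "n_features": self.n_features,
            "fold_aucs": self.fold_aucs,
            "best_fold": self.best_fold,
            "panel": self.panel,
            "params": {
                part: [[W.tolist(), b.tolist()] for W, b in self.params[part]]
                for part in ("fe", "head")
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path) -> "TrainedClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["layer_widths"] = tuple(cfg["layer_widths"])
        cfg["head_widths"] = tuple(cfg["head_widths"])
        params = {
            part: [(np.array(W), np.array(b)) for W, b in payload["params"][part]]
            for part in ("fe", "head")
        }
        return cls(
            params=params,
            config=NetConfig(**cfg),
            n_features=payload["n_features"],
            fold_aucs=payload["fold_aucs"],
            best_fold=payload["best_fold"],
            panel=payload.get("panel"),
        )


@dataclass
class Prediction:
    """Per-sample class probabilities and hard calls.

    ``label`` follows the tie-to-malignant rule: 1 (benign) only when the
    malignant probability is strictly below the benign probability.
    """

    y_malignant: np.ndarray  # \hat y^0
    y_benign: np.ndarray  # \hat y^1
    score: np.ndarray  # benign probability in [0, 1]
    label: np.ndarray  # 1 = benign, 0 = malignant

    def class_names(self) -> np.ndarray:
        return np.where(self.label == 1, "benign", "malignant")


def labels_to_y(labels) -> np.ndarray:
    """Map benign/malignant labels to {1, 0}."""
    labels = np.asarray(labels)
    y = np.where(labels == "benign", 1, np.where(labels == "malignant", 0, -1))
    if np.any(y < 0):
        raise ValueError("labels must be 'benign' or 'malignant'")
    return y.astype(int)


def _sgd_fit(X, y, config: NetConfig, rng: np.random.Generator) -> dict:
    params = init_params(X.shape[1], config, rng)
    flat, unflatten = flatten(params)

    def loss_flat(fp, Xb, yb, Pb):
        return total_loss(unflatten(fp), Xb, yb, config, P=Pb)

    grad_flat = grad(loss_flat)
    n = X.shape[0]
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        starts = list(range(0, n, config.batch_size))
        # avoid a trailing singleton batch (pairwise terms need >= 2)
        if len(starts) > 1 and n - starts[-1] < 2:
            starts.pop()
        for s in starts:
            idx = perm[s : s + config.batch_size]
            Xb, yb = X[idx], y[idx]
            Pb = pairwise_similarities(Xb, config.nu_x, config.eps_clamp)
            g = grad_flat(flat, Xb, yb, Pb)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient: training diverged")
            norm = float(np.linalg.norm(g))
            if norm > config.clip_norm:
                g = g * (config.clip_norm / norm)
            flat = flat - config.learning_rate * g
        if not np.all(np.isfinite(flat)):
            raise FloatingPointError("non-finite parameters: training diverged")
    return unflatten(flat)


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: NetConfig,
    panel: Optional[Sequence[str]] = None,
    normalizer: Optional[NormalizationModel] = None,
) -> TrainedClassifier:
    """Stratified k-fold training; returns the fold model with best val AUC.

    ``X`` must be a complete (post-normalization) panel matrix and ``y``
    the {0, 1} labels with 1 = benign.  Each fold trains an independent
    model for ``config.epochs`` epochs of minibatch SGD; validation AUC is
    computed from the malignancy probability on the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be complete (normalize first)")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present (y in {0, 1})")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    best_params, best_auc, best_fold, aucs = None, -np.inf, -1, []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        rng = np.random.default_rng([config.seed, fold])
        params = _sgd_fit(X[tr], y[tr], config, rng)
        probs = forward_probs(params, X[va])
        truth = np.where(y[va] == 0, "malignant", "benign")
        auc = roc_auc(probs[:, 0], truth)
        aucs.append(float(auc))
        if auc > best_auc:
            best_params, best_auc, best_fold = params, auc, fold
    return TrainedClassifier(
        params=best_params,
        config=config,
        n_features=X.shape[1],
        fold_aucs=aucs,
        best_fold=best_fold,
        panel=list(panel) if panel is not None else None,
        normalizer=normalizer,
    )


def _check_features(classifier: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != classifier.n_features:
        raise ValueError(
            f"classifier expects {classifier.n_features} features, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be complete (normalize first)")
    return X


def predict(classifier: TrainedClassifier, X: np.ndarray) -> Prediction:
    """Class probabilities and hard labels (1 = benign iff y0 < y1)."""
    X = _check_features(classifier, X)
    probs = forward_probs(classifier.params, X)
    y0 = np.asarray(probs[:, 0])
    y1 = np.asarray(probs[:, 1])
    label = np.where(y0 < y1, 1, 0)
    return Prediction(y_malignant=y0, y_benign=y1, score=y1, label=label)


def embed(classifier: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Deterministic latent coordinates of samples."""
    X = _check_features(classifier, X)
    return np.asarray(forward_latent(classifier.params, X))
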