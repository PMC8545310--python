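"""Subtopic discovery and classification: stacked-RBM features + softmax.

Sparse high-dimensional token-count vectors are compressed by a deep
belief network — a stack of restricted Boltzmann machines trained
layer-wise with one-step contrastive divergence (CD-1) on binarized
counts — and classified by a softmax regression head
h(m)[t] = exp(s_t . m) / sum_u exp(s_u . m) over the l subtopic classes.

Subtopics are not predefined: messages of one topic are clustered in DBN
feature space (seeded k-means), clusters are named by their highest-lift
token, and the resulting pseudo-labels are the "partial labeled data"
that fine-tune the softmax head. Fine-tuning minimises the L2-penalised
cross-entropy

    J(s) = -(1/m) sum_i sum_t y_t^i log h_t(m^i)
           + (lambda/2) ||s||^2 + (lambda/2) sum_p ||theta_p||^2

(theta_p the RBM weight matrices) by gradient descent with backtracking
line search or by limited-memory BFGS; the deep weights are frozen by
default and updated by backpropagation only when asked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .topics import build_vocabulary, to_matrix

__all__ = [
    "RBMLayer",
    "DBNFeatures",
    "SoftmaxHead",
    "FinetuneConfig",
    "SubtopicRanking",
    "StepSizeError",
    "softmax_forward",
    "finetune_cost",
    "finetune",
    "discover_subtopics",
    "label_clusters",
    "rank_subtopics",
    "SubtopicModel",
]


class StepSizeError(RuntimeError):
    """Gradient descent could not find a decreasing step."""


class RBMLayer(BaseEstimator, TransformerMixin):
    """One restricted Boltzmann machine trained with CD-1.

    Visible units are binary (counts binarized at >= 1 upstream). The
    mean per-sample reconstruction error of each epoch is recorded in
    ``reconstruction_errors_``.
    """

    def __init__(self, n_hidden: int, epochs: int = 10,
                 learning_rate: float = 0.1, batch_size: int = 64,
                 seed: int = 0):
        self.n_hidden = n_hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y=None) -> "RBMLayer":
        X = _dense01(X)
        if X.shape[0] == 0:
            raise ValueError("empty training data")
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        self.weights_ = rng.normal(0.0, 0.01, size=(d, self.n_hidden))
        self.visible_bias_ = np.zeros(d)
        self.hidden_bias_ = np.zeros(self.n_hidden)
        self.reconstruction_errors_ = []
        lr = self.learning_rate
        for _ in range(self.epochs):
            order = rng.permutation(n)
            errs = []
            for start in range(0, n, self.batch_size):
                v0 = X[order[start:start + self.batch_size]]
                h0 = expit(v0 @ self.weights_ + self.hidden_bias_)
                h_sample = (rng.random(h0.shape) < h0).astype(float)
                v1 = expit(h_sample @ self.weights_.T + self.visible_bias_)
                h1 = expit(v1 @ self.weights_ + self.hidden_bias_)
                b = v0.shape[0]
                self.weights_ += lr * (v0.T @ h0 - v1.T @ h1) / b
                self.visible_bias_ += lr * np.mean(v0 - v1, axis=0)
                self.hidden_bias_ += lr * np.mean(h0 - h1, axis=0)
                errs.append(float(np.mean((v0 - v1) ** 2)))
            self.reconstruction_errors_.append(float(np.mean(errs)))
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic mean-field hidden activations (no sampling)."""
        check_is_fitted(self, "weights_")
        X = _dense(X)
        if X.shape[1] != self.weights_.shape[0]:
            raise ValueError("input width does not match layer")
        return expit(X @ self.weights_ + self.hidden_bias_)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


def _dense01(X) -> np.ndarray:
    return (_dense(X) >= 1).astype(float)


class DBNFeatures(BaseEstimator, TransformerMixin):
    """Stack of RBM layers trained greedily; each layer's mean-field
    output feeds the next. Default unit counts 2000-1000-500 with 1000
    pre-training epochs at learning rate 0.01."""

    def __init__(self, layer_sizes: Tuple[int, ...] = (2000, 1000, 500),
                 epochs: int = 1000, learning_rate: float = 0.01,
                 batch_size: int = 64, seed: int = 0):
        self.layer_sizes = layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y=None) -> "DBNFeatures":
        if len(self.layer_sizes) < 1:
            raise ValueError("at least one layer required")
        data = _dense01(X)
        self.layers_ = []
        for p, width in enumerate(self.layer_sizes):
            layer = RBMLayer(width, epochs=self.epochs,
                             learning_rate=self.learning_rate,
                             batch_size=self.batch_size,
                             seed=self.seed + p)
            layer.fit(data)
            data = layer.transform(data)
            self.layers_.append(layer)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "layers_")
        data = _dense01(X)
        for layer in self.layers_:
            data = layer.transform(data)
        return data


def dbn_features(model: DBNFeatures, v) -> np.ndarray:
    """Top-layer activation vector(s) for count input ``v``."""
    v = np.atleast_2d(_dense(v))
    return model.transform(v)


@dataclass
class SoftmaxHead:
    """Softmax regression parameters: one weight vector s_t per subtopic."""

    weights: np.ndarray  # (l, d)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] < 2:
            raise ValueError("head needs an (l >= 2, d) weight matrix")

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]


def softmax_forward(head: SoftmaxHead, m: np.ndarray) -> np.ndarray:
    """Class probabilities h[t] = exp(s_t . m) / sum_u exp(s_u . m)."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite input")
    if m.ndim == 1:
        return softmax(head.weights @ m)
    return softmax(m @ head.weights.T, axis=1)


@dataclass
class FinetuneConfig:
    """Fine-tuning settings: penalty factor lambda (default 2), stored
    L-BFGS update memory m (default 6), optimizer choice, and stopping
    rules. ``update_layers`` backpropagates into the RBM weights; the
    default trains the head only."""

    penalty: float = 2.0
    memory: int = 6
    optimizer: str = "l-bfgs"  # or "gradient-descent"
    max_iter: int = 200
    tol: float = 1e-7
    update_layers: bool = False

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.memory < 1:
            raise ValueError("memory must be >= 1")
        if self.optimizer not in ("l-bfgs", "gradient-descent"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _one_hot(y: np.ndarray, l: int) -> np.ndarray:
    Y = np.zeros((len(y), l))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def finetune_cost(head_w: np.ndarray, M: np.ndarray, Y: np.ndarray,
                  penalty: float, theta_sq: float = 0.0
                  ) -> Tuple[float, np.ndarray]:
    """Cost J(s) and its analytic gradient for fixed features M.

    ``theta_sq`` carries sum_p ||theta_p||^2 of the (frozen) RBM weights
    so the reported cost matches the full objective.
    """
    n = M.shape[0]
    P = softmax(M @ head_w.T, axis=1)
    ce = -np.sum(Y * np.log(np.clip(P, 1e-300, None))) / n
    J = ce + 0.5 * penalty * float(np.sum(head_w ** 2)) \
        + 0.5 * penalty * theta_sq
    grad = (P - Y).T @ M / n + penalty * head_w
    return J, grad


def _deep_cost_grad(params: Dict[str, np.ndarray], X01: np.ndarray,
                    Y: np.ndarray, penalty: float
                    ) -> Tuple[float, Dict[str, np.ndarray]]:
    """Full-objective cost/gradient when the RBM stack is unfrozen."""
    Ws, cs, S = params["Ws"], params["cs"], params["S"]
    acts = [X01]
    a = X01
    for W, c in zip(Ws, cs):
        a = expit(a @ W + c)
        acts.append(a)
    n = X01.shape[0]
    P = softmax(a @ S.T, axis=1)
    ce = -np.sum(Y * np.log(np.clip(P, 1e-300, None))) / n
    J = ce + 0.5 * penalty * (float(np.sum(S ** 2))
                              + sum(float(np.sum(W ** 2)) for W in Ws))
    dlog = (P - Y) / n
    dS = dlog.T @ acts[-1] + penalty * S
    da = dlog @ S
    dWs, dcs = [], []
    for p in range(len(Ws) - 1, -1, -1):
        dz = da * acts[p + 1] * (1 - acts[p + 1])
        dWs.insert(0, acts[p].T @ dz + penalty * Ws[p])
        dcs.insert(0, dz.sum(axis=0))
        da = dz @ Ws[p].T
    return J, {"Ws": dWs, "cs": dcs, "S": dS}


def finetune(dbn: Optional[DBNFeatures], head: SoftmaxHead,
             X, y: Sequence[int],
             cfg: Optional[FinetuneConfig] = None
             ) -> Tuple[SoftmaxHead, List[float]]:
    """Optimize the fine-tuning objective on labeled data.

    ``X`` is raw count data when a DBN is given (features are its
    mean-field output), else the feature matrix itself. ``y`` holds class
    indices in ``0..l-1``. Returns the optimized head and the cost trace,
    which is non-increasing for the line-searched gradient-descent path.
    """
    cfg = cfg or FinetuneConfig()
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty labeled subset")
    if y.min() < 0 or y.max() >= head.n_classes:
        raise ValueError("labels out of range")
    Y = _one_hot(y, head.n_classes)
    if cfg.update_layers:
        if dbn is None:
            raise ValueError("update_layers requires a DBN")
        return _finetune_deep(dbn, head, _dense01(X), Y, cfg)
    if dbn is not None:
        M = dbn.transform(X)
    else:
        M = _dense(X)
    theta_sq = 0.0
    if dbn is not None:
        theta_sq = sum(float(np.sum(l.weights_ ** 2)) for l in dbn.layers_)
    fun = lambda w: finetune_cost(
        w.reshape(head.weights.shape), M, Y, cfg.penalty, theta_sq)
    trace: List[float] = []
    if cfg.optimizer == "l-bfgs":
        def f(w):
            J, g = fun(w)
            trace.append(J)
            return J, g.ravel()
        res = minimize(f, head.weights.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxcor": cfg.memory, "maxiter": cfg.max_iter,
                                "ftol": cfg.tol, "gtol": 1e-9})
        w = res.x.reshape(head.weights.shape)
        trace.append(float(res.fun))  # cost at the returned parameters
    else:
        w = head.weights.copy()
        J, g = fun(w.ravel())
        trace.append(J)
        step = 1.0
        for _ in range(cfg.max_iter):
            # backtracking line search keeps the trace non-increasing
            for _ in range(60):
                J_new, g_new = fun((w - step * g.reshape(w.shape)).ravel())
                if J_new <= J:
                    break
                step *= 0.5
            else:
                raise StepSizeError(
                    "gradient descent diverged: no decreasing step found; "
                    "reduce the penalty or rescale the features")
            w = w - step * g.reshape(w.shape)
            trace.append(J_new)
            if J - J_new < cfg.tol:
                J, g = J_new, g_new
                break
            J, g = J_new, g_new
            step *= 1.5
    return SoftmaxHead(w), trace


def _finetune_deep(dbn: DBNFeatures, head: SoftmaxHead, X01, Y, cfg
                   ) -> Tuple[SoftmaxHead, List[float]]:
    params = {
        "Ws": [l.weights_.copy() for l in dbn.layers_],
        "cs": [l.hidden_bias_.copy() for l in dbn.layers_],
        "S": head.weights.copy(),
    }
    trace: List[float] = []
    J, grads = _deep_cost_grad(params, X01, Y, cfg.penalty)
    trace.append(J)
    step = 0.1
    for _ in range(cfg.max_iter):
        for _ in range(60):
            trial = {
                "Ws": [W - step * dW for W, dW in zip(params["Ws"],
                                                      grads["Ws"])],
                "cs": [c - step * dc for c, dc in zip(params["cs"],
                                                      grads["cs"])],
                "S": params["S"] - step * grads["S"],
            }
            J_new, g_new = _deep_cost_grad(trial, X01, Y, cfg.penalty)
            if J_new <= J:
                break
            step *= 0.5
        else:
            raise StepSizeError("deep fine-tuning diverged")
        params, grads = trial, g_new
        trace.append(J_new)
        if J - J_new < cfg.tol:
            break
        J = J_new
        step *= 1.5
    for layer, W, c in zip(dbn.layers_, params["Ws"], params["cs"]):
        layer.weights_ = W
        layer.hidden_bias_ = c
    return SoftmaxHead(params["S"]), trace


def discover_subtopics(features: np.ndarray, k: int, seed: int = 0
                       ) -> np.ndarray:
    """Seeded k-means partition of DBN feature vectors into k pseudo-
    subtopics; returns a cluster index per message."""
    features = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > features.shape[0]:
        raise ValueError("k exceeds the number of messages")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(features)


def label_clusters(assignments: np.ndarray,
                   token_lists: Sequence[Sequence[str]]) -> Dict[int, str]:
    """Name each cluster by its highest-lift token (in-cluster frequency
    over corpus frequency); ties break lexicographically."""
    overall: Dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            overall[t] = overall.get(t, 0) + 1
    n_total = len(token_lists)
    labels: Dict[int, str] = {}
    for c in np.unique(assignments):
        idx = np.flatnonzero(assignments == c)
        counts: Dict[str, int] = {}
        for i in idx:
            for t in set(token_lists[i]):
                counts[t] = counts.get(t, 0) + 1
        best, best_lift = f"cluster{c}", -1.0
        for t, cnt in sorted(counts.items()):
            lift = (cnt / len(idx)) / (overall[t] / n_total)
            if lift > best_lift:
                best, best_lift = t, lift
        labels[int(c)] = best
    return labels


@dataclass
class SubtopicRanking:
    """Descending percentage of a topic's messages per subtopic."""

    topic: str
    entries: List[Tuple[str, float]] = field(default_factory=list)


def rank_subtopics(assignments: Sequence[str], topic: str
                   ) -> SubtopicRanking:
    """Percentage of the topic's messages per subtopic, two decimals,
    descending (e.g. ``flu (3.50)``)."""
    assignments = list(assignments)
    if not assignments:
        raise ValueError(f"no assignments for topic {topic!r}")
    n = len(assignments)
    counts: Dict[str, int] = {}
    for s in assignments:
        counts[s] = counts.get(s, 0) + 1
    entries = sorted(
        ((s, round(100.0 * c / n, 2)) for s, c in counts.items()),
        key=lambda e: (-e[1], e[0]),
    )
    return SubtopicRanking(topic=topic, entries=entries)


class SubtopicModel(BaseEstimator):
    """End-to-end subtopic pipeline for one topic's messages.

    fit: build a vocabulary, train the RBM stack, cluster the DBN
    features into ``k`` pseudo-subtopics, name the clusters by lift, and
    fine-tune the softmax head on the pseudo-labels. predict: DBN
    features -> softmax head -> cluster name.
    """

    def __init__(self, k: int = 100, layer_sizes: Tuple[int, ...] = (64, 32),
                 epochs: int = 15, learning_rate: float = 0.05,
                 penalty: float = 2.0, memory: int = 6,
                 optimizer: str = "l-bfgs", max_vocabulary: int = 2000,
                 min_token_count: int = 2, seed: int = 0):
        self.k = k
        self.layer_sizes = layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.penalty = penalty
        self.memory = memory
        self.optimizer = optimizer
        self.max_vocabulary = max_vocabulary
        self.min_token_count = min_token_count
        self.seed = seed

    def fit(self, X: Sequence[Sequence[str]], y=None) -> "SubtopicModel":
        X = list(X)
        k = min(self.k, len(X))
        if k < 2:
            raise ValueError("need at least 2 messages")
        self.vocabulary_ = build_vocabulary(X, self.min_token_count,
                                            self.max_vocabulary)
        M = to_matrix(X, self.vocabulary_)
        self.dbn_ = DBNFeatures(self.layer_sizes, epochs=self.epochs,
                                learning_rate=self.learning_rate,
                                seed=self.seed)
        self.dbn_.fit(M)
        feats = self.dbn_.transform(M)
        assign = discover_subtopics(feats, k, seed=self.seed)
        self.cluster_names_ = label_clusters(assign, X)
        head = SoftmaxHead(np.zeros((k, feats.shape[1])))
        cfg = FinetuneConfig(penalty=self.penalty, memory=self.memory,
                             optimizer=self.optimizer)
        self.head_, self.cost_trace_ = finetune(None, head, feats, assign,
                                                cfg)
        return self

    def predict(self, X: Sequence[Sequence[str]]) -> List[str]:
        check_is_fitted(self, "head_")
        M = to_matrix(list(X), self.vocabulary_)
        P = softmax_forward(self.head_, self.dbn_.transform(M))
        return [self.cluster_names_[int(i)] for i in np.argmax(P, axis=1)]
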