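"""Ten-class topic classification over bag-of-words message vectors.

Each topic class x carries a weight vector w_x over a fixed vocabulary;
a message with feature vector t is scored P(x|t) proportional to
exp(sum_i w_xi t_i), normalized over the classes (multinomial logistic
regression). Training minimises the L2-penalised cross-entropy; model
selection uses seeded stratified 10-fold cross-validation and the final
report an 80/20 holdout.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .metrics import multiclass_report

__all__ = [
    "build_vocabulary",
    "vectorize",
    "TopicClassifier",
    "train_topic_classifier",
    "topic_prevalence",
]


def build_vocabulary(token_lists: Sequence[Sequence[str]],
                     min_count: int = 5,
                     max_size: int = 2000) -> Dict[str, int]:
    """Training vocabulary: tokens seen at least ``min_count`` times,
    most frequent first, capped at ``max_size`` (the DBN input width)."""
    counts: Dict[str, int] = {}
    for toks in token_lists:
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    keep = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )[:max_size]
    return {t: i for i, t in enumerate(keep)}


def vectorize(tokens: Sequence[str],
              vocabulary: Dict[str, int]) -> Dict[int, int]:
    """Sparse token-count vector; out-of-vocabulary tokens are dropped."""
    if not vocabulary:
        raise ValueError("empty vocabulary")
    v: Dict[int, int] = {}
    for t in tokens:
        i = vocabulary.get(t)
        if i is not None:
            v[i] = v.get(i, 0) + 1
    return v


def to_matrix(token_lists: Sequence[Sequence[str]],
              vocabulary: Dict[str, int]) -> sp.csr_matrix:
    """Stack count vectors into a CSR document-term matrix."""
    if not vocabulary:
        raise ValueError("empty vocabulary")
    rows, cols, data = [], [], []
    for r, toks in enumerate(token_lists):
        for i, c in vectorize(toks, vocabulary).items():
            rows.append(r)
            cols.append(i)
            data.append(c)
    return sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(token_lists), len(vocabulary)),
        dtype=float,
    )


class TopicClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logistic topic classifier over token-count features.

    Parameters
    ----------
    min_token_count : minimum training frequency for a vocabulary token.
    max_vocabulary : vocabulary cap (ties the feature width to the DBN
        input width downstream).
    C : inverse L2 regularisation strength passed to the solver.
    seed : seeds fold assignment and the solver.

    Attributes (after ``fit``)
    --------------------------
    vocabulary_ : token -> column index map.
    classes_ : class labels in weight-row order.
    weights_ : (n_classes, d) class weight matrix w_x.
    intercept_ : (n_classes,) bias terms.
    """

    def __init__(self, min_token_count: int = 5, max_vocabulary: int = 2000,
                 C: float = 1.0, seed: int = 0):
        self.min_token_count = min_token_count
        self.max_vocabulary = max_vocabulary
        self.C = C
        self.seed = seed

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[str]
            ) -> "TopicClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate training set: a single class")
        self.vocabulary_ = build_vocabulary(
            X, self.min_token_count, self.max_vocabulary)
        if not self.vocabulary_:
            raise ValueError(
                "empty vocabulary: no token reaches min_token_count")
        M = to_matrix(X, self.vocabulary_)
        lr = LogisticRegression(C=self.C, max_iter=1000,
                                random_state=self.seed)
        lr.fit(M, y)
        self.classes_ = lr.classes_
        if lr.coef_.shape[0] == 1:
            # binary fits return one row; expand to per-class softmax form
            self.weights_ = np.vstack([-lr.coef_ / 2, lr.coef_ / 2])
            self.intercept_ = np.concatenate([-lr.intercept_ / 2,
                                              lr.intercept_ / 2])
        else:
            self.weights_ = lr.coef_
            self.intercept_ = lr.intercept_
        return self

    def decision_scores(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        check_is_fitted(self, "weights_")
        M = to_matrix(X, self.vocabulary_)
        return M @ self.weights_.T + self.intercept_

    def predict_proba(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        """Normalized exponential of the per-class weighted sums."""
        return softmax(self.decision_scores(X), axis=1)

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]

    def predict_topic(self, v: Dict[int, int]) -> Dict[str, float]:
        """Class-probability map for one sparse feature vector."""
        check_is_fitted(self, "weights_")
        d = self.weights_.shape[1]
        if any(i >= d for i in v):
            raise ValueError("feature index exceeds model dimension")
        x = np.zeros(d)
        for i, c in v.items():
            x[i] = c
        p = softmax(self.weights_ @ x + self.intercept_)
        return dict(zip(self.classes_, p))


def train_topic_classifier(
    X: Sequence[Sequence[str]],
    y: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    holdout: float = 0.2,
    **params,
) -> Tuple[TopicClassifier, pd.DataFrame]:
    """Cross-validated training: seeded stratified k-fold CV for model
    assessment, then a fit on the 80% split with a 20% holdout report,
    and a final fit on everything.

    Returns the final model and a per-fold metric table (accuracy,
    macro sensitivity / F-measure / G-mean) with the holdout row appended.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: a single class")
    X = list(X)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        clf = TopicClassifier(seed=seed, **params)
        clf.fit([X[i] for i in tr], y[tr])
        rep = multiclass_report(y[te], clf.predict([X[i] for i in te]))
        rows.append({"fold": k, **rep})
    tr, te = train_test_split(np.arange(len(y)), test_size=holdout,
                              random_state=seed, stratify=y)
    clf = TopicClassifier(seed=seed, **params)
    clf.fit([X[i] for i in tr], y[tr])
    rows.append({"fold": "holdout",
                 **multiclass_report(y[te], clf.predict([X[i] for i in te]))})
    final = TopicClassifier(seed=seed, **params).fit(X, y)
    return final, pd.DataFrame(rows)


def topic_prevalence(predictions: Sequence[str],
                     min_percent: float = 2.0) -> Dict[str, float]:
    """Percentage of messages per topic; topics under ``min_percent`` are
    disregarded in the report but still count in the denominator."""
    preds = list(predictions)
    if not preds:
        raise ValueError("no predictions")
    n = len(preds)
    counts: Dict[str, int] = {}
    for p in preds:
        counts[p] = counts.get(p, 0) + 1
    pct = {t: 100.0 * c / n for t, c in counts.items()}
    return {t: v for t, v in sorted(pct.items(), key=lambda kv: -kv[1])
            if v >= min_percent}
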