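"""Hierarchical (tree-grown) affect analyzer for six-emotion labelling.

The classifier starts from a root and grows as vocabulary words arrive:
for each word the softmax likelihoods of the current node's children are
sorted (o1 >= o2 >= o3) and one of three structural actions fires —

* add_to_child   when o1 - o2 > alpha (strong association, node not full);
* merge_children when o1 - o2 < alpha and o2 - o3 > beta (two children
  claim the word; they merge into a new child that receives it);
* new_child      when o1 - o2 < alpha and o2 - o3 < beta, or the node is
  full (the tree expands horizontally).

Equality on either threshold resolves to new_child, the most conservative
structural action. Depth and per-branch child capacity are hard limits;
every decision is recorded in a construction log for auditability.

Words are embedded by their per-emotion co-occurrence profile, so words
used in similar emotional contexts group under the same child. Node
classifiers are softmax scorers over bag-of-token features trained by
mini-batch SGD with momentum and weight decay (a width-3 convolutional
token-window variant over the profile embeddings is config-exposed);
leaves carry emotion heads. The final label maps to a polarity:
joy/surprise positive (surprise configurable), anger/disgust/fear/sadness
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .stream import EMOTIONS

__all__ = [
    "GrowthDecision",
    "TreeNode",
    "TreeConfig",
    "grow_decision",
    "build_tree",
    "TreeCNNEmotionClassifier",
    "polarity_of",
    "DEFAULT_POLARITY",
]

DEFAULT_POLARITY = {
    "joy": "positive", "surprise": "positive",
    "anger": "negative", "disgust": "negative",
    "fear": "negative", "sadness": "negative",
}


def polarity_of(emotion: str,
                mapping: Optional[Dict[str, str]] = None) -> str:
    mapping = mapping or DEFAULT_POLARITY
    if emotion not in mapping:
        raise ValueError(f"no polarity configured for {emotion!r}")
    return mapping[emotion]


@dataclass(frozen=True)
class GrowthDecision:
    """Outcome of the three growth rules for one insertion."""

    o: Tuple[float, float, float]
    action: str  # add_to_child | merge_children | new_child
    boundary: bool = False


def grow_decision(o: Sequence[float], alpha: float, beta: float,
                  node_full: bool) -> GrowthDecision:
    """Apply the growth rules to sorted top-3 softmax outputs.

    ``o`` must be sorted descending with sum <= 1 (pad with zeros when a
    node has fewer than three children). A full node always grows
    horizontally; threshold equalities resolve to new_child.
    """
    o1, o2, o3 = (float(x) for x in o)
    if not (o1 >= o2 >= o3):
        raise ValueError("softmax outputs must be sorted descending")
    if o1 + o2 + o3 > 1 + 1e-9:
        raise ValueError("top-3 softmax outputs exceed 1")
    if node_full:
        return GrowthDecision((o1, o2, o3), "new_child")
    d12, d23 = o1 - o2, o2 - o3
    eps = 1e-9  # threshold equality, up to float noise
    if abs(d12 - alpha) <= eps or (d12 < alpha and abs(d23 - beta) <= eps):
        return GrowthDecision((o1, o2, o3), "new_child", boundary=True)
    if d12 > alpha:
        return GrowthDecision((o1, o2, o3), "add_to_child")
    if d23 > beta:
        return GrowthDecision((o1, o2, o3), "merge_children")
    return GrowthDecision((o1, o2, o3), "new_child")


@dataclass
class TreeConfig:
    alpha: float = 0.1
    beta: float = 0.1
    max_depth: int = 3
    max_children: int = 5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.max_depth < 1 or self.max_children < 1:
            raise ValueError("max_depth and max_children must be >= 1")


class TreeNode:
    """A tree node holding member words and a prototype embedding."""

    __slots__ = ("name", "depth", "children", "words", "prototype",
                 "_wsum", "_wcount", "classifier", "emotion_head")

    def __init__(self, name: str, depth: int, dim: int):
        self.name = name
        self.depth = depth
        self.children: List["TreeNode"] = []
        self.words: List[str] = []
        self._wsum = np.zeros(dim)
        self._wcount = 0
        self.prototype = np.zeros(dim)
        self.classifier = None
        self.emotion_head = None

    def add_word(self, word: str, emb: np.ndarray) -> None:
        self.words.append(word)
        self._wsum += emb
        self._wcount += 1
        self.prototype = self._wsum / self._wcount

    def subtree_words(self) -> List[str]:
        out = list(self.words)
        for c in self.children:
            out.extend(c.subtree_words())
        return out

    def max_depth(self) -> int:
        return max([self.depth] + [c.max_depth() for c in self.children])


def _child_softmax(node: TreeNode, emb: np.ndarray
                   ) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    scores = np.array([c.prototype @ emb for c in node.children])
    p = softmax(scores)
    top = sorted(p, reverse=True)[:3]
    while len(top) < 3:
        top.append(0.0)
    return p, (float(top[0]), float(top[1]), float(top[2]))


def build_tree(words: Sequence[Tuple[str, np.ndarray]],
               cfg: Optional[TreeConfig] = None
               ) -> Tuple[TreeNode, List[dict]]:
    """Grow the tree by routing embedded words through the growth rules.

    Returns the root and the construction log (one record per decision:
    word, node path, sorted outputs, action taken, including the
    documented fallbacks at the depth/capacity limits). Structural
    invariants — depth <= max_depth, children per branch <= max_children
    — hold after every insertion.
    """
    cfg = cfg or TreeConfig()
    words = list(words)
    if not words:
        raise ValueError("empty word stream")
    dim = len(words[0][1])
    root = TreeNode("root", 0, dim)
    log: List[dict] = []
    counter = [0]

    def new_node(parent: TreeNode, word: str, emb: np.ndarray) -> TreeNode:
        counter[0] += 1
        node = TreeNode(f"n{counter[0]}", parent.depth + 1, dim)
        node.add_word(word, emb)
        parent.children.append(node)
        return node

    for word, emb in words:
        emb = np.asarray(emb, dtype=float)
        node = root
        path = "root"
        while True:
            if not node.children:
                if node.depth >= cfg.max_depth:
                    node.add_word(word, emb)  # leaf at the depth cap
                    log.append({"word": word, "node": path, "o": None,
                                "action": "absorb_at_depth_cap"})
                    break
                new_node(node, word, emb)
                log.append({"word": word, "node": path, "o": None,
                            "action": "new_child"})
                break
            raw = [c.prototype @ emb for c in node.children]
            full = len(node.children) >= cfg.max_children
            if max(raw) <= 0.0:
                # the word has no likelihood under any child: the
                # structure grows (horizontally if there is room)
                dec = GrowthDecision((0.0, 0.0, 0.0), "new_child")
                o = dec.o
            else:
                _, o = _child_softmax(node, emb)
                dec = grow_decision(o, cfg.alpha, cfg.beta, node_full=full)
            best = node.children[int(np.argmax(raw))]
            if dec.action == "add_to_child":
                if best.children:
                    log.append({"word": word, "node": path, "o": o,
                                "action": "descend"})
                    node, path = best, f"{path}/{best.name}"
                    continue
                best.add_word(word, emb)
                log.append({"word": word, "node": path, "o": o,
                            "action": "add_to_child"})
                break
            if dec.action == "merge_children" and _can_merge(node, cfg):
                merged = _merge_top2(node, emb, counter)
                merged.add_word(word, emb)
                log.append({"word": word, "node": path, "o": o,
                            "action": "merge_children"})
                break
            # new_child (or merge blocked by the depth cap)
            if full:
                if best.depth >= cfg.max_depth or not best.children:
                    if best.depth >= cfg.max_depth:
                        best.add_word(word, emb)
                        log.append({"word": word, "node": path, "o": o,
                                    "action": "add_to_child_full"})
                        break
                log.append({"word": word, "node": path, "o": o,
                            "action": "descend_full"})
                node, path = best, f"{path}/{best.name}"
                continue
            new_node(node, word, emb)
            log.append({"word": word, "node": path, "o": o,
                        "action": "new_child"})
            break
    return root, log


def _can_merge(node: TreeNode, cfg: TreeConfig) -> bool:
    if len(node.children) < 2:
        return False
    depths = sorted(node.children, key=lambda c: -_score_rank(c))
    top2 = depths[:2]
    # moving the pair one level down must not breach the depth cap
    return max(c.max_depth() for c in top2) + 1 <= cfg.max_depth


def _score_rank(c: TreeNode) -> float:
    return float(np.linalg.norm(c.prototype))


def _merge_top2(node: TreeNode, emb: np.ndarray, counter: List[int]
                ) -> TreeNode:
    """Merge the two children most associated with the word into a new
    child node; the pair become its children one level deeper."""
    scores = [c.prototype @ emb for c in node.children]
    order = np.argsort(scores)[::-1]
    a, b = node.children[order[0]], node.children[order[1]]
    counter[0] += 1
    dim = len(emb)
    merged = TreeNode(f"n{counter[0]}", node.depth + 1, dim)
    for child in (a, b):
        node.children.remove(child)
        _reroot(child, merged.depth + 1)
        merged.children.append(child)
        merged._wsum += child._wsum
        merged._wcount += max(child._wcount, 1)
    if merged._wcount:
        merged.prototype = merged._wsum / merged._wcount
    node.children.append(merged)
    return merged


def _reroot(node: TreeNode, depth: int) -> None:
    node.depth = depth
    for c in node.children:
        _reroot(c, depth + 1)


# ---------------------------------------------------------------------------
# trainable classifier over the grown tree


def _sgd_softmax(X: np.ndarray, y: np.ndarray, n_classes: int, epochs: int,
                 lr: float, momentum: float, weight_decay: float,
                 batch_size: int, rng: np.random.Generator
                 ) -> Tuple[np.ndarray, np.ndarray, List[float]]:
    """Mini-batch SGD with classical momentum and L2 weight decay on a
    linear softmax scorer; returns weights, bias and per-epoch loss."""
    n, d = X.shape
    W = rng.normal(0.0, 0.01, size=(n_classes, d))
    b = np.zeros(n_classes)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            Xb, yb = X[idx], y[idx]
            P = softmax(Xb @ W.T + b, axis=1)
            epoch_loss += -float(np.sum(
                np.log(np.clip(P[np.arange(len(yb)), yb], 1e-300, None))))
            G = P.copy()
            G[np.arange(len(yb)), yb] -= 1.0
            gW = G.T @ Xb / len(yb) + weight_decay * W
            gb = G.mean(axis=0)
            vW = momentum * vW - lr * gW
            vb = momentum * vb - lr * gb
            W = W + vW
            b = b + vb
        losses.append(epoch_loss / n)
    return W, b, losses


class TreeCNNEmotionClassifier(BaseEstimator, ClassifierMixin):
    """Tree-grown hierarchical emotion classifier.

    fit() embeds vocabulary words by their per-emotion co-occurrence
    profiles, grows the tree (most frequent word first — the stream's
    main word seeds the root's first child), then trains a softmax
    routing classifier at each internal node and an emotion head at each
    leaf with mini-batch SGD (momentum 0.9, weight decay 0.001, learning
    rate 0.1 by default). predict() routes each message to a leaf and
    reads its emotion head; classify() adds the polarity.
    """

    def __init__(self, alpha: float = 0.1, beta: float = 0.1,
                 max_depth: int = 3, max_children: int = 5,
                 epochs: int = 50, learning_rate: float = 0.1,
                 momentum: float = 0.9, weight_decay: float = 0.001,
                 batch_size: int = 32, conv_width: int = 1,
                 surprise_positive: bool = True, seed: int = 0):
        self.alpha = alpha
        self.beta = beta
        self.max_depth = max_depth
        self.max_children = max_children
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.conv_width = conv_width
        self.surprise_positive = surprise_positive
        self.seed = seed

    # -- embedding ---------------------------------------------------------

    def _embed_words(self, X, y) -> Tuple[Dict[str, int], np.ndarray,
                                          List[str]]:
        emo_idx = {e: i for i, e in enumerate(EMOTIONS)}
        counts: Dict[str, np.ndarray] = {}
        freq: Dict[str, int] = {}
        for toks, e in zip(X, y):
            for t in toks:
                if t not in counts:
                    counts[t] = np.zeros(len(EMOTIONS))
                counts[t][emo_idx[e]] += 1
                freq[t] = freq.get(t, 0) + 1
        order = sorted(freq, key=lambda t: (-freq[t], t))
        vocab = {t: i for i, t in enumerate(order)}
        emb = np.zeros((len(order), len(EMOTIONS)))
        for t, i in vocab.items():
            v = counts[t]
            emb[i] = v / v.sum()
        return vocab, emb, order

    def _features(self, X) -> np.ndarray:
        """Message features: token-count bag over the training vocabulary
        (conv_width 1), or max-pooled width-3 window responses of fixed
        random filters over the word-profile embedding sequence."""
        V = self.vocabulary_
        if self.conv_width == 1:
            M = np.zeros((len(X), len(V)))
            for r, toks in enumerate(X):
                for t in toks:
                    i = V.get(t)
                    if i is not None:
                        M[r, i] += 1.0
            return M
        F = self.conv_filters_
        dim = self.word_embeddings_.shape[1] * self.conv_width
        out = np.zeros((len(X), F.shape[0]))
        for r, toks in enumerate(X):
            embs = [self.word_embeddings_[V[t]] for t in toks if t in V]
            if len(embs) < self.conv_width:
                continue
            E = np.stack(embs)
            wins = np.stack([
                E[i:i + self.conv_width].ravel()
                for i in range(len(embs) - self.conv_width + 1)
            ])
            out[r] = np.tanh(wins @ F.T).max(axis=0)
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[str]
            ) -> "TreeCNNEmotionClassifier":
        X = [list(t) for t in X]
        y = list(y)
        if len(set(y)) < 2:
            raise ValueError("degenerate training set: a single emotion")
        rng = np.random.default_rng(self.seed)
        self.vocabulary_, self.word_embeddings_, order = self._embed_words(
            X, y)
        if self.conv_width not in (1, 3):
            raise ValueError("conv_width must be 1 or 3")
        if self.conv_width == 3:
            self.conv_filters_ = rng.normal(
                0.0, 1.0, size=(32, self.word_embeddings_.shape[1] * 3))
        cfg = TreeConfig(self.alpha, self.beta, self.max_depth,
                         self.max_children)
        stream = [(t, self.word_embeddings_[self.vocabulary_[t]])
                  for t in order]
        self.tree_, self.construction_log_ = build_tree(stream, cfg)
        self.classes_ = np.array(sorted(set(y)))
        self._train_tokens_ = X
        feats = self._features(X)
        y_arr = np.asarray(y)
        self.loss_trace_ = np.zeros(self.epochs)
        self._train_node(self.tree_, np.arange(len(X)), feats, y_arr, rng)
        self.fallback_emotion_ = max(sorted(set(y)), key=y.count)
        return self

    def _word_route_labels(self, node: TreeNode, X_idx: np.ndarray,
                           feats: np.ndarray) -> np.ndarray:
        """Ground-truth routing label: the child whose subtree vocabulary
        overlaps the message most (ties -> first child)."""
        word_sets = [set(c.subtree_words()) for c in node.children]
        overlaps = np.zeros((len(node.children), len(X_idx)))
        for r, i in enumerate(X_idx):
            toks = self._train_tokens_[i]
            for c_i, ws in enumerate(word_sets):
                overlaps[c_i, r] = sum(1 for t in toks if t in ws)
        return np.argmax(overlaps, axis=0)

    def _train_node(self, node: TreeNode, idx: np.ndarray,
                    feats: np.ndarray, y: np.ndarray,
                    rng: np.random.Generator) -> None:
        if len(idx) == 0:
            return
        if node.children:
            labels = self._word_route_labels(node, idx, feats)
            if len(node.children) >= 2 and len(set(labels.tolist())) >= 2:
                W, b, losses = _sgd_softmax(
                    feats[idx], labels, len(node.children), self.epochs,
                    self.learning_rate, self.momentum, self.weight_decay,
                    self.batch_size, rng)
                node.classifier = (W, b)
                self.loss_trace_ = self.loss_trace_ + np.asarray(losses)
            for c_i, child in enumerate(node.children):
                self._train_node(child, idx[labels == c_i], feats, y, rng)
        else:
            cls_idx = {c: i for i, c in enumerate(self.classes_)}
            labels = np.array([cls_idx[v] for v in y[idx]])
            if len(set(labels.tolist())) >= 2:
                W, b, losses = _sgd_softmax(
                    feats[idx], labels, len(self.classes_), self.epochs,
                    self.learning_rate, self.momentum, self.weight_decay,
                    self.batch_size, rng)
                node.emotion_head = (W, b)
                self.loss_trace_ = self.loss_trace_ + np.asarray(losses)
            else:
                node.emotion_head = str(y[idx][0])

    # -- inference ---------------------------------------------------------

    def _route(self, x: np.ndarray) -> TreeNode:
        node = self.tree_
        while node.children:
            if node.classifier is not None:
                W, b = node.classifier
                node = node.children[int(np.argmax(W @ x + b))]
            else:
                node = node.children[0]
        return node

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        check_is_fitted(self, "tree_")
        feats = self._features([list(t) for t in X])
        out = []
        for x in feats:
            leaf = self._route(x)
            head = leaf.emotion_head
            if head is None:
                out.append(self.fallback_emotion_)
            elif isinstance(head, str):
                out.append(head)
            else:
                W, b = head
                out.append(str(self.classes_[int(np.argmax(W @ x + b))]))
        return np.array(out)

    def classify(self, tokens: Sequence[str]) -> Tuple[str, str]:
        """One message -> (emotion, polarity)."""
        if not tokens:
            raise ValueError("unclassifiable: empty token list")
        emotion = str(self.predict([list(tokens)])[0])
        mapping = dict(DEFAULT_POLARITY)
        mapping["surprise"] = ("positive" if self.surprise_positive
                               else "negative")
        return emotion, polarity_of(emotion, mapping)
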