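"""From-scratch CART trees and a Gini random forest with impurity importance.

The classifier is built from first principles rather than wrapping a library
implementation, because the feature-importance decomposition it reports is
the quantity of interest:

* node impurity is the Gini index  G = 1 - sum_i p(c_i | t)^2;
* a split's quality is the sample-proportion-weighted impurity decrease
  n_ij = w_j G_j - w_jL G_jL - w_jR G_jR;
* per-tree importance of feature i is f_i = (sum of n_ij over nodes that
  split on i) / (sum over all internal nodes), and the forest importance
  F_i is the average of f_i over trees, renormalized to sum to 1.

Trees are grown greedily: at each node a random feature subset is drawn,
candidate thresholds are the midpoints of consecutive distinct sorted
values, and the threshold maximizing the impurity decrease wins.  Each tree
trains on a bootstrap resample of size n.  Prediction is by plurality vote;
vote fractions double as class scores for ROC analysis.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba``, ``get_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "gini",
    "impurity_decrease",
    "best_split",
    "SplitRule",
    "Tree",
    "GiniDecisionTreeClassifier",
    "GiniRandomForestClassifier",
    "grow_tree",
    "fit_forest",
    "predict",
    "predict_vote_fractions",
    "feature_importance",
    "forest_to_json",
    "forest_from_json",
]

# Impurity decreases below this are numerical dust, not real splits.
_MIN_DECREASE = 1e-12


def gini(class_counts) -> float:
    """Gini impurity 1 - sum p_i^2 of a node's class-count vector.

    0 for a pure node; 1 - 1/k for a uniform mix of k classes.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("Gini impurity undefined for an empty node")
    p = counts / total
    return float(1.0 - np.sum(p**2))


def impurity_decrease(parent_counts, left_counts, right_counts, weight: float = 1.0) -> float:
    """Weighted impurity decrease n_ij of one split.

    ``weight`` is the parent node's sample proportion w_j (fraction of the
    tree's training instances reaching it); children inherit weights in
    proportion to their sample counts, so

        n_ij = w_j G_j - w_jL G_jL - w_jR G_jR.
    """
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("child class counts must sum to the parent's")
    n = parent.sum()
    wl = weight * left.sum() / n
    wr = weight * right.sum() / n
    return float(weight * gini(parent) - wl * gini(left) - wr * gini(right))


@dataclass(frozen=True)
class SplitRule:
    """Axis-aligned split: left child takes instances with x[feature] <= threshold."""

    feature: int
    threshold: float
    decrease: float = 0.0


def _one_hot(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    oh = np.zeros((y_codes.size, n_classes))
    oh[np.arange(y_codes.size), y_codes] = 1.0
    return oh


def _search_split(
    X: np.ndarray,
    y_onehot: np.ndarray,
    idx: np.ndarray,
    features: np.ndarray,
) -> SplitRule | None:
    """Best midpoint split over ``features`` for the instances in ``idx``.

    Returns None when no candidate yields a positive impurity decrease
    (constant features or a pure node).  Deterministic: features are scanned
    in ascending index order and only strictly better decreases replace the
    incumbent, so ties go to the lowest feature index / lowest threshold.
    """
    n = idx.size
    oh = y_onehot[idx]
    total = oh.sum(axis=0)
    g_parent = 1.0 - np.sum((total / n) ** 2)
    best: SplitRule | None = None
    n_left = np.arange(1, n)
    n_right = n - n_left
    for f in np.sort(features):
        x = X[idx, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        valid = xs[:-1] < xs[1:]
        if not valid.any():
            continue
        left = np.cumsum(oh[order], axis=0)[:-1]
        right = total - left
        g_left = 1.0 - np.sum(left**2, axis=1) / n_left**2
        g_right = 1.0 - np.sum(right**2, axis=1) / n_right**2
        dec = g_parent - (n_left * g_left + n_right * g_right) / n
        dec[~valid] = -np.inf
        i = int(np.argmax(dec))
        if dec[i] > _MIN_DECREASE and (best is None or dec[i] > best.decrease):
            best = SplitRule(
                feature=int(f),
                threshold=float(0.5 * (xs[i] + xs[i + 1])),
                decrease=float(dec[i]),
            )
    return best


def best_split(X, y, candidate_features=None) -> SplitRule | None:
    """Best Gini split of a node's data over the candidate features."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _, y_codes = np.unique(np.asarray(y), return_inverse=True)
    n_classes = int(y_codes.max()) + 1
    if candidate_features is None:
        candidate_features = np.arange(X.shape[1])
    return _search_split(
        X,
        _one_hot(y_codes, n_classes),
        np.arange(X.shape[0]),
        np.asarray(candidate_features, dtype=int),
    )


@dataclass
class Tree:
    """Flat-array CART tree.

    ``feature[i] == -1`` marks a leaf.  ``counts`` holds the class-count
    vector of each node over the tree's own training set; node weights
    w_j = counts[j].sum() / counts[0].sum().
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray
    leaf_class: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def node_depth(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes, dtype=int)
        for j in range(self.n_nodes):
            for child in (self.left[j], self.right[j]):
                if child >= 0:
                    depth[child] = depth[j] + 1
        return depth

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.intp)
        while True:
            internal = self.feature[idx] >= 0
            if not internal.any():
                return self.leaf_class[idx]
            rows = np.flatnonzero(internal)
            node = idx[rows]
            go_left = X[rows, self.feature[node]] <= self.threshold[node]
            idx[rows] = np.where(go_left, self.left[node], self.right[node])

    def importances(self, n_features: int) -> np.ndarray:
        """Per-tree impurity importance f_i (sums to 1, or all zero for a stump)."""
        n_root = self.counts[0].sum()
        contrib = np.zeros(n_features)
        for j in range(self.n_nodes):
            if self.feature[j] < 0:
                continue
            w = self.counts[j].sum() / n_root
            n_ij = impurity_decrease(
                self.counts[j], self.counts[self.left[j]], self.counts[self.right[j]], weight=w
            )
            contrib[self.feature[j]] += n_ij
        total = contrib.sum()
        return contrib / total if total > 0 else contrib

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "counts": self.counts.tolist(),
            "leaf_class": self.leaf_class.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=int),
            right=np.asarray(d["right"], dtype=int),
            counts=np.asarray(d["counts"], dtype=float),
            leaf_class=np.asarray(d["leaf_class"], dtype=int),
        )


def _grow(
    X: np.ndarray,
    y_codes: np.ndarray,
    n_classes: int,
    max_depth: int | None,
    min_samples_split: int,
    max_features: int,
    rng: np.random.Generator,
) -> Tree:
    n_total_features = X.shape[1]
    y_onehot = _one_hot(y_codes, n_classes)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    counts: list[np.ndarray] = []
    leaf_class: list[int] = []

    # stack of (instance indices, depth, parent node id, is_left_child)
    stack: list[tuple[np.ndarray, int, int, bool]] = [(np.arange(X.shape[0]), 0, -1, False)]
    while stack:
        idx, depth, parent, is_left = stack.pop()
        node_id = len(feature)
        if parent >= 0:
            (left if is_left else right)[parent] = node_id
        node_counts = y_onehot[idx].sum(axis=0)
        counts.append(node_counts)
        # plurality with ties to the lowest class index
        leaf_class.append(int(np.argmax(node_counts)))

        rule = None
        can_split = (
            idx.size >= min_samples_split
            and (max_depth is None or depth < max_depth)
            and np.count_nonzero(node_counts) > 1
        )
        if can_split:
            cand = rng.choice(n_total_features, size=max_features, replace=False)
            rule = _search_split(X, y_onehot, idx, cand)
        if rule is None:
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            continue
        feature.append(rule.feature)
        threshold.append(rule.threshold)
        left.append(-1)
        right.append(-1)
        mask = X[idx, rule.feature] <= rule.threshold
        # push right first so the left child is materialized first (stable ids)
        stack.append((idx[~mask], depth + 1, node_id, False))
        stack.append((idx[mask], depth + 1, node_id, True))

    return Tree(
        feature=np.asarray(feature, dtype=int),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=int),
        right=np.asarray(right, dtype=int),
        counts=np.vstack(counts),
        leaf_class=np.asarray(leaf_class, dtype=int),
    )


def _check_Xy(X, y=None, n_features: int | None = None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
    if X.shape[0] == 0:
        raise ValueError("cannot fit/predict on an empty dataset")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"X has {X.shape[1]} features but the model was fitted with {n_features}"
        )
    if y is None:
        return X
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    return X, y


def _class_order(labels) -> list:
    """Fixed class order: case-insensitive alphabetical (BCC < melanoma < normal < SCC)."""
    return sorted(set(labels), key=lambda v: (str(v).lower(), str(v)))


def _resolve_max_features(max_features, n_features: int) -> int:
    if max_features is None:
        return n_features
    if max_features == "sqrt":
        return max(1, int(np.floor(np.sqrt(n_features))))
    mf = int(max_features)
    if not 1 <= mf <= n_features:
        raise ValueError(f"max_features={max_features} outside [1, {n_features}]")
    return mf


class GiniDecisionTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy CART classifier with Gini splitting and midpoint thresholds.

    Parameters
    ----------
    max_depth : int or None
        Maximum tree depth; ``0`` yields a single majority-vote leaf.
    min_samples_split : int
        Smallest node that may be split further.
    max_features : int, "sqrt" or None
        Size of the random feature subset drawn afresh at each node;
        None uses all features (plain CART).
    random_state : int, Generator or None
        Seeds the feature-subset draws.
    """

    def __init__(self, max_depth=None, min_samples_split=2, max_features=None, random_state=None):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        self.classes_ = np.asarray(_class_order(y))
        lookup = {c: i for i, c in enumerate(self.classes_)}
        y_codes = np.fromiter((lookup[v] for v in y), dtype=int, count=len(y))
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.tree_ = _grow(
            X,
            y_codes,
            len(self.classes_),
            self.max_depth,
            self.min_samples_split,
            _resolve_max_features(self.max_features, X.shape[1]),
            rng,
        )
        self.feature_importances_ = self.tree_.importances(self.n_features_in_)
        return self

    def predict(self, X):
        X = _check_Xy(X, n_features=self.n_features_in_)
        return self.classes_[self.tree_.predict_codes(X)]

    def get_depth(self) -> int:
        return int(self.tree_.node_depth().max())


class GiniRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Bootstrap ensemble of Gini CART trees voting by plurality.

    Defaults mirror the study configuration for the skin-tissue problem:
    220 trees of depth at most 14 with floor(sqrt(n_features)) candidate
    features per split.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray
        Class labels in fixed (case-insensitive alphabetical) order.
    feature_importances_ : ndarray
        Mean per-tree impurity importance, renormalized to sum to 1.
    """

    def __init__(
        self,
        n_estimators: int = 220,
        max_depth: int | None = 14,
        min_samples_split: int = 2,
        max_features="sqrt",
        bootstrap: bool = True,
        random_state=None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        self.classes_ = np.asarray(_class_order(y))
        lookup = {c: i for i, c in enumerate(self.classes_)}
        y_codes = np.fromiter((lookup[v] for v in y), dtype=int, count=len(y))
        self.n_features_in_ = X.shape[1]
        n = X.shape[0]
        k = len(self.classes_)
        mf = _resolve_max_features(self.max_features, X.shape[1])

        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        per_tree = np.zeros((self.n_estimators, self.n_features_in_))
        for t in range(self.n_estimators):
            if self.bootstrap:
                sample = rng.integers(0, n, size=n)
                Xt, yt = X[sample], y_codes[sample]
            else:
                Xt, yt = X, y_codes
            tree = _grow(Xt, yt, k, self.max_depth, self.min_samples_split, mf, rng)
            self.trees_.append(tree)
            per_tree[t] = tree.importances(self.n_features_in_)
        mean_imp = per_tree.mean(axis=0)
        total = mean_imp.sum()
        self.feature_importances_ = mean_imp / total if total > 0 else mean_imp
        return self

    def _vote_counts(self, X) -> np.ndarray:
        X = _check_Xy(X, n_features=self.n_features_in_)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.trees_:
            codes = tree.predict_codes(X)
            votes[np.arange(X.shape[0]), codes] += 1.0
        return votes

    def predict_proba(self, X) -> np.ndarray:
        """Vote fractions per class (columns follow ``classes_``); rows sum to 1."""
        return self._vote_counts(X) / len(self.trees_)

    def predict(self, X):
        # argmax breaks ties toward the lowest class index (fixed class order)
        return self.classes_[np.argmax(self._vote_counts(X), axis=1)]


# ---------------------------------------------------------------------------
# Functional wrappers and JSON persistence


def grow_tree(X, y, max_depth=None, min_samples_split=2, random_state=None) -> GiniDecisionTreeClassifier:
    """Grow a single full-feature CART tree (see :class:`GiniDecisionTreeClassifier`)."""
    return GiniDecisionTreeClassifier(
        max_depth=max_depth, min_samples_split=min_samples_split, random_state=random_state
    ).fit(X, y)


def fit_forest(
    X,
    y,
    n_trees: int = 220,
    max_depth: int | None = 14,
    features_per_split="sqrt",
    seed=None,
    bootstrap: bool = True,
) -> GiniRandomForestClassifier:
    """Fit a Gini random forest (see :class:`GiniRandomForestClassifier`)."""
    return GiniRandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=features_per_split,
        bootstrap=bootstrap,
        random_state=seed,
    ).fit(X, y)


def predict(model: GiniRandomForestClassifier, X):
    return model.predict(X)


def predict_vote_fractions(model: GiniRandomForestClassifier, X):
    return model.predict_proba(X)


def feature_importance(model) -> np.ndarray:
    return model.feature_importances_


def forest_to_json(model: GiniRandomForestClassifier) -> str:
    """Serialize a fitted forest; ``forest_from_json`` restores identical predictions."""
    payload = {
        "params": model.get_params(),
        "classes": model.classes_.tolist(),
        "n_features_in": model.n_features_in_,
        "feature_importances": model.feature_importances_.tolist(),
        "trees": [t.to_dict() for t in model.trees_],
    }
    return json.dumps(payload)


def forest_from_json(text: str) -> GiniRandomForestClassifier:
    payload = json.loads(text)
    model = GiniRandomForestClassifier(**payload["params"])
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = int(payload["n_features_in"])
    model.feature_importances_ = np.asarray(payload["feature_importances"], dtype=float)
    model.trees_ = [Tree.from_dict(d) for d in payload["trees"]]
    return model
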