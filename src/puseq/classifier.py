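"""Inner binary classifier contract for the PU loop.

The default is an information-gain (entropy criterion) decision tree with
Laplace-smoothed leaf probabilities: a leaf holding ``n`` training examples
of which ``n_pos`` are positive estimates ``Pr[pos] = (n_pos + 1) / (n + 2)``.
Raw leaf frequencies are near 0/1 and would make the min-over-spies threshold
degenerate; Laplace smoothing is the standard probability-estimation-tree fix.

Labels are integers: 1 = positive class (c1), 0 = negative class (c2).
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

POSITIVE, NEGATIVE = 1, 0

# Cost-complexity pruning plays the role of C4.5's default pruning. The spy
# threshold depends on probability plateaus: examples that are feature-wise
# indistinguishable must share a leaf (and hence tie), so noise splits inside
# class-homogeneous regions have to be pruned away. 0.02 is roughly the
# entropy decrease a spurious split can achieve at benchmark sample sizes.
DEFAULT_TREE_PARAMS = {"min_samples_leaf": 5, "ccp_alpha": 0.02}


class ProbClassifier(Protocol):
    """What the PU loop needs from a trained classifier."""

    feature_dimension: int

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray: ...


def _check_training_set(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X rows ({X.shape}) must match |y| ({y.shape[0]})")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    return X, y


def _laplace_tree_proba(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Pr[positive] per example from Laplace-smoothed leaf counts."""
    leaves = tree.tree_.apply(np.asarray(X, dtype=np.float32))
    n = tree.tree_.weighted_n_node_samples[leaves]
    # tree_.value holds per-node class fractions; recover counts via n.
    value = tree.tree_.value[leaves, 0, :]
    pos_col = int(np.flatnonzero(tree.classes_ == POSITIVE)[0])
    n_pos = value[:, pos_col] * n
    return (n_pos + 1.0) / (n + 2.0)


class TreeProbClassifier:
    """Entropy-criterion decision tree with Laplace leaf probabilities."""

    def __init__(self, seed: int = 0, **params):
        self.seed = seed
        self.params = {**DEFAULT_TREE_PARAMS, **params}
        self._tree: DecisionTreeClassifier | None = None
        self.feature_dimension: int = -1

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TreeProbClassifier":
        X, y = _check_training_set(X, y)
        self._tree = DecisionTreeClassifier(
            criterion="entropy", random_state=self.seed, **self.params
        )
        self._tree.fit(X, y)
        self.feature_dimension = X.shape[1]
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self._tree is None:
            raise RuntimeError("classifier not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dimension:
            raise ValueError(
                f"feature dimension mismatch: expected {self.feature_dimension}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return _laplace_tree_proba(self._tree, X)


class ForestProbClassifier:
    """Random forest averaging Laplace-smoothed per-tree probabilities."""

    def __init__(self, seed: int = 0, n_estimators: int = 100, **params):
        self.seed = seed
        self.n_estimators = n_estimators
        self.params = params
        self._forest: RandomForestClassifier | None = None
        self.feature_dimension: int = -1

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForestProbClassifier":
        X, y = _check_training_set(X, y)
        self._forest = RandomForestClassifier(
            criterion="entropy",
            n_estimators=self.n_estimators,
            random_state=self.seed,
            **self.params,
        )
        self._forest.fit(X, y)
        self.feature_dimension = X.shape[1]
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        if self._forest is None:
            raise RuntimeError("classifier not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_dimension:
            raise ValueError(
                f"feature dimension mismatch: expected {self.feature_dimension}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        probs = np.stack([_laplace_tree_proba(t, X) for t in self._forest.estimators_])
        return probs.mean(axis=0)


CLASSIFIER_FACTORIES: dict[str, Callable[..., object]] = {
    "tree": TreeProbClassifier,
    "forest": ForestProbClassifier,
}


def make_classifier(name: str = "tree", seed: int = 0, **params):
    """Instantiate an unfitted classifier by factory name."""
    try:
        factory = CLASSIFIER_FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; available: {sorted(CLASSIFIER_FACTORIES)}"
        ) from None
    return factory(seed=seed, **params)


def train_tree(X: np.ndarray, y: np.ndarray, seed: int = 0, **params) -> TreeProbClassifier:
    """Train the default decision tree on labels in {1 (positive), 0 (negative)}."""
    return TreeProbClassifier(seed=seed, **params).fit(X, y)
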