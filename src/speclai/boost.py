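"""Second-order gradient-boosted regression trees (scikit-learn API).

Squared-error boosting in the style of modern tree boosters: each tree is
grown greedily on the gradient/curvature statistics of the current ensemble
prediction, split gain is

    0.5 * (GL^2/(HL + lambda) + GR^2/(HR + lambda) - G^2/(H + lambda)) - gamma

with leaf weight ``-G/(H + lambda)``.  For squared error the per-sample
gradient is the residual and the curvature is 1, so ``min_child_weight``
bounds the child sample count.  Row subsampling (without replacement) and
per-tree column subsampling are supported, seeded by ``random_state``.

Written against the estimator contract of scikit-learn so it composes with
``GridSearchCV``; kept self-contained because no boosted-tree library with
this exact hyperparameter surface is available at runtime.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["BoostedTreesRegressor"]

# node: (feature, threshold, left_id, right_id, leaf_value)
_Node = Tuple[int, float, int, int, float]


def _build_tree(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    max_depth: int,
    min_child_weight: float,
    gamma: float,
    reg_lambda: float,
) -> List[_Node]:
    nodes: List[_Node] = []

    def grow(idx: np.ndarray, depth: int) -> int:
        node_id = len(nodes)
        nodes.append((-1, 0.0, -1, -1, 0.0))
        G, H = g[idx].sum(), h[idx].sum()
        leaf_value = -G / (H + reg_lambda)
        if depth >= max_depth or len(idx) < 2:
            nodes[node_id] = (-1, 0.0, -1, -1, leaf_value)
            return node_id

        Xn = X[idx]
        order = np.argsort(Xn, axis=0, kind="stable")
        g_sorted = np.take_along_axis(g[idx][:, None].repeat(Xn.shape[1], 1), order, axis=0)
        h_sorted = np.take_along_axis(h[idx][:, None].repeat(Xn.shape[1], 1), order, axis=0)
        x_sorted = np.take_along_axis(Xn, order, axis=0)
        GL = np.cumsum(g_sorted, axis=0)[:-1]
        HL = np.cumsum(h_sorted, axis=0)[:-1]
        GR, HR = G - GL, H - HL
        valid = (HL >= min_child_weight) & (HR >= min_child_weight)
        valid &= x_sorted[1:] > x_sorted[:-1]  # no split between equal values
        base = G * G / (H + reg_lambda)
        gain = 0.5 * (GL**2 / (HL + reg_lambda) + GR**2 / (HR + reg_lambda) - base) - gamma
        gain = np.where(valid, gain, -np.inf)
        best_flat = int(np.argmax(gain))
        best_pos, best_feat = np.unravel_index(best_flat, gain.shape)
        if not np.isfinite(gain[best_pos, best_feat]) or gain[best_pos, best_feat] <= 0:
            nodes[node_id] = (-1, 0.0, -1, -1, leaf_value)
            return node_id
        threshold = 0.5 * (x_sorted[best_pos, best_feat] + x_sorted[best_pos + 1, best_feat])
        mask = Xn[:, best_feat] <= threshold
        left = grow(idx[mask], depth + 1)
        right = grow(idx[~mask], depth + 1)
        nodes[node_id] = (int(best_feat), float(threshold), left, right, 0.0)
        return node_id

    grow(np.arange(X.shape[0]), 0)
    return nodes


def _predict_tree(nodes: List[_Node], X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        node_id, idx = stack.pop()
        feat, thr, left, right, value = nodes[node_id]
        if feat < 0:
            out[idx] = value
            continue
        mask = X[idx, feat] <= thr
        stack.append((left, idx[mask]))
        stack.append((right, idx[~mask]))
    return out


class BoostedTreesRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regression trees with a second-order split objective.

    Parameters mirror the conventional boosted-tree surface: ``n_estimators``,
    ``max_depth``, ``min_child_weight``, ``gamma`` (minimum split gain),
    ``subsample`` (row fraction per tree), ``colsample_bytree`` (column
    fraction per tree), ``learning_rate`` and the L2 leaf penalty
    ``reg_lambda``.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int = 3,
        min_child_weight: float = 1.0,
        gamma: float = 0.0,
        subsample: float = 1.0,
        colsample_bytree: float = 1.0,
        learning_rate: float = 0.1,
        reg_lambda: float = 1.0,
        base_score: Optional[float] = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_child_weight = min_child_weight
        self.gamma = gamma
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.learning_rate = learning_rate
        self.reg_lambda = reg_lambda
        self.base_score = base_score
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        self.base_score_ = float(np.mean(y)) if self.base_score is None else float(self.base_score)
        pred = np.full(n, self.base_score_)
        self.trees_: List[Tuple[np.ndarray, List[_Node]]] = []
        n_rows = max(1, int(round(self.subsample * n)))
        n_cols = max(1, int(round(self.colsample_bytree * p)))
        for _ in range(self.n_estimators):
            rows = rng.choice(n, size=n_rows, replace=False) if n_rows < n else np.arange(n)
            cols = np.sort(rng.choice(p, size=n_cols, replace=False)) if n_cols < p else np.arange(p)
            g = pred[rows] - y[rows]  # squared loss: gradient = residual
            h = np.ones(len(rows))  # curvature = 1
            nodes = _build_tree(
                X[np.ix_(rows, cols)], g, h,
                self.max_depth, self.min_child_weight, self.gamma, self.reg_lambda,
            )
            self.trees_.append((cols, nodes))
            pred += self.learning_rate * _predict_tree(nodes, X[:, cols])
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        pred = np.full(X.shape[0], self.base_score_)
        for cols, nodes in self.trees_:
            pred += self.learning_rate * _predict_tree(nodes, X[:, cols])
        return pred
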