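"""Binary regression/classification trees with pluggable split criteria.

Three criteria are supported:

* ``LEAST_SQUARES`` — sum of squared errors, for continuous responses
  (lower is better);
* ``GINI`` — size-weighted impurity ``n * p * (1 - p)`` of a 0/1 response
  (lower is better);
* ``ZTP_LOGLIK`` — the zero-truncated Poisson log-likelihood of a node's
  positive counts, each child evaluated at its own rate MLE (higher is
  better).

Candidate thresholds are midpoints between consecutive distinct sorted
feature values (for 0/1 markers that is the single threshold 0.5).  Ties in
split quality break toward the lowest feature index, then lowest threshold,
so tree growth is fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import numpy as np
from scipy import special

from .distributions import ztp_loglik, ztp_mle, ztp_rate_from_mean

__all__ = [
    "SplitCriterion",
    "TreeConfig",
    "TreeNode",
    "node_score",
    "best_split",
    "grow_tree",
    "predict_tree",
]

# relative tolerance below which a score change does not count as improvement
_GAIN_TOL = 1e-9


class SplitCriterion(enum.Enum):
    LEAST_SQUARES = "least_squares"
    GINI = "gini"
    ZTP_LOGLIK = "ztp_loglik"


@dataclasses.dataclass(frozen=True)
class TreeConfig:
    """Growth controls for a single tree.

    ``nodesize`` is the minimum number of samples a leaf may hold; a node
    with fewer than ``2 * nodesize`` samples is terminal.  ``max_depth=None``
    means unlimited (no pruning is ever performed).
    """

    mtry: int
    nodesize: int = 1
    max_depth: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")


@dataclasses.dataclass
class TreeNode:
    """A node of a fitted tree; leaves have no children and no split."""

    leaf_value: float
    n_samples: int
    feature_index: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _validate_response(y: np.ndarray, criterion: SplitCriterion) -> None:
    if y.size == 0:
        raise ValueError("empty response")
    if criterion is SplitCriterion.GINI:
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("GINI criterion requires a 0/1 response")
    elif criterion is SplitCriterion.ZTP_LOGLIK:
        if np.any(y < 1) or np.any(y != np.floor(y)):
            raise ValueError("ZTP_LOGLIK criterion requires integer counts >= 1")


def node_score(y_subset, criterion: SplitCriterion) -> float:
    """Criterion value of a single node.

    SSE and weighted Gini are losses (lower better); the ZTP score is the
    log-likelihood at the node's rate MLE (higher better) including the
    ``sum log(y!)`` term.
    """
    y = np.asarray(y_subset, dtype=float)
    _validate_response(y, criterion)
    if criterion is SplitCriterion.LEAST_SQUARES:
        return float(np.sum((y - y.mean()) ** 2))
    if criterion is SplitCriterion.GINI:
        p = y.mean()
        return float(y.size * p * (1.0 - p))
    return ztp_loglik(y.astype(np.int64), ztp_mle(y.astype(np.int64)))


def _ztp_partial_ll(n, s, mu):
    """ZTP log-likelihood without the mu-free ``sum log(y!)`` term.

    That term cancels between a parent and the union of its children, so it
    can be dropped from split comparisons without changing any choice.
    """
    return -n * np.log(-np.expm1(-mu)) + np.log(mu) * s - n * mu


def _split_scores(ys: np.ndarray, left_sizes: np.ndarray, criterion: SplitCriterion):
    """Loss of every candidate split of sorted responses ``ys``.

    ``left_sizes[k]`` rows go left for candidate ``k``.  Returns values on a
    "lower is better" scale for all criteria (ZTP negated).
    """
    n = ys.size
    csum = np.cumsum(ys)
    nl = left_sizes.astype(float)
    nr = n - nl
    sl = csum[left_sizes - 1]
    sr = csum[-1] - sl
    if criterion is SplitCriterion.LEAST_SQUARES:
        csum2 = np.cumsum(ys * ys)
        s2l = csum2[left_sizes - 1]
        s2r = csum2[-1] - s2l
        return (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
    if criterion is SplitCriterion.GINI:
        return sl * (nl - sl) / nl + sr * (nr - sr) / nr
    mu_l = ztp_rate_from_mean(sl / nl)
    mu_r = ztp_rate_from_mean(sr / nr)
    return -(_ztp_partial_ll(nl, sl, mu_l) + _ztp_partial_ll(nr, sr, mu_r))


def _parent_loss(y: np.ndarray, criterion: SplitCriterion) -> float:
    if criterion is SplitCriterion.ZTP_LOGLIK:
        n, s = y.size, y.sum()
        return float(-_ztp_partial_ll(n, s, ztp_rate_from_mean(s / n)))
    return node_score(y, criterion)


def _best_split_binary(X_cand: np.ndarray, y: np.ndarray, features, nodesize, criterion):
    """Vectorized split search when every candidate column is 0/1 coded.

    The only possible threshold is 0.5, so all candidates are scored in a
    few matrix operations.  Returns ``(loss, feature, threshold)`` or None.
    """
    n = y.size
    left = X_cand == 0.0
    nl = left.sum(axis=0).astype(float)
    nr = n - nl
    ok = (nl >= nodesize) & (nr >= nodesize) & (nl > 0) & (nr > 0)
    if not np.any(ok):
        return None
    sl = y @ left
    sr = y.sum() - sl
    with np.errstate(divide="ignore", invalid="ignore"):
        if criterion is SplitCriterion.LEAST_SQUARES:
            y2 = y * y
            s2l = y2 @ left
            s2r = y2.sum() - s2l
            losses = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
        elif criterion is SplitCriterion.GINI:
            losses = sl * (nl - sl) / nl + sr * (nr - sr) / nr
        else:
            losses = np.full(nl.size, np.inf)
            mu_l = ztp_rate_from_mean(sl[ok] / nl[ok])
            mu_r = ztp_rate_from_mean(sr[ok] / nr[ok])
            losses[ok] = -(
                _ztp_partial_ll(nl[ok], sl[ok], mu_l)
                + _ztp_partial_ll(nr[ok], sr[ok], mu_r)
            )
    losses = np.where(ok, losses, np.inf)
    k = int(np.argmin(losses))  # first minimum -> lowest feature index
    if not np.isfinite(losses[k]):
        return None
    return float(losses[k]), int(features[k]), 0.5


def best_split(
    X_sub: np.ndarray,
    y: np.ndarray,
    criterion: SplitCriterion,
    candidate_features,
    nodesize: int,
):
    """Best admissible (feature, threshold) among the candidate features.

    Maximizes the children's summed ZTP log-likelihood (equivalently
    minimizes summed SSE or weighted Gini impurity); both children must keep
    at least ``nodesize`` samples.  Returns ``(feature, threshold, gain)``
    with ``gain > 0``, or ``None`` when no admissible split improves on the
    parent node.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_response(y, criterion)
    n = y.size
    if n < 2 * nodesize:
        return None
    parent = _parent_loss(y, criterion)
    tol = _GAIN_TOL * (1.0 + abs(parent))
    features = sorted(int(f) for f in candidate_features)
    X_cand = X_sub[:, features]
    if ((X_cand == 0.0) | (X_cand == 1.0)).all():
        found = _best_split_binary(X_cand, y, features, nodesize, criterion)
        if found is None or parent - found[0] <= tol:
            return None
        return found[1], found[2], parent - found[0]
    best = None  # (loss, feature, threshold)
    for feature in features:
        x = X_sub[:, feature]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y[order]
        boundaries = np.flatnonzero(xs[:-1] != xs[1:])  # split after index b
        left_sizes = boundaries + 1
        keep = (left_sizes >= nodesize) & (n - left_sizes >= nodesize)
        if not np.any(keep):
            continue
        left_sizes = left_sizes[keep]
        thresholds = (xs[left_sizes - 1] + xs[left_sizes]) / 2.0
        losses = _split_scores(ys, left_sizes, criterion)
        k = int(np.argmin(losses))  # first minimum -> lowest threshold
        if best is None or losses[k] < best[0]:
            best = (float(losses[k]), feature, float(thresholds[k]))
    if best is None or parent - best[0] <= tol:
        return None
    return best[1], best[2], parent - best[0]


def _leaf_value(y: np.ndarray, criterion: SplitCriterion) -> float:
    if criterion is SplitCriterion.ZTP_LOGLIK:
        return ztp_mle(y.astype(np.int64))
    return float(np.mean(y))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    criterion: SplitCriterion,
    config: TreeConfig,
    rng: Optional[np.random.Generator] = None,
) -> TreeNode:
    """Grow an unpruned tree, drawing a fresh mtry feature subset per node."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per response value")
    _validate_response(y, criterion)
    p = X.shape[1]
    if config.mtry > p:
        raise ValueError(f"mtry={config.mtry} exceeds feature count {p}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        y_node = y[rows]
        node = TreeNode(leaf_value=_leaf_value(y_node, criterion), n_samples=rows.size)
        if rows.size < 2 * config.nodesize:
            return node
        if config.max_depth is not None and depth >= config.max_depth:
            return node
        candidates = rng.choice(p, size=config.mtry, replace=False)
        found = best_split(X[rows], y_node, criterion, candidates, config.nodesize)
        if found is None:
            return node
        feature, threshold, _gain = found
        go_left = X[rows, feature] <= threshold
        node.feature_index = feature
        node.threshold = threshold
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    return build(np.arange(y.size), 0)


def predict_tree(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Route each row of ``X`` to a leaf (left when ``x[f] <= threshold``)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        node = tree
        while not node.is_leaf:
            if node.feature_index >= row.size:
                raise ValueError("feature count does not match training data")
            node = node.left if row[node.feature_index] <= node.threshold else node.right
        out[i] = node.leaf_value
    return out
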