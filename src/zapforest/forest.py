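"""Bagged tree ensembles (bootstrap aggregation over :mod:`zapforest.tree`).

Each tree is grown on a bootstrap sample (with replacement, same size as the
training set) using a per-tree random stream spawned from the forest seed, so
results are bit-identical whether trees are grown sequentially or in
parallel.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed

from .tree import SplitCriterion, TreeConfig, TreeNode, grow_tree, predict_tree

__all__ = ["ForestModel", "fit_forest", "predict_forest", "save_forest", "load_forest"]

_SCHEMA_VERSION = 1


@dataclasses.dataclass
class ForestModel:
    trees: list
    criterion: SplitCriterion
    config: TreeConfig
    ntree: int
    seed: int
    n_features: int
    feature_names: Optional[Sequence[str]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_forest(self, X)


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tree_index,)))


def _grow_one(X, y, criterion, config, seed, b, bootstrap):
    rng = _tree_rng(seed, b)
    n = y.size
    idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
    return grow_tree(X[idx], y[idx], criterion, config, rng=rng)


def fit_forest(
    X,
    y,
    criterion: SplitCriterion,
    config: TreeConfig,
    ntree: int,
    seed: int,
    feature_names: Optional[Sequence[str]] = None,
    bootstrap: bool = True,
    n_jobs: int = 1,
) -> ForestModel:
    """Fit ``ntree`` bagged trees.

    ``bootstrap=False`` (each tree sees the full sample) exists for testing
    the averaging contract; production fits always resample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if y.size < 2 * config.nodesize:
        raise ValueError("too few samples for the requested nodesize")
    if criterion is SplitCriterion.ZTP_LOGLIK and np.any(y < 1):
        raise ValueError(
            "ZTP_LOGLIK forest requires all responses >= 1; filter positives first"
        )
    if n_jobs == 1:
        trees = [_grow_one(X, y, criterion, config, seed, b, bootstrap) for b in range(ntree)]
    else:
        trees = Parallel(n_jobs=n_jobs)(
            delayed(_grow_one)(X, y, criterion, config, seed, b, bootstrap)
            for b in range(ntree)
        )
    return ForestModel(
        trees=trees,
        criterion=criterion,
        config=config,
        ntree=ntree,
        seed=seed,
        n_features=X.shape[1],
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def predict_forest(model: ForestModel, X) -> np.ndarray:
    """Ensemble prediction: the arithmetic mean of per-tree predictions.

    For GINI forests this is a zero-probability in [0, 1]; for ZTP forests a
    pooled positive rate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, model expects {model.n_features}"
        )
    acc = np.zeros(X.shape[0])
    for tree in model.trees:
        acc += predict_tree(tree, X)
    return acc / model.ntree


def oob_predictions(model: ForestModel, X, y) -> np.ndarray:
    """Out-of-bag ensemble predictions (diagnostic only; NaN where never OOB)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for b, tree in enumerate(model.trees):
        rng = _tree_rng(model.seed, b)
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size:
            acc[oob] += predict_tree(tree, X[oob])
            cnt[oob] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


# ---------------------------------------------------------------------------
# serialization: versioned JSON schema so CV runs can be resumed


def _node_to_dict(node: TreeNode) -> dict:
    d = {"value": node.leaf_value, "n": node.n_samples}
    if not node.is_leaf:
        d.update(
            feature=node.feature_index,
            threshold=node.threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(leaf_value=d["value"], n_samples=d["n"])
    if "feature" in d:
        node.feature_index = d["feature"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def forest_to_dict(model: ForestModel) -> dict:
    return {
        "schema": "zapforest.forest",
        "version": _SCHEMA_VERSION,
        "criterion": model.criterion.value,
        "config": {
            "mtry": model.config.mtry,
            "nodesize": model.config.nodesize,
            "max_depth": model.config.max_depth,
            "seed": model.config.seed,
        },
        "ntree": model.ntree,
        "seed": model.seed,
        "n_features": model.n_features,
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "trees": [_node_to_dict(t) for t in model.trees],
    }


def forest_from_dict(d: dict) -> ForestModel:
    if d.get("schema") != "zapforest.forest" or d.get("version") != _SCHEMA_VERSION:
        raise ValueError("not a recognized forest schema")
    cfg = TreeConfig(**d["config"])
    return ForestModel(
        trees=[_node_from_dict(t) for t in d["trees"]],
        criterion=SplitCriterion(d["criterion"]),
        config=cfg,
        ntree=d["ntree"],
        seed=d["seed"],
        n_features=d["n_features"],
        feature_names=d["feature_names"],
    )


def save_forest(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(forest_to_dict(model), fh)


def load_forest(path) -> ForestModel:
    with open(path) as fh:
        return forest_from_dict(json.load(fh))
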