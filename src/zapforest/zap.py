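"""Two-part zero-altered Poisson random forest.

Step 1 fits a binary (Gini) forest to the zero indicator ``I(y == 0)``,
giving per-row zero probabilities ``theta``.  Step 2 fits a forest with the
zero-truncated Poisson log-likelihood criterion to the positive counts only,
giving per-row truncated rates ``mu``.  Two prediction rules combine them:

* expected value: ``(1 - theta) * mu / (1 - exp(-mu))`` — the ZAP mean;
* classify-then-count: 0 when ``theta > threshold``, else ``mu``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .forest import ForestModel, fit_forest, forest_from_dict, forest_to_dict, predict_forest
from .tree import SplitCriterion, TreeConfig
from .distributions import ztp_mean

__all__ = [
    "ZAPForestModel",
    "fit_zap",
    "predict_zap_parts",
    "predict_zap_mean",
    "predict_zap_classify",
    "save_zap",
    "load_zap",
]


@dataclasses.dataclass
class ZAPForestModel:
    zero_forest: ForestModel
    pos_forest: ForestModel
    threshold: float = 0.5
    #: if True, each ZTP tree's rate is converted to a truncated mean before
    #: averaging; default applies the mean formula once at the forest level.
    average_tree_means: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


def fit_zap(
    X,
    y,
    config: TreeConfig,
    ntree: int,
    seed: int,
    threshold: float = 0.5,
    feature_names: Optional[Sequence[str]] = None,
    pos_config: Optional[TreeConfig] = None,
    pos_ntree: Optional[int] = None,
    n_jobs: int = 1,
) -> ZAPForestModel:
    """Fit the two forests of the hurdle model.

    Both parts share hyperparameters by default (one joint tuning pass);
    ``pos_config``/``pos_ntree`` override the truncated part when separate
    tuning is wanted.  Seeds for the two parts are derived from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("responses must be nonnegative integer counts")
    y = y.astype(np.int64)
    is_zero = (y == 0).astype(float)
    n_zero = int(is_zero.sum())
    n_pos = y.size - n_zero
    if n_pos == 0:
        raise ValueError("all responses are zero: truncated (positive) part is unfittable")
    if n_zero == 0:
        raise ValueError("no zero responses: zero part is unfittable")
    pos_cfg = pos_config if pos_config is not None else config
    if pos_cfg.mtry > X.shape[1]:
        raise ValueError("mtry exceeds feature count")
    zero_forest = fit_forest(
        X,
        is_zero,
        SplitCriterion.GINI,
        config,
        ntree=ntree,
        seed=seed * 2 + 1,
        feature_names=feature_names,
        n_jobs=n_jobs,
    )
    pos_mask = y > 0
    pos_forest = fit_forest(
        X[pos_mask],
        y[pos_mask].astype(float),
        SplitCriterion.ZTP_LOGLIK,
        pos_cfg,
        ntree=pos_ntree if pos_ntree is not None else ntree,
        seed=seed * 2 + 2,
        feature_names=feature_names,
        n_jobs=n_jobs,
    )
    return ZAPForestModel(zero_forest=zero_forest, pos_forest=pos_forest, threshold=threshold)


def predict_zap_parts(model: ZAPForestModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-row ``(theta_hat, mu_hat)`` from the two forests."""
    theta = predict_forest(model.zero_forest, X)
    mu = predict_forest(model.pos_forest, X)
    return theta, mu


def predict_zap_mean(model: ZAPForestModel, X) -> np.ndarray:
    """Expected-value rule: the ZAP mean ``(1 - theta) * mu / (1 - exp(-mu))``."""
    theta, mu = predict_zap_parts(model, X)
    if model.average_tree_means:
        # alternative aggregation: average each tree's truncated mean
        from .tree import predict_tree

        acc = np.zeros(np.asarray(X).shape[0])
        for tree in model.pos_forest.trees:
            acc += ztp_mean(predict_tree(tree, np.asarray(X, dtype=float)))
        return (1.0 - theta) * acc / model.pos_forest.ntree
    return (1.0 - theta) * ztp_mean(mu)


def predict_zap_classify(model: ZAPForestModel, X) -> np.ndarray:
    """Threshold rule: 0 where ``theta > threshold``, else ``mu``.

    A ``theta`` exactly at the threshold routes to the count branch.
    """
    theta, mu = predict_zap_parts(model, X)
    return np.where(theta > model.threshold, 0.0, mu)


def save_zap(model: ZAPForestModel, path) -> None:
    payload = {
        "schema": "zapforest.zap",
        "version": 1,
        "threshold": model.threshold,
        "average_tree_means": model.average_tree_means,
        "zero_forest": forest_to_dict(model.zero_forest),
        "pos_forest": forest_to_dict(model.pos_forest),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_zap(path) -> ZAPForestModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("schema") != "zapforest.zap":
        raise ValueError("not a recognized ZAP forest file")
    return ZAPForestModel(
        zero_forest=forest_from_dict(d["zero_forest"]),
        pos_forest=forest_from_dict(d["pos_forest"]),
        threshold=d["threshold"],
        average_tree_means=d["average_tree_means"],
    )
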