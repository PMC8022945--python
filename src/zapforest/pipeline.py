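"""Nested cross-validation benchmark and permutation variable importance.

The protocol: an outer 5-fold split of the (line, environment) records; in
each outer fold the forest hyperparameters are tuned by 5-fold inner CV on
the outer-training records (the ridge penalty by 10-fold inner CV), the
winning configuration is refitted on the whole outer-training set, and the
outer test fold is predicted.  Spearman correlation, MAAPE and MAE are
reported per environment and across environments as mean +/- SE over the
five outer folds.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import GenomicDataset, build_design
from .forest import ForestModel, fit_forest, predict_forest
from .metrics import fold_summary, maape, mae, spearman_cor
from .ridge import Family, default_lambda_grid, fit_poisson_ridge, fit_ridge, select_lambda
from .tree import SplitCriterion, TreeConfig, predict_tree
from .zap import ZAPForestModel, fit_zap, predict_zap_classify, predict_zap_mean

__all__ = [
    "HyperGrid",
    "FoldPlan",
    "BenchmarkConfig",
    "BenchmarkResult",
    "DATASET1_GRID",
    "DATASET2_GRID",
    "make_folds",
    "tune_forest",
    "run_benchmark",
    "permutation_vim",
    "average_vim_tables",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("RR", "GPR", "RF", "ZAP_RF", "ZAPC_RF")


@dataclasses.dataclass(frozen=True)
class HyperGrid:
    """Forest hyperparameter grid.

    By default the full factorial of the three value lists is searched; an
    explicit ``combinations`` list (e.g. a hand-picked 9-row subset) can be
    supplied instead.
    """

    ntree_values: Sequence[int] = (100, 300, 500)
    mtry_values: Sequence[int] = (30, 50, 100)
    nodesize_values: Sequence[int] = (2, 5, 15)
    combinations: Optional[Sequence[tuple]] = None

    def combos(self) -> list:
        if self.combinations is not None:
            out = [tuple(c) for c in self.combinations]
        else:
            out = list(
                itertools.product(self.ntree_values, self.mtry_values, self.nodesize_values)
            )
        if not out:
            raise ValueError("empty hyperparameter grid")
        return out


DATASET1_GRID = HyperGrid(mtry_values=(30, 50, 100))
DATASET2_GRID = HyperGrid(mtry_values=(150, 230, 320))


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Seeded partition of record indices into k folds (ids 1..k)."""

    assignments: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(n_records: int, k: int, seed: int) -> FoldPlan:
    """Uniform random partition; fold sizes differ by at most one."""
    if k > n_records:
        raise ValueError(f"cannot make {k} folds from {n_records} records")
    rng = np.random.default_rng(seed)
    assignments = rng.permutation(np.arange(n_records) % k + 1)
    return FoldPlan(assignments=assignments, k=k, seed=seed)


def make_folds_by_line(lines: Sequence, k: int, seed: int) -> FoldPlan:
    """Partition whole lines: all records of a line share a fold."""
    unique = list(dict.fromkeys(lines))
    if k > len(unique):
        raise ValueError("more folds than lines")
    rng = np.random.default_rng(seed)
    line_fold = dict(zip(unique, rng.permutation(np.arange(len(unique)) % k + 1)))
    assignments = np.array([line_fold[ln] for ln in lines])
    return FoldPlan(assignments=assignments, k=k, seed=seed)


def _clip_mtry(mtry: int, p: int) -> int:
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds p={p}; clipping")
        return p
    return mtry


def _fit_predict_rf(X_tr, y_tr, X_te, combo, seed):
    ntree, mtry, nodesize = combo
    cfg = TreeConfig(mtry=_clip_mtry(mtry, X_tr.shape[1]), nodesize=nodesize)
    model = fit_forest(X_tr, y_tr, SplitCriterion.LEAST_SQUARES, cfg, ntree=ntree, seed=seed)
    return predict_forest(model, X_te)


def _fit_predict_zap(X_tr, y_tr, X_te, combo, seed):
    ntree, mtry, nodesize = combo
    cfg = TreeConfig(mtry=_clip_mtry(mtry, X_tr.shape[1]), nodesize=nodesize)
    model = fit_zap(X_tr, y_tr, cfg, ntree=ntree, seed=seed)
    return predict_zap_mean(model, X_te)


def tune_forest(
    X,
    y,
    grid: HyperGrid,
    fit_predict=_fit_predict_rf,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple:
    """Grid search by mean inner-CV MAE; returns (ntree, mtry, nodesize).

    Combinations that fail on some inner fold (e.g. a fold with no positive
    counts for the hurdle model) are skipped with a warning.  Ties break
    toward smaller ntree, then larger nodesize.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plan = make_folds(y.size, inner_k, seed)
    combos = grid.combos()
    results = []
    for combo in combos:
        fold_maes = []
        try:
            for fold in range(1, inner_k + 1):
                tr, te = plan.train_indices(fold), plan.test_indices(fold)
                pred = fit_predict(X[tr], y[tr], X[te], combo, seed=seed + fold)
                fold_maes.append(mae(y[te], pred))
        except ValueError as exc:
            logger.warning("skipping combination %s: %s", combo, exc)
            continue
        results.append((float(np.mean(fold_maes)), combo))
    if not results:
        raise ValueError("every hyperparameter combination failed during inner CV")
    best_score = min(r[0] for r in results)
    # ties -> smaller ntree, then larger nodesize
    tied = [c for s, c in results if s <= best_score + 1e-12]
    tied.sort(key=lambda c: (c[0], -c[2]))
    return tied[0]


@dataclasses.dataclass
class BenchmarkConfig:
    outer_k: int = 5
    inner_k_forest: int = 5
    inner_k_lambda: int = 10
    grid: Optional[HyperGrid] = None  # None -> use fixed_params, no tuning
    fixed_params: tuple = (300, 50, 5)  # (ntree, mtry, nodesize)
    lambda_grid_size: int = 50
    seed: int = 0
    threshold: float = 0.5
    by_line: bool = False
    pool_mode: str = "pool"  # or "average_env" for across-environment cells
    keep_models: bool = False


@dataclasses.dataclass
class BenchmarkResult:
    metrics: pd.DataFrame  # model, environment, metric, mean, se
    fold_values: pd.DataFrame  # model, environment, metric, fold, value
    predictions: pd.DataFrame  # fold, model, line, environment, y, yhat
    chosen_params: dict  # (fold, model) -> hyperparameters
    models: dict  # (fold, model) -> fitted model (if keep_models)
    fold_plan: FoldPlan


def _fit_one_model(name, X_tr, y_tr, cfg: BenchmarkConfig, params, seed):
    """Returns (fitted, predict_fn)."""
    if name == "RR":
        lam = select_lambda(
            X_tr, y_tr, Family.GAUSSIAN, cfg.inner_k_lambda,
            default_lambda_grid(X_tr, y_tr, cfg.lambda_grid_size), seed,
        )
        fit = fit_ridge(X_tr, y_tr, lam)
        return fit, fit.predict
    if name == "GPR":
        lam = select_lambda(
            X_tr, y_tr, Family.POISSON, cfg.inner_k_lambda,
            default_lambda_grid(X_tr, y_tr, cfg.lambda_grid_size), seed,
        )
        fit = fit_poisson_ridge(X_tr, y_tr, lam)
        return fit, fit.predict
    ntree, mtry, nodesize = params
    tree_cfg = TreeConfig(mtry=_clip_mtry(mtry, X_tr.shape[1]), nodesize=nodesize)
    if name == "RF":
        model = fit_forest(
            X_tr, y_tr, SplitCriterion.LEAST_SQUARES, tree_cfg, ntree=ntree, seed=seed
        )
        return model, lambda X: predict_forest(model, X)
    if name == "ZAP":
        model = fit_zap(X_tr, y_tr, tree_cfg, ntree=ntree, seed=seed, threshold=cfg.threshold)
        return model, None
    raise ValueError(f"unknown model {name!r}")


def run_benchmark(
    dataset: GenomicDataset,
    models: Sequence[str],
    include_GE: bool = False,
    config: Optional[BenchmarkConfig] = None,
) -> BenchmarkResult:
    """Nested-CV comparison of the requested models on one dataset.

    ZAP_RF and ZAPC_RF share a single fitted hurdle model per fold (they are
    two prediction rules of the same model).
    """
    cfg = config or BenchmarkConfig()
    models = list(models)
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    if not models:
        raise ValueError("no models requested")
    X, labels = build_design(dataset, include_GE=include_GE)
    y = dataset.counts.astype(float)
    envs = dataset.records["environment"].to_numpy()
    n = y.size
    if cfg.by_line:
        plan = make_folds_by_line(dataset.records["line"].tolist(), cfg.outer_k, cfg.seed)
    else:
        plan = make_folds(n, cfg.outer_k, cfg.seed)

    need_zap = "ZAP_RF" in models or "ZAPC_RF" in models
    chosen, kept, pred_rows = {}, {}, []
    for fold in range(1, cfg.outer_k + 1):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        X_tr, y_tr, X_te = X[tr], y[tr], X[te]
        fold_seed = cfg.seed * 1000 + fold
        to_fit = [m for m in models if m not in ("ZAP_RF", "ZAPC_RF")]
        if need_zap:
            to_fit.append("ZAP")
        for name in to_fit:
            logger.info("outer fold %d: fitting %s", fold, name)
            params = cfg.fixed_params
            if name in ("RF", "ZAP") and cfg.grid is not None:
                fp = _fit_predict_rf if name == "RF" else _fit_predict_zap
                params = tune_forest(
                    X_tr, y_tr, cfg.grid, fit_predict=fp,
                    inner_k=cfg.inner_k_forest, seed=fold_seed,
                )
            try:
                fitted, predict = _fit_one_model(name, X_tr, y_tr, cfg, params, fold_seed)
            except Exception as exc:
                raise RuntimeError(f"model {name} failed on outer fold {fold}: {exc}") from exc
            if name == "ZAP":
                outputs = {}
                if "ZAP_RF" in models:
                    outputs["ZAP_RF"] = predict_zap_mean(fitted, X_te)
                if "ZAPC_RF" in models:
                    outputs["ZAPC_RF"] = predict_zap_classify(fitted, X_te)
                for sub in outputs:
                    chosen[(fold, sub)] = params
                    if cfg.keep_models:
                        kept[(fold, sub)] = fitted
            else:
                outputs = {name: predict(X_te)}
                chosen[(fold, name)] = params if name in ("RF",) else None
                if cfg.keep_models:
                    kept[(fold, name)] = fitted
            for model_name, yhat in outputs.items():
                for j, idx in enumerate(te):
                    pred_rows.append(
                        (fold, model_name, dataset.records["line"].iat[idx],
                         envs[idx], y[idx], float(yhat[j]))
                    )
    predictions = pd.DataFrame(
        pred_rows, columns=["fold", "model", "line", "environment", "y", "yhat"]
    )
    fold_values = _metric_fold_values(predictions, dataset.environments, cfg.pool_mode)
    metrics = _summarize(fold_values)
    return BenchmarkResult(
        metrics=metrics,
        fold_values=fold_values,
        predictions=predictions,
        chosen_params=chosen,
        models=kept,
        fold_plan=plan,
    )


_METRIC_FNS = {"SPEARMAN": spearman_cor, "MAAPE": maape, "MAE": mae}


def _metric_fold_values(predictions: pd.DataFrame, environments, pool_mode: str) -> pd.DataFrame:
    rows = []
    for (model, fold), sub in predictions.groupby(["model", "fold"]):
        cells = {env: sub[sub["environment"] == env] for env in environments}
        per_env = {}
        for metric, fn in _METRIC_FNS.items():
            for env, cell in cells.items():
                if len(cell) >= 2:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        per_env[(metric, env)] = fn(cell["y"].to_numpy(), cell["yhat"].to_numpy())
                    rows.append((model, env, metric, fold, per_env[(metric, env)]))
            if pool_mode == "pool":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    val = fn(sub["y"].to_numpy(), sub["yhat"].to_numpy())
            else:
                vals = [per_env[k] for k in per_env if k[0] == metric]
                val = float(np.mean(vals))
            rows.append((model, "ALL", metric, fold, val))
    return pd.DataFrame(rows, columns=["model", "environment", "metric", "fold", "value"])


def _summarize(fold_values: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (model, env, metric), sub in fold_values.groupby(["model", "environment", "metric"]):
        vals = sub["value"].to_numpy()
        if vals.size >= 2:
            mean, se = fold_summary(vals)
        else:
            mean, se = float(vals.mean()), float("nan")
        rows.append((model, env, metric, mean, se))
    return pd.DataFrame(rows, columns=["model", "environment", "metric", "mean", "se"])


# ---------------------------------------------------------------------------
# permutation variable importance


def _tree_features(tree) -> set:
    out, stack = set(), [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.add(node.feature_index)
            stack.extend((node.left, node.right))
    return out


def _vim_single_forest(forest: ForestModel, X, y, pe_fn, seed, n_permutations):
    """Per-predictor mean/sd over trees of PE(permuted) - PE(original)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    # one permutation set per (predictor, repeat), shared across trees
    perms = {
        j: [rng.permutation(n) for _ in range(n_permutations)] for j in range(p)
    }
    diffs = np.zeros((forest.ntree, p))
    for b, tree in enumerate(forest.trees):
        base_pred = predict_tree(tree, X)
        base_pe = pe_fn(y, base_pred)
        for j in _tree_features(tree):  # unused features shift nothing
            acc = 0.0
            for perm in perms[j]:
                Xp = X.copy()
                Xp[:, j] = X[perm, j]
                acc += pe_fn(y, predict_tree(tree, Xp)) - base_pe
            diffs[b, j] = acc / n_permutations
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1) if forest.ntree > 1 else np.zeros(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        importance = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    return importance


def _pe_mse(y, pred):
    return float(np.mean((y - pred) ** 2))


def _pe_misclass(y, pred):
    return float(np.mean((pred > 0.5).astype(float) != y))


def _vim_table(importance, feature_names, part, n_top):
    order = np.argsort(-importance, kind="stable")
    table = pd.DataFrame(
        {
            "feature": [feature_names[j] for j in order],
            "importance": importance[order],
            "part": part,
            "rank": np.arange(1, importance.size + 1),
        }
    )
    return table.head(n_top) if n_top is not None else table


def permutation_vim(
    model,
    test_X,
    test_y,
    feature_names: Optional[Sequence[str]] = None,
    n_top: Optional[int] = 30,
    seed: int = 0,
    n_permutations: int = 1,
):
    """Permutation importance on a held-out test set.

    For each tree the test-set prediction error (PE) is computed, each
    predictor column is permuted and the PE recomputed; the per-tree
    differences are averaged over trees and normalized by their standard
    deviation across trees.  Plain forests yield one table; hurdle models
    yield two — the zero part scored by misclassification rate of the
    ``I(y == 0)`` indicator, the truncated part by squared error of the
    predicted positive rate against the positive counts.
    """
    X = np.asarray(test_X, dtype=float)
    y = np.asarray(test_y, dtype=float)
    if isinstance(model, ZAPForestModel):
        p = model.zero_forest.n_features
    else:
        p = model.n_features
    if X.shape[1] != p:
        raise ValueError("test design does not match the model's feature space")
    if feature_names is None:
        feature_names = (
            model.zero_forest.feature_names
            if isinstance(model, ZAPForestModel)
            else model.feature_names
        ) or [f"X{j}" for j in range(p)]
    if isinstance(model, ZAPForestModel):
        zero_imp = _vim_single_forest(
            model.zero_forest, X, (y == 0).astype(float), _pe_misclass, seed, n_permutations
        )
        pos_mask = y > 0
        if not np.any(pos_mask):
            raise ValueError("test set has no positive counts for the truncated part")
        pos_imp = _vim_single_forest(
            model.pos_forest, X[pos_mask], y[pos_mask], _pe_mse, seed + 1, n_permutations
        )
        return (
            _vim_table(zero_imp, feature_names, "ZERO", n_top),
            _vim_table(pos_imp, feature_names, "TRUNCATED", n_top),
        )
    importance = _vim_single_forest(model, X, y, _pe_mse, seed, n_permutations)
    return _vim_table(importance, feature_names, "SINGLE", n_top)


def average_vim_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average per-feature importances over folds and re-rank."""
    concat = pd.concat(tables, ignore_index=True)
    part = concat["part"].iloc[0]
    avg = concat.groupby("feature", as_index=False)["importance"].mean()
    avg = avg.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    avg["part"] = part
    avg["rank"] = np.arange(1, len(avg) + 1)
    return avg
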