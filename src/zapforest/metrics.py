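"""Prediction-performance metrics: Spearman correlation, MAAPE, MAE, and
fold-level mean/standard-error summaries.

MAAPE is the mean arctangent absolute percentage error,
``mean(arctan |(y - yhat) / y|)``, bounded by pi/2.  Observed zeros need an
explicit convention: a term is 0 when both observed and predicted are zero
and pi/2 (the arctan limit) when only the observed value is zero — important
here because zero-inflated counts hit the denominator constantly.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

__all__ = ["spearman_cor", "maape", "mae", "fold_summary"]


def _check_lengths(y, yhat, minimum=1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < minimum:
        raise ValueError(f"need at least {minimum} observations")
    return y, yhat


def spearman_cor(y, yhat) -> float:
    """Pearson correlation of average ranks (ties get their mean rank).

    Returns 0 with a warning when either vector is constant (rank
    correlation is undefined there).
    """
    y, yhat = _check_lengths(y, yhat, minimum=2)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        warnings.warn("constant input: Spearman correlation undefined, returning 0")
        return 0.0
    ry = stats.rankdata(y)
    rh = stats.rankdata(yhat)
    return float(np.corrcoef(ry, rh)[0, 1])


def maape(y, yhat) -> float:
    """Mean arctangent absolute percentage error, in ``[0, pi/2]``."""
    y, yhat = _check_lengths(y, yhat)
    terms = np.empty(y.size)
    zero = y == 0
    exact = zero & (yhat == y)
    terms[exact] = 0.0
    terms[zero & ~exact] = math.pi / 2.0
    pos = ~zero
    terms[pos] = np.arctan(np.abs((y[pos] - yhat[pos]) / y[pos]))
    return float(terms.mean())


def mae(y, yhat) -> float:
    """Mean absolute error of prediction."""
    y, yhat = _check_lengths(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def fold_summary(values) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(k)) of k per-fold metric values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("standard error needs at least 2 fold values")
    k = values.size
    return float(values.mean()), float(values.std(ddof=1) / math.sqrt(k))
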