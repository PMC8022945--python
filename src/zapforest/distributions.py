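"""Zero-truncated Poisson (ZTP) and zero-altered (hurdle) Poisson (ZAP) primitives.

The ZAP random variable puts probability ``theta`` on zero and, conditional on
being positive, follows a Poisson distribution truncated at zero with rate
``mu``.  The positive-part maximum-likelihood estimate of ``mu`` solves the
implicit moment equation ``mean = mu / (1 - exp(-mu))``, which has no interior
solution when the sample mean is 1; in that degenerate case ``MU_MIN`` is
returned.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MU_MIN",
    "ZAPParams",
    "PositiveCountSample",
    "zap_pmf",
    "zap_moments",
    "ztp_mean",
    "ztp_loglik",
    "ztp_mle",
    "ztp_rate_from_mean",
    "zap_sample",
]

#: Floor value for the truncated-Poisson rate when the MLE degenerates
#: (all positive observations equal to 1).
MU_MIN = 1e-8


@dataclasses.dataclass(frozen=True)
class ZAPParams:
    """Parameter pair of the zero-altered Poisson distribution.

    Parameters
    ----------
    theta : float
        Probability of a (structural) zero, in ``[0, 1)``.
    mu : float
        Rate of the zero-truncated Poisson part, strictly positive.
    """

    theta: float
    mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if not self.mu > 0.0:
            raise ValueError(f"mu must be > 0, got {self.mu}")


@dataclasses.dataclass(frozen=True)
class PositiveCountSample:
    """A sample of strictly positive integer counts (the hurdle's count part)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.size == 0:
            raise ValueError("positive-count sample must be nonempty")
        if not np.all(values == np.floor(values)) or np.any(values < 1):
            raise ValueError("all values must be integers >= 1")
        object.__setattr__(self, "values", values.astype(np.int64))

    @property
    def n_pos(self) -> int:
        return int(self.values.size)


def _as_positive_values(sample) -> np.ndarray:
    if isinstance(sample, PositiveCountSample):
        return sample.values
    return PositiveCountSample(np.asarray(sample)).values


def ztp_mean(mu):
    """Mean of the zero-truncated Poisson, ``mu / (1 - exp(-mu))``."""
    mu = np.asarray(mu, dtype=float)
    return mu / -np.expm1(-mu)


def zap_pmf(y, params: ZAPParams):
    """ZAP probability mass function.

    ``P(Y=0) = theta`` and, for ``y > 0``,
    ``P(Y=y) = (1 - theta) * exp(-mu) * mu**y / ((1 - exp(-mu)) * y!)``.
    Computed in log space so large ``y`` do not overflow.
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.issubdtype(np.asarray(y_arr).dtype, np.number):
        raise ValueError("y must be a nonnegative integer")
    if np.any(y_arr != np.floor(y_arr)):
        raise ValueError("y must be integer-valued")
    theta, mu = params.theta, params.mu
    with np.errstate(divide="ignore"):
        log_pos = (
            math.log1p(-theta)
            + stats.poisson.logpmf(y_arr, mu)
            - math.log(-math.expm1(-mu))
        )
    out = np.where(y_arr == 0, theta, np.exp(log_pos))
    if np.isscalar(y) or y_arr.ndim == 0:
        return float(out)
    return out


def zap_moments(params: ZAPParams) -> tuple[float, float]:
    """Mean and variance of the ZAP distribution.

    mean = (1 - theta) * mu / (1 - exp(-mu))
    var  = (1 - theta) * (mu + mu^2) / (1 - exp(-mu)) - mean^2
    """
    theta, mu = params.theta, params.mu
    one_minus_exp = -math.expm1(-mu)
    mean = (1.0 - theta) * mu / one_minus_exp
    second_moment = (1.0 - theta) * (mu + mu * mu) / one_minus_exp
    variance = second_moment - mean * mean
    return mean, max(variance, 0.0)


def ztp_loglik(sample, mu: float) -> float:
    """Log-likelihood of positive counts under a zero-truncated Poisson.

    ``LL+ = -N+ log(1 - e^{-mu}) + log(mu) * sum(y) - N+ * mu - sum(log y!)``
    """
    values = _as_positive_values(sample)
    if not mu > 0.0:
        raise ValueError(f"mu must be > 0, got {mu}")
    n = values.size
    return float(
        -n * math.log(-math.expm1(-mu))
        + math.log(mu) * values.sum()
        - n * mu
        - special.gammaln(values + 1).sum()
    )


def ztp_rate_from_mean(target_mean):
    """Invert ``m(mu) = mu / (1 - exp(-mu))`` for an array of target means.

    Vectorized safeguarded Newton iteration; any element that does not reach
    ``|m(mu) - target| < 1e-10`` falls back to scalar bisection (brentq).
    Targets at or below ``1 + 1e-8`` map to :data:`MU_MIN`.
    """
    target = np.atleast_1d(np.asarray(target_mean, dtype=float))
    if np.any(target < 1.0 - 1e-9):
        raise ValueError("ZTP mean targets must be >= 1")
    degenerate = target <= 1.0 + 1e-8
    # the working target keeps degenerate entries on a harmless fixed point
    t_work = np.where(degenerate, 2.0, target)
    mu = np.where(t_work > 2.0, t_work, 2.0 * (t_work - 1.0))
    converged = False
    for _ in range(100):
        one_minus_exp = -np.expm1(-mu)
        f = mu / one_minus_exp - t_work
        if np.max(np.abs(f)) < 1e-10:
            converged = True
            break
        # d/dmu [mu / (1 - e^-mu)]
        deriv = (one_minus_exp - mu * np.exp(-mu)) / (one_minus_exp * one_minus_exp)
        mu = np.clip(mu - f / deriv, mu * 0.1, mu * 10.0 + 1.0)
    if not converged:
        # brentq rescue for stragglers
        bad = np.abs(mu / -np.expm1(-mu) - t_work) >= 1e-10
        for i in np.flatnonzero(bad):
            t = t_work[i]
            hi = max(t, 2.0) * 2.0
            mu[i] = optimize.brentq(
                lambda m: m / -math.expm1(-m) - t, 1e-12, hi, xtol=1e-13, maxiter=200
            )
    mu = np.where(degenerate, MU_MIN, mu)
    if np.isscalar(target_mean):
        return float(mu[0])
    return mu


def ztp_mle(sample) -> float:
    """Maximum-likelihood rate of a zero-truncated Poisson sample.

    Solves ``mean(y) = mu / (1 - exp(-mu))``; returns :data:`MU_MIN` when the
    sample mean is (numerically) 1, where the interior MLE does not exist.
    """
    values = _as_positive_values(sample)
    return float(ztp_rate_from_mean(float(values.mean())))


def zap_sample(theta_vec, mu_vec, seed) -> np.ndarray:
    """Draw one ZAP count per (theta, mu) pair, reproducibly.

    A Bernoulli(theta) draw selects zero; otherwise the positive count comes
    from the inverse CDF of the truncated Poisson (a uniform restricted to
    ``(e^{-mu}, 1]`` pushed through the untruncated Poisson quantile), so the
    cost does not degrade for small ``mu`` the way rejection sampling would.
    """
    theta = np.asarray(theta_vec, dtype=float)
    mu = np.asarray(mu_vec, dtype=float)
    if theta.shape != mu.shape:
        raise ValueError(f"shape mismatch: theta {theta.shape} vs mu {mu.shape}")
    if np.any(theta < 0) or np.any(theta >= 1):
        raise ValueError("theta entries must be in [0, 1)")
    if np.any(mu <= 0):
        raise ValueError("mu entries must be > 0")
    rng = np.random.default_rng(seed)
    is_zero = rng.random(theta.shape) < theta
    u = rng.random(mu.shape)
    p0 = np.exp(-mu)
    # map U(0,1) onto (P(Y=0), 1] of the untruncated Poisson CDF
    counts = stats.poisson.ppf(p0 + u * (1.0 - p0), mu).astype(np.int64)
    counts = np.maximum(counts, 1)
    counts[is_zero] = 0
    return counts
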