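"""Entropy, mutual information, and expected-posterior-entropy estimators.

All quantities are in nats.  Closed forms wrap scipy's distribution
entropies; sample-based estimates use the Kozachenko–Leonenko k-th
nearest-neighbor estimator, and the Monte Carlo estimate of the expected
posterior entropy (EPE) averages the negative log posterior density over
joint prior-predictive draws — the same quantity that serves as the training
loss of the mixture-density compression network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from scipy import special, stats
from scipy.spatial import cKDTree

__all__ = [
    "InfoEstimate",
    "gamma_entropy",
    "normal_entropy",
    "uniform_entropy",
    "knn_entropy",
    "knn_mutual_information",
    "epe_estimate",
    "cpe_of_abc_posterior",
]

DEFAULT_K = 4


@dataclass(frozen=True)
class InfoEstimate:
    """An information-theoretic estimate with its provenance."""

    value: float
    estimator: Literal["closed_form", "knn", "monte_carlo"]
    sample_count: int = 0
    k_nn: Optional[int] = None

    def __float__(self) -> float:
        return float(self.value)


def gamma_entropy(shape: float, rate: float) -> float:
    """Differential entropy of Gamma(shape, rate):
    ``shape - ln(rate) + ln Gamma(shape) + (1 - shape) psi(shape)``."""
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    return float(stats.gamma(a=shape, scale=1.0 / rate).entropy())


def normal_entropy(sd: float) -> float:
    """Differential entropy of a normal with standard deviation ``sd``."""
    if sd <= 0:
        raise ValueError("standard deviation must be positive")
    return float(0.5 * np.log(2.0 * np.pi * np.e * sd ** 2))


def uniform_entropy(lo: float, hi: float) -> float:
    if not lo < hi:
        raise ValueError("requires lo < hi")
    return float(np.log(hi - lo))


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def knn_entropy(samples, k: int = DEFAULT_K,
                on_duplicates: Literal["raise", "jitter"] = "raise",
                rng=None) -> InfoEstimate:
    """Kozachenko–Leonenko k-th nearest-neighbor entropy estimate.

    ``H_hat = psi(m) - psi(k) + ln c_d + (d / m) sum_i ln eps_i`` with
    ``eps_i`` the Euclidean distance from sample i to its k-th neighbor and
    ``c_d`` the volume of the unit d-ball.  Duplicate points give zero
    distances; by default this fails loudly, or a tiny jitter can be added.
    """
    x = _as_2d(samples)
    m, d = x.shape
    if k < 1 or m <= k:
        raise ValueError("requires m > k_nn >= 1")
    tree = cKDTree(x)
    eps = tree.query(x, k=k + 1, workers=-1)[0][:, k]
    if np.any(eps == 0):
        if on_duplicates == "jitter":
            rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            scale = 1e-10 * max(1.0, float(np.abs(x).max()))
            x = x + scale * rng.standard_normal(x.shape)
            eps = cKDTree(x).query(x, k=k + 1, workers=-1)[0][:, k]
        else:
            raise ValueError(
                "duplicate points give zero k-NN distance; pass on_duplicates='jitter'"
            )
    log_cd = (d / 2.0) * np.log(np.pi) - special.gammaln(d / 2.0 + 1.0)
    value = special.digamma(m) - special.digamma(k) + log_cd + d * float(np.mean(np.log(eps)))
    return InfoEstimate(float(value), "knn", sample_count=m, k_nn=k)


def knn_mutual_information(x, y, k: int = DEFAULT_K, clip_negative: bool = False,
                           on_duplicates: Literal["raise", "jitter"] = "raise",
                           rng=None) -> InfoEstimate:
    """MI via the three-entropy decomposition ``H(x) + H(y) - H([x, y])``,
    each term estimated with :func:`knn_entropy` under a shared metric.
    Exactly symmetric in its arguments by construction."""
    x, y = _as_2d(x), _as_2d(y)
    if len(x) != len(y):
        raise ValueError("x and y must share the sample count")
    kwargs = dict(k=k, on_duplicates=on_duplicates, rng=rng)
    hx = knn_entropy(x, **kwargs).value
    hy = knn_entropy(y, **kwargs).value
    hxy = knn_entropy(np.column_stack([x, y]), **kwargs).value
    value = hx + hy - hxy
    if clip_negative:
        value = max(value, 0.0)
    return InfoEstimate(float(value), "knn", sample_count=len(x), k_nn=k)


def epe_estimate(log_density: Callable, params, summaries,
                 vectorized: bool = False) -> InfoEstimate:
    """Monte Carlo estimate of the expected posterior entropy:
    ``-(1/m) sum_i log f_hat(theta_i | t_i)`` over joint draws.

    ``log_density(theta_row, t_row)`` returns the log conditional density;
    with ``vectorized=True`` it is called once on the full (m, p) and (m, q)
    arrays and must return an (m,) array.
    """
    params = _as_2d(params)
    summaries = _as_2d(summaries)
    if len(params) != len(summaries):
        raise ValueError("params and summaries must share length m")
    if vectorized:
        logf = np.asarray(log_density(params, summaries), dtype=float).ravel()
    else:
        logf = np.array([
            float(log_density(params[i], summaries[i])) for i in range(len(params))
        ])
    bad = np.flatnonzero(~np.isfinite(logf))
    if bad.size:
        raise FloatingPointError(f"non-finite log density at indices {bad[:5].tolist()}")
    return InfoEstimate(float(-np.mean(logf)), "monte_carlo", sample_count=len(params))


def cpe_of_abc_posterior(samples, k: int = DEFAULT_K, **kwargs) -> float:
    """Conditional posterior entropy of one example's accepted parameter
    draws, estimated by nearest neighbors."""
    return knn_entropy(samples, k=k, **kwargs).value
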