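"""Rejection ABC against a reference table, plus greedy min-CPE selection.

Summaries are standardized to zero mean and unit variance using moments from
the training split, distances are Euclidean in the standardized space, and
acceptance is by count: the ``s`` table rows closest to the observed
summaries are the approximate posterior sample.  Ties are broken by
ascending row index so the pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .info import DEFAULT_K, knn_entropy

__all__ = [
    "standardize",
    "summary_moments",
    "RejectionABC",
    "PosteriorSamples",
    "rejection_sample",
    "min_cpe_select",
    "save_posterior_samples",
    "load_posterior_samples",
]


def summary_moments(train_summaries) -> tuple[np.ndarray, np.ndarray]:
    """Per-summary mean and standard deviation from the training split."""
    t = np.atleast_2d(np.asarray(train_summaries, dtype=float))
    mean = t.mean(axis=0)
    sd = t.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"summary column(s) {zero.tolist()} have zero variance")
    return mean, sd


def standardize(summaries, moments) -> np.ndarray:
    """Columnwise ``(t - mean) / sd`` with training-split moments."""
    mean, sd = moments
    return (np.atleast_2d(np.asarray(summaries, dtype=float)) - mean) / sd


@dataclass
class PosteriorSamples:
    """Accepted parameter draws for one observed example."""

    params: np.ndarray  # (s, p)
    provenance: str = "abc"  # {"abc", "mdn", "quadrature", "prior"}
    distances: Optional[np.ndarray] = None  # sorted non-decreasing
    indices: Optional[np.ndarray] = None

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.distances is not None:
            d = np.asarray(self.distances, dtype=float)
            if np.any(np.diff(d) < 0):
                raise ValueError("distances must be sorted non-decreasing")
            self.distances = d

    @property
    def s(self) -> int:
        return len(self.params)


def save_posterior_samples(samples: Sequence[PosteriorSamples], path):
    """Persist per-example accepted draws as HDF5 (/samples, /distances)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.stack([p.params for p in samples]))
        if all(p.distances is not None for p in samples):
            f.create_dataset("distances",
                             data=np.stack([p.distances for p in samples]))
        f.attrs["provenance"] = samples[0].provenance


def load_posterior_samples(path) -> list[PosteriorSamples]:
    import h5py

    with h5py.File(path, "r") as f:
        params = f["samples"][...]
        dists = f["distances"][...] if "distances" in f else None
        provenance = f.attrs.get("provenance", "abc")
    return [PosteriorSamples(params=params[i], provenance=provenance,
                             distances=None if dists is None else dists[i])
            for i in range(len(params))]


class RejectionABC(BaseEstimator):
    """Nearest-neighbor rejection sampler over a summary reference table.

    ``fit`` stores the table parameters and standardization moments;
    ``sample`` returns, for each observed summary vector, the ``accept_count``
    parameter rows with the smallest Euclidean distance in standardized
    summary space.
    """

    def __init__(self, accept_count: int = 1000):
        self.accept_count = accept_count

    def fit(self, summaries, params):
        params = np.atleast_2d(np.asarray(params, dtype=float))
        summaries = np.atleast_2d(np.asarray(summaries, dtype=float))
        if params.shape[0] == 1 and summaries.shape[0] > 1:
            params = params.T
        if len(params) != len(summaries):
            raise ValueError("summaries and params must share length m")
        if self.accept_count > len(params):
            raise ValueError("accept_count exceeds the reference-table size")
        self.moments_ = summary_moments(summaries)
        self.table_summaries_ = standardize(summaries, self.moments_)
        self.table_params_ = params
        return self

    def _accept_one(self, t_obs: np.ndarray) -> PosteriorSamples:
        d2 = np.sum((self.table_summaries_ - t_obs) ** 2, axis=1)
        s = self.accept_count
        if s == len(d2):
            idx = np.arange(len(d2))
        else:
            # exact s smallest with ties at the threshold broken by row index
            thr = np.partition(d2, s - 1)[s - 1]
            below = np.flatnonzero(d2 < thr)
            ties = np.flatnonzero(d2 == thr)
            idx = np.concatenate([below, ties[:s - below.size]])
        order = np.lexsort((idx, d2[idx]))
        idx = idx[order]
        return PosteriorSamples(
            params=self.table_params_[idx], provenance="abc",
            distances=np.sqrt(d2[idx]), indices=idx,
        )

    def sample(self, observed_summaries, standardized: bool = False):
        """Accepted samples per observed example.

        Returns a single :class:`PosteriorSamples` for a 1-D input, else a
        list of them.  ``observed_summaries`` are raw by default and are
        standardized with the table's training moments.
        """
        obs = np.asarray(observed_summaries, dtype=float)
        single = obs.ndim == 1
        obs = np.atleast_2d(obs)
        if not standardized:
            obs = standardize(obs, self.moments_)
        out = [self._accept_one(row) for row in obs]
        return out[0] if single else out


def rejection_sample(observed_t, table_summaries, table_params,
                     accept_count: int = 1000) -> PosteriorSamples:
    """One-shot rejection ABC for a single observed summary vector."""
    abc = RejectionABC(accept_count).fit(table_summaries, table_params)
    return abc.sample(observed_t)


def min_cpe_select(observed_summaries, table_summaries, table_params,
                   accept_count: int = 1000, k_nn: int = DEFAULT_K,
                   candidate_names: Optional[Sequence[str]] = None,
                   return_trace: bool = False):
    """Greedy subset selection by minimizing the conditional posterior entropy.

    Starting from the empty set — scored by the prior entropy estimated from
    the table's parameter draws — each round adds the candidate summary whose
    inclusion yields the lowest nearest-neighbor entropy of the ABC-accepted
    parameters, stopping when no candidate lowers the current entropy.  The
    selected subset may be empty: when the observed data are unsurprising,
    conditioning can *increase* the posterior entropy and this criterion then
    discards even a sufficient statistic.
    """
    obs = np.asarray(observed_summaries, dtype=float).ravel()
    table_summaries = np.atleast_2d(np.asarray(table_summaries, dtype=float))
    table_params = np.atleast_2d(np.asarray(table_params, dtype=float))
    if table_params.shape[0] == 1 and table_summaries.shape[0] > 1:
        table_params = table_params.T
    c = table_summaries.shape[1]
    if obs.size != c:
        raise ValueError("observed summaries must match the candidate count")
    if c < 1:
        raise ValueError("need at least one candidate")
    names = list(candidate_names) if candidate_names is not None else list(range(c))

    current_cpe = knn_entropy(table_params, k=k_nn).value  # empty set: prior entropy
    selected: list[int] = []
    remaining = list(range(c))
    trace = [([], current_cpe)]
    while remaining:
        scores = []
        for j in remaining:
            cols = selected + [j]
            post = rejection_sample(obs[cols], table_summaries[:, cols],
                                    table_params, accept_count)
            scores.append(knn_entropy(post.params, k=k_nn).value)
        best = int(np.argmin(scores))
        if scores[best] >= current_cpe:
            break
        current_cpe = scores[best]
        selected.append(remaining.pop(best))
        trace.append(([names[i] for i in selected], current_cpe))
    result = [names[i] for i in selected]
    if return_trace:
        return result, selected, trace
    return result
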