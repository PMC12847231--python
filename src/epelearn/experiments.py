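"""Config-driven reproduction of the reference analyses.

Each ``run_*`` function wires simulators, summary extractors, rejection ABC
and the evaluation metrics into one pipeline and returns aggregated metric
reports.  Problem sizes default to the full study conditions but every run
accepts smaller tables so pipelines can be exercised at reduced scale; the
method ranking is expected to be stable under proportional scaling even
though absolute metric values drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import info
from .abc import RejectionABC, min_cpe_select
from .evaluation import (KDEConfig, MetricReport, aggregate,
                         benchmark_true_posterior, nlp_kde, rmise)
from .mdn import MDNCompressor
from .regression import LinearPosteriorMean, NonlinearPosteriorMean, PLSSummaries
from .simulators import (ReferenceTable, benchmark_candidate_summaries,
                         gamma_posterior, simulate_benchmark,
                         simulate_gamma_toy, simulate_piecewise,
                         simulate_tree_table, tree_candidate_summary_table)

__all__ = [
    "run_gamma_toy",
    "run_piecewise",
    "run_benchmark",
    "run_growing_tree",
    "load_candidate_summary_table",
    "BENCHMARK_METHODS",
    "TREE_METHODS",
]

BENCHMARK_METHODS = ("likelihood", "expert", "mdn_compression", "mdn",
                     "nonlinear_regression", "linear_regression", "min_cpe",
                     "pls", "prior")
TREE_METHODS = ("expert", "mdn_compression", "mdn", "nonlinear_regression",
                "linear_regression", "min_cpe", "pls", "prior")


# -- gamma toy -----------------------------------------------------------

def run_gamma_toy(a: float = 1.5, b: float = 1.0, n: int = 4, m: int = 10 ** 5,
                  t_example: float = 0.3, seed=0) -> dict:
    """Closed-form and Monte Carlo quantities for the conjugate gamma toy.

    Returns the prior entropy, the conditional posterior entropy at the
    example second moment, the Monte Carlo expected posterior entropy of the
    sufficient statistic, and the prior-predictive fraction of draws whose
    posterior entropy exceeds the prior entropy.
    """
    rng = np.random.default_rng(seed)
    prior_entropy = info.gamma_entropy(a, b)
    cpe_example = info.gamma_entropy(*gamma_posterior(a, b, n, t_example))
    table = simulate_gamma_toy(a, b, n, m, rng)
    theta = table.params[:, 0]
    t = table.summaries[:, 0]
    alpha, beta = a + n / 2.0, b + n * t / 2.0
    # vectorized gamma entropy: alpha is shared, beta varies over draws
    post_entropy = (alpha - np.log(beta) + special.gammaln(alpha)
                    + (1.0 - alpha) * special.digamma(alpha))
    epe = float(np.mean(-stats.gamma.logpdf(theta, a=alpha, scale=1.0 / beta)))
    return {
        "prior_entropy": prior_entropy,
        "cpe_at_example": cpe_example,
        "epe": epe,
        "fraction_cpe_increase": float(np.mean(post_entropy > prior_entropy)),
    }


# -- piecewise model -----------------------------------------------------

def run_piecewise(m: int = 10 ** 5, n: int = 100, prior_sd: float = 0.25,
                  k_nn: int = info.DEFAULT_K, seed=0) -> dict:
    """Mutual information between the parameter and each candidate summary
    (sample mean, log sample variance), under priors centred at -1 and +1."""
    rng = np.random.default_rng(seed)
    out = {}
    for label, center in (("left", -1.0), ("right", 1.0)):
        table = simulate_piecewise(center, prior_sd, n, m, rng)
        y = table.payloads[:, :, 0]
        theta = table.params[:, 0]
        summaries = {
            "mean": y.mean(axis=1),
            "log_var": np.log(y.var(axis=1, ddof=1)),
        }
        for name, t in summaries.items():
            out[(label, name)] = info.knn_mutual_information(theta, t, k=k_nn).value
    return out


# -- shared pipeline helpers --------------------------------------------

@dataclass
class ExperimentResult:
    """Aggregated NLP and RMISE per method, plus run metadata."""

    experiment: str
    reports: dict = field(default_factory=dict)  # method -> {metric: MetricReport}
    meta: dict = field(default_factory=dict)

    def nlp(self, method: str) -> MetricReport:
        return self.reports[method]["nlp"]

    def rmise(self, method: str) -> MetricReport:
        return self.reports[method]["rmise"]

    def to_frame(self) -> pd.DataFrame:
        rows = [self.reports[meth][met].row()
                for meth in self.reports for met in self.reports[meth]]
        return pd.DataFrame(rows)


def _score_samples(samples_per_example, test_params, kde_config, experiment,
                   method) -> dict:
    nlps, rmises = [], []
    for samples, theta in zip(samples_per_example, test_params):
        nlps.append(nlp_kde(samples, theta, kde_config))
        rmises.append(rmise(samples, theta))
    return {
        "nlp": aggregate(nlps, method, experiment, "nlp"),
        "rmise": aggregate(rmises, method, experiment, "rmise"),
    }


def _abc_samples(train_summaries, train_params, test_summaries, s):
    abc = RejectionABC(accept_count=s).fit(train_summaries, train_params)
    return [post.params for post in abc.sample(test_summaries)]


# -- benchmark experiment ------------------------------------------------

def run_benchmark(train_m: int = 10 ** 6, val_m: int = 10 ** 4,
                  test_m: int = 10 ** 3, n: int = 10, s: int = 1000,
                  methods: Sequence[str] = BENCHMARK_METHODS, seed=0,
                  max_epochs: int = 500) -> ExperimentResult:
    """Tanh-mixture benchmark: simulate tables, extract summaries with each
    method, run rejection ABC, and aggregate NLP / RMISE over the test set."""
    rng = np.random.default_rng(seed)
    train = simulate_benchmark(n, train_m, rng)
    val = simulate_benchmark(n, val_m, rng)
    test = simulate_benchmark(n, test_m, rng)
    kde_config = KDEConfig()  # unbounded parameter space
    result = ExperimentResult("benchmark", meta={
        "train_m": train_m, "val_m": val_m, "test_m": test_m, "n": n, "s": s,
    })
    needs_candidates = {"expert", "linear_regression", "min_cpe", "pls"} & set(methods)
    if needs_candidates:
        cand_train = benchmark_candidate_summaries(train.payloads)
        cand_test = benchmark_candidate_summaries(test.payloads)

    mdn_est = None
    if {"mdn_compression", "mdn"} & set(methods):
        mdn_est = MDNCompressor(
            compressor="set_mlp", compressor_hidden=(16, 16), output_dim=1,
            family="gaussian", n_components=2, batch_size=512,
            max_epochs=max_epochs, random_state=int(rng.integers(2 ** 31)),
        )
        mdn_est.fit(train.payloads, train.params,
                    validation_data=(val.payloads, val.params))
        result.meta["mdn_val_loss"] = mdn_est.best_val_loss_

    for method in methods:
        if method == "prior":
            samples = [rng.standard_normal((s, 1)) for _ in range(test_m)]
        elif method == "likelihood":
            samples = [benchmark_true_posterior(test.payloads[i]).sample(s, rng)
                       for i in range(test_m)]
        elif method == "mdn_compression":
            t_train = mdn_est.transform(train.payloads)
            t_test = mdn_est.transform(test.payloads)
            samples = _abc_samples(t_train, train.params, t_test, s)
        elif method == "mdn":
            samples = list(mdn_est.sample(test.payloads, s, rng))
        elif method == "nonlinear_regression":
            reg = NonlinearPosteriorMean(
                compressor="set_mlp", compressor_hidden=(16, 16),
                batch_size=512, max_epochs=max_epochs,
                random_state=int(rng.integers(2 ** 31)),
            )
            reg.fit(train.payloads, train.params,
                    validation_data=(val.payloads, val.params))
            samples = _abc_samples(reg.transform(train.payloads), train.params,
                                   reg.transform(test.payloads), s)
        elif method == "linear_regression":
            lin = LinearPosteriorMean().fit(cand_train, train.params)
            samples = _abc_samples(lin.transform(cand_train), train.params,
                                   lin.transform(cand_test), s)
        elif method == "expert":
            samples = _abc_samples(cand_train, train.params, cand_test, s)
        elif method == "pls":
            pls = PLSSummaries(folds=5, random_state=int(rng.integers(2 ** 31)))
            pls.fit(cand_train, train.params)
            samples = _abc_samples(pls.transform(cand_train), train.params,
                                   pls.transform(cand_test), s)
            result.meta["pls_components"] = pls.n_components_
        elif method == "min_cpe":
            samples = _min_cpe_samples(cand_train, train.params, cand_test, s, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        result.reports[method] = _score_samples(
            samples, test.params, kde_config, "benchmark", method)
    return result


def _min_cpe_samples(cand_train, train_params, cand_test, s, rng):
    """Greedy min-CPE selection per test example, then ABC with the chosen
    subset; an empty selection falls back to prior draws from the table."""
    samples = []
    m = len(train_params)
    for obs in cand_test:
        selected = min_cpe_select(obs, cand_train, train_params, accept_count=s)
        if selected:
            cols = list(selected)
            abc = RejectionABC(accept_count=s).fit(cand_train[:, cols], train_params)
            samples.append(abc.sample(obs[cols]).params)
        else:
            idx = rng.choice(m, size=s, replace=False)
            samples.append(np.atleast_2d(train_params)[idx])
    return samples


# -- growing-tree experiment ---------------------------------------------

def run_growing_tree(train_m: int = 10 ** 5, val_m: int = 10 ** 3,
                     test_m: int = 10 ** 3, n: int = 100, s: int = 1000,
                     methods: Sequence[str] = TREE_METHODS, seed=0,
                     max_epochs: int = 500, prior=(0.0, 2.0),
                     mdn_components: int = 10) -> ExperimentResult:
    """Preferential-attachment trees: infer the attachment exponent.

    Neural methods use the GIN compressor; candidate-based methods use the
    degree/diameter/betweenness summaries plus a uniform distractor.  NLP
    uses boundary reflection on the prior support.
    """
    rng = np.random.default_rng(seed)
    lo, hi = prior
    train = simulate_tree_table(lo, hi, n, train_m, rng)
    val = simulate_tree_table(lo, hi, n, val_m, rng)
    test = simulate_tree_table(lo, hi, n, test_m, rng)
    kde_config = KDEConfig(bounds=[(lo, hi)])
    result = ExperimentResult("growing_tree", meta={
        "train_m": train_m, "val_m": val_m, "test_m": test_m, "n": n, "s": s,
    })
    needs_candidates = {"expert", "linear_regression", "min_cpe", "pls"} & set(methods)
    if needs_candidates:
        cand_train = tree_candidate_summary_table(train, rng)
        cand_test = tree_candidate_summary_table(test, rng)

    mdn_est = None
    if {"mdn_compression", "mdn"} & set(methods):
        mdn_est = MDNCompressor(
            compressor="gin", compressor_hidden=(8,), output_dim=1,
            family="gaussian", n_components=mdn_components, batch_size=32,
            max_epochs=max_epochs, random_state=int(rng.integers(2 ** 31)),
        )
        mdn_est.fit(train.payloads, train.params,
                    validation_data=(val.payloads, val.params))
        result.meta["mdn_val_loss"] = mdn_est.best_val_loss_

    for method in methods:
        if method == "prior":
            samples = [rng.uniform(lo, hi, size=(s, 1)) for _ in range(test_m)]
        elif method == "mdn_compression":
            t_train = mdn_est.transform(train.payloads)
            t_test = mdn_est.transform(test.payloads)
            samples = _abc_samples(t_train, train.params, t_test, s)
        elif method == "mdn":
            samples = list(mdn_est.sample(test.payloads, s, rng))
        elif method == "nonlinear_regression":
            reg = NonlinearPosteriorMean(
                compressor="gin", compressor_hidden=(8,), batch_size=32,
                max_epochs=max_epochs, random_state=int(rng.integers(2 ** 31)),
            )
            reg.fit(train.payloads, train.params,
                    validation_data=(val.payloads, val.params))
            samples = _abc_samples(reg.transform(train.payloads), train.params,
                                   reg.transform(test.payloads), s)
        elif method == "linear_regression":
            lin = LinearPosteriorMean().fit(cand_train, train.params)
            samples = _abc_samples(lin.transform(cand_train), train.params,
                                   lin.transform(cand_test), s)
        elif method == "expert":
            samples = _abc_samples(cand_train, train.params, cand_test, s)
        elif method == "pls":
            pls = PLSSummaries(folds=5, random_state=int(rng.integers(2 ** 31)))
            pls.fit(cand_train, train.params)
            samples = _abc_samples(pls.transform(cand_train), train.params,
                                   pls.transform(cand_test), s)
            result.meta["pls_components"] = pls.n_components_
        elif method == "min_cpe":
            samples = _min_cpe_samples(cand_train, train.params, cand_test, s, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        result.reports[method] = _score_samples(
            samples, test.params, kde_config, "growing_tree", method)
    return result


# -- external candidate-summary tables ----------------------------------

def load_candidate_summary_table(path, n_params: int = 2, n_summaries: int = 7,
                                 prior_bounds=(0.0, 10.0)) -> ReferenceTable:
    """Read an externally produced candidate-summary table (CSV with a header
    row: ``n_params`` parameter columns followed by ``n_summaries`` candidate
    columns) into a vector-payload reference table."""
    frame = pd.read_csv(path)
    expected = n_params + n_summaries
    if frame.shape[1] != expected:
        raise ValueError(
            f"expected {expected} columns ({n_params} parameters + "
            f"{n_summaries} summaries), found {list(frame.columns)}"
        )
    params = frame.iloc[:, :n_params].to_numpy(dtype=float)
    payload = frame.iloc[:, n_params:].to_numpy(dtype=float)
    if prior_bounds is not None:
        lo, hi = prior_bounds
        if np.any((params < lo) | (params > hi)):
            warnings.warn("parameters outside the expected prior support")
    return ReferenceTable(params=params, payloads=payload,
                          payload_kind="vector", model="candidate_table")


def save_candidate_summary_table(table: ReferenceTable, path):
    """Round-trip companion to :func:`load_candidate_summary_table`."""
    p = table.params.shape[1]
    c = table.payloads.shape[1]
    columns = [f"param_{i}" for i in range(p)] + [f"summary_{j}" for j in range(c)]
    pd.DataFrame(np.column_stack([table.params, table.payloads]),
                 columns=columns).to_csv(path, index=False)
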