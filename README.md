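# epelearn

Learning low-dimensional summary statistics for approximate Bayesian
computation (ABC) by minimizing the **expected posterior entropy (EPE)**.

## The problem

Rejection ABC infers parameters θ of a simulator without evaluating its
likelihood: draw `(θᵢ, zᵢ)` from the prior predictive (the *reference
table*), then accept the θᵢ whose simulated data lie closest to the
observation. In high dimensions this only works after compressing the data
to summary statistics `t(y)` — and the choice of `t` caps the fidelity of
the whole inference: as the acceptance tolerance shrinks, ABC converges to
the *summary* posterior `f(θ | t(y))`, not the true posterior `f(θ | y)`.

`epelearn` selects and learns summaries by minimizing the expected posterior
entropy

```
H = −∫ dθ dt p(θ, t) log f(θ | t),
```

estimated from m joint prior-predictive draws as

```
Ĥ = −m⁻¹ Σᵢ log f̂(θᵢ | t(zᵢ)),
```

where `f̂` is a conditional mixture density network (MDN) and `t` is a
bottleneck neural compressor trained end-to-end on this loss. After
training, the compressor output is the summary statistic; maximizing mutual
information I{θ, t}, maximizing expected surprise, and minimizing the
expected KL divergence from the true to the summary posterior are all
equivalent to this objective.

The package is aimed at practitioners of simulation-based inference who
need to benchmark summary-extraction methods against each other on
tractable problems before deploying them.

## What's inside

| Module | Contents |
| --- | --- |
| `simulators` | Conjugate gamma–normal toy, reflected (bimodal) variant, piecewise likelihood, tanh-mixture benchmark, preferential-attachment growing trees; hand-crafted candidate summaries; HDF5 reference tables |
| `info` | Closed-form entropies; Kozachenko–Leonenko k-NN entropy and mutual information; Monte Carlo EPE |
| `compressors` | Permutation-invariant set MLP, tabular MLP, graph isomorphism network (GIN) |
| `mdn` | Gaussian / scaled-beta mixture heads; `MDNCompressor` — end-to-end EPE training |
| `regression` | `LinearPosteriorMean`, `NonlinearPosteriorMean` (quadratic Bayes-risk summaries), `PLSSummaries` |
| `abc` | Summary standardization, count-based rejection sampling, greedy min-CPE subset selection |
| `evaluation` | RMISE; KDE negative log probability with Scott bandwidth and boundary reflection; quadrature gold-standard posterior |
| `experiments` | One-call reproduction pipelines and the external candidate-table reader |

Estimators follow scikit-learn conventions (`fit` / `transform` /
`get_params`; fitted attributes end in `_`) and compose with sklearn
pipelines. All training runs on a tiny built-in reverse-mode autodiff
engine (`_autodiff`) with Adam and a validation-plateau learning-rate
schedule — no deep-learning framework required.

## Worked example

Learn a one-dimensional summary for the benchmark model (a symmetric
two-component normal mixture whose observations have zero mean and unit
variance for *every* θ, plus a pure-noise column — so naive moment matching
fails), then run rejection ABC with it:

```python
import numpy as np
from epelearn import MDNCompressor, RejectionABC, nlp_kde
from epelearn.simulators import simulate_benchmark

rng = np.random.default_rng(0)
train = simulate_benchmark(n=10, m=100_000, rng=rng)
val = simulate_benchmark(n=10, m=10_000, rng=rng)
test = simulate_benchmark(n=10, m=5, rng=rng)

est = MDNCompressor(compressor="set_mlp", n_components=2, output_dim=1,
                    batch_size=512, max_epochs=60, random_state=1)
est.fit(train.payloads, train.params,
        validation_data=(val.payloads, val.params))
print(f"validation EPE: {est.best_val_loss_:.3f}")

abc = RejectionABC(accept_count=1000).fit(est.transform(train.payloads),
                                          train.params)
for post, theta in zip(abc.sample(est.transform(test.payloads)), test.params):
    print(f"true theta {theta[0]:+.2f}  ABC NLP {nlp_kde(post.params, theta):.2f}")
```

This prints:

```
validation EPE: 1.039
true theta -2.46  ABC NLP 1.22
true theta +0.44  ABC NLP 0.85
true theta +0.07  ABC NLP 0.67
true theta -1.04  ABC NLP 1.25
...
```

The validation EPE (≈ 1.04 nats) sits between the prior entropy
½ln(2πe) ≈ 1.42 — the ceiling attained by uninformative summaries — and is
close to the likelihood-based test-set NLP ≈ 1.05 from exact quadrature;
per-example NLP values fluctuate around that level (small-|θ| datasets are
easier than large-|θ| ones, whose posteriors are strongly bimodal). A posterior-mean regression summary instead
collapses to ≈ 1.42 here, because the posterior is bimodal and its mean is
zero for every dataset.

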