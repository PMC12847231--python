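"""Mixture-density heads and end-to-end MDN compression.

The conditional posterior approximation given summaries ``t`` is a mixture

    f_hat(theta | t) = sum_j softmax_j(eta(t)) * component_j(theta | t),

where the mixture logits ``eta`` and per-component parameters are each
produced by an independent two-layer MLP (one hidden layer of 16 tanh units
followed by a linear output) acting on the summaries.  Two component
families are supported: normals parameterized by locations ``mu`` and
log-scales ``kappa`` (variance ``exp(2 kappa)``), and beta distributions
rescaled to a bounded support ``(lo, hi)`` parameterized by log shapes.

:class:`MDNCompressor` trains a bottleneck compressor jointly with the
mixture head by minimizing the Monte Carlo estimate of the expected
posterior entropy, ``-(1/m) sum_i log f_hat(theta_i | t(z_i))``.  After
training, the compressor output *is* the learned summary statistic; the head
additionally provides direct posterior sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator, TransformerMixin

from . import _autodiff as ad
from ._training import TrainConfig, TrainHistory, fit_minibatch
from .compressors import CompressorConfig, CompressorState, build_compressor

__all__ = [
    "MDNConfig",
    "MixtureParams",
    "mdn_log_prob",
    "mdn_sample",
    "scaled_beta_log_prob",
    "MDNCompressor",
    "train_mdn_compressor",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MDNConfig:
    family: str = "gaussian"  # or "scaled_beta"
    n_components: int = 2
    param_dim: int = 1
    summary_dim: int = 1
    hidden: int = 16
    support: Optional[tuple] = None  # (lo, hi) for scaled_beta

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("need at least one mixture component")
        if self.family == "scaled_beta":
            if self.support is None or not self.support[0] < self.support[1]:
                raise ValueError("scaled_beta requires support bounds lo < hi")
        elif self.family != "gaussian":
            raise ValueError(f"unknown component family {self.family!r}")


@dataclass
class MixtureParams:
    """Per-example mixture parameters (leading axis = examples)."""

    family: str
    logits: np.ndarray  # (m, k)
    loc: Optional[np.ndarray] = None        # gaussian: (m, k, p)
    log_scale: Optional[np.ndarray] = None  # gaussian: (m, k, p)
    log_alpha: Optional[np.ndarray] = None  # scaled_beta: (m, k, p)
    log_beta: Optional[np.ndarray] = None   # scaled_beta: (m, k, p)
    support: Optional[tuple] = None

    def __len__(self):
        return len(self.logits)

    def __getitem__(self, i) -> "MixtureParams":
        out = MixtureParams(self.family, np.atleast_2d(self.logits[i]),
                            support=self.support)
        for name in ("loc", "log_scale", "log_alpha", "log_beta"):
            val = getattr(self, name)
            if val is not None:
                val = val[i]
                if np.isscalar(i):
                    val = val[None]
                setattr(out, name, val)
        return out

    @property
    def weights(self) -> np.ndarray:
        return special.softmax(self.logits, axis=-1)

    def log_prob(self, theta) -> np.ndarray:
        """Log mixture density at ``theta`` ((m, p) or (p,)) per example."""
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 1:
            theta = np.broadcast_to(theta[None], (len(self), theta.size))
        th = theta[:, None, :]  # (m, 1, p)
        logw = self.logits - special.logsumexp(self.logits, axis=1, keepdims=True)
        if self.family == "gaussian":
            comp = -self.log_scale - 0.5 * _LOG_2PI \
                - 0.5 * np.exp(-2.0 * self.log_scale) * (th - self.loc) ** 2
            comp = comp.sum(axis=2)
        else:
            lo, hi = self.support
            inside = np.all((theta > lo) & (theta < hi), axis=1)
            x = np.clip((th - lo) / (hi - lo), 1e-300, 1.0 - 1e-16)
            alpha, beta = np.exp(self.log_alpha), np.exp(self.log_beta)
            comp = ((alpha - 1) * np.log(x) + (beta - 1) * np.log1p(-x)
                    - special.betaln(alpha, beta) - np.log(hi - lo))
            comp = comp.sum(axis=2)
            out = special.logsumexp(logw + comp, axis=1)
            return np.where(inside, out, -np.inf)
        return special.logsumexp(logw + comp, axis=1)

    def sample(self, s: int, rng=None) -> np.ndarray:
        """Ancestral sampling: (m, s, p) draws."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        m, k = self.logits.shape
        w = self.weights
        comp = np.array([rng.choice(k, size=s, p=w[i]) for i in range(m)])
        rows = np.arange(m)[:, None]
        if self.family == "gaussian":
            loc = self.loc[rows, comp]           # (m, s, p)
            scale = np.exp(self.log_scale[rows, comp])
            return loc + scale * rng.standard_normal(loc.shape)
        lo, hi = self.support
        alpha = np.exp(self.log_alpha[rows, comp])
        beta = np.exp(self.log_beta[rows, comp])
        return lo + (hi - lo) * rng.beta(alpha, beta)


def mdn_log_prob(params_out: MixtureParams, theta) -> np.ndarray:
    """Log density of the mixture at ``theta``; numerically stable."""
    return params_out.log_prob(theta)


def mdn_sample(params_out: MixtureParams, s: int, rng=None) -> np.ndarray:
    return params_out.sample(s, rng)


def scaled_beta_log_prob(shapes, bounds, theta) -> float:
    """Log density of a beta distribution rescaled to ``bounds`` at ``theta``."""
    alpha, beta = shapes
    lo, hi = bounds
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shapes must be positive")
    if not lo < hi:
        raise ValueError("requires lo < hi")
    theta = float(theta)
    if not lo < theta < hi:
        return -np.inf
    x = (theta - lo) / (hi - lo)
    return float((alpha - 1) * np.log(x) + (beta - 1) * np.log1p(-x)
                 - special.betaln(alpha, beta) - np.log(hi - lo))


class _MDNHead:
    """Independent two-layer MLPs mapping summaries to mixture parameters."""

    def __init__(self, config: MDNConfig):
        self.config = config

    def _head_dims(self):
        c = self.config
        kp = c.n_components * c.param_dim
        if c.family == "gaussian":
            return [("logits", c.n_components), ("loc", kp), ("log_scale", kp)]
        return [("logits", c.n_components), ("log_alpha", kp), ("log_beta", kp)]

    def init_params(self, rng) -> list[ad.Tensor]:
        from .compressors import _init_linear

        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        params = []
        for _, out_dim in self._head_dims():
            params.extend(_init_linear(rng, self.config.summary_dim, self.config.hidden))
            params.extend(_init_linear(rng, self.config.hidden, out_dim))
        return params

    def forward(self, params: Sequence[ad.Tensor], t: ad.Tensor) -> dict:
        out = {}
        for i, (name, _) in enumerate(self._head_dims()):
            w1, b1, w2, b2 = params[4 * i:4 * i + 4]
            out[name] = ad.linear(ad.tanh(ad.linear(t, w1, b1)), w2, b2)
        return out

    def log_prob(self, head_out: dict, theta: np.ndarray) -> ad.Tensor:
        """Differentiable log mixture density; ``theta`` is an (m, p) constant."""
        c = self.config
        m = theta.shape[0]
        k, p = c.n_components, c.param_dim
        th = ad.Tensor(theta[:, None, :])  # (m, 1, p) constant
        logw = ad.log_softmax(head_out["logits"], axis=1)  # (m, k)
        if c.family == "gaussian":
            mu = ad.reshape(head_out["loc"], (m, k, p))
            kappa = ad.reshape(head_out["log_scale"], (m, k, p))
            diff = th - mu
            comp = (-kappa - ad.Tensor(np.array(0.5 * _LOG_2PI))
                    - ad.mul(ad.mul(ad.exp(kappa * (-2.0)), diff * diff),
                             ad.Tensor(np.array(0.5))))
            comp = ad.tensor_sum(comp, axis=2)
        else:
            lo, hi = c.support
            x = np.clip((theta[:, None, :] - lo) / (hi - lo), 1e-12, 1.0 - 1e-12)
            la = ad.reshape(head_out["log_alpha"], (m, k, p))
            lb = ad.reshape(head_out["log_beta"], (m, k, p))
            alpha, beta = ad.exp(la), ad.exp(lb)
            log_x = ad.Tensor(np.log(x))
            log_1mx = ad.Tensor(np.log1p(-x))
            lbeta = ad.gammaln(alpha) + ad.gammaln(beta) - ad.gammaln(alpha + beta)
            comp = ((alpha - 1.0) * log_x + (beta - 1.0) * log_1mx - lbeta
                    - ad.Tensor(np.array(np.log(hi - lo))))
            comp = ad.tensor_sum(comp, axis=2)
        return ad.logsumexp(logw + comp, axis=1)

    def to_mixture(self, head_out: dict) -> MixtureParams:
        c = self.config
        m = head_out["logits"].data.shape[0]
        k, p = c.n_components, c.param_dim
        get = lambda name: head_out[name].data.reshape(m, k, p) if name in head_out else None
        return MixtureParams(
            family=c.family, logits=head_out["logits"].data.copy(),
            loc=get("loc"), log_scale=get("log_scale"),
            log_alpha=get("log_alpha"), log_beta=get("log_beta"),
            support=c.support,
        )


class MDNCompressor(BaseEstimator, TransformerMixin):
    """End-to-end EPE-minimizing summary learner (compressor + mixture head).

    Parameters mirror the training protocol: Adam with an initial learning
    rate of 1e-2, decayed tenfold after ``decay_patience`` validation epochs
    without improvement, stopping after ``stop_patience``; the returned model
    is the one with the lowest validation loss.

    After :meth:`fit`, ``transform`` maps payload batches to learned
    summaries, ``log_prob``/``sample`` expose the conditional mixture, and
    ``loss_history_`` records the optimization trace.
    """

    def __init__(self, compressor="set_mlp", compressor_hidden=(16, 16),
                 output_dim=None, gin_epsilon=0.0, family="gaussian",
                 n_components=2, head_hidden=16, support=None, batch_size=512,
                 learning_rate=1e-2, decay_factor=0.1, decay_patience=10,
                 stop_patience=20, max_epochs=500, random_state=None):
        self.compressor = compressor
        self.compressor_hidden = compressor_hidden
        self.output_dim = output_dim
        self.gin_epsilon = gin_epsilon
        self.family = family
        self.n_components = n_components
        self.head_hidden = head_hidden
        self.support = support
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.decay_patience = decay_patience
        self.stop_patience = stop_patience
        self.max_epochs = max_epochs
        self.random_state = random_state

    # -- internals -------------------------------------------------------
    def _input_dim(self, X) -> int:
        if self.compressor == "gin":
            return 1  # constant all-ones node features
        return np.asarray(X).shape[-1]

    def _batch(self, X, idx=None):
        data = np.asarray(X)
        if idx is not None:
            data = data[idx]
        return self._comp.prepare_batch(data)

    def _forward_summaries(self, batch) -> ad.Tensor:
        return self._comp.forward(self.compressor_state_.params, batch)

    def _loss_tensor(self, batch, theta: np.ndarray) -> ad.Tensor:
        t = self._forward_summaries(batch)
        head_out = self._head.forward(self.head_params_, t)
        logp = self._head.log_prob(head_out, theta)
        return -ad.tensor_mean(logp)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Fit on payloads ``X`` and parameters ``y`` ((m, p) or (m,)).

        ``validation_data`` is an ``(X_val, y_val)`` pair; without it a
        random 10% of the training rows is held out for the schedule.
        """
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and len(X) > 1:
            y = y.T
        rng = np.random.default_rng(self.random_state)
        p = y.shape[1]
        q = self.output_dim if self.output_dim is not None else p
        ccfg = CompressorConfig(
            kind=self.compressor, input_dim=self._input_dim(X),
            hidden=tuple(self.compressor_hidden), output_dim=q,
            gin_epsilon=self.gin_epsilon,
        )
        self._comp = build_compressor(ccfg)
        mcfg = MDNConfig(
            family=self.family, n_components=self.n_components, param_dim=p,
            summary_dim=q, hidden=self.head_hidden,
            support=tuple(self.support) if self.support is not None else None,
        )
        self._head = _MDNHead(mcfg)
        self.mdn_config_ = mcfg
        comp_params = self._comp.init_params(rng)
        self.head_params_ = self._head.init_params(rng)
        self.compressor_state_ = CompressorState(ccfg, comp_params)

        if validation_data is None:
            m = len(y)
            n_val = max(1, m // 10)
            perm = rng.permutation(m)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            X_arr = np.asarray(X)
            X_train, y_train = X_arr[train_idx], y[train_idx]
            X_val, y_val = X_arr[val_idx], y[val_idx]
        else:
            X_train, y_train = np.asarray(X), y
            X_val, y_val = validation_data
            X_val = np.asarray(X_val)
            y_val = np.atleast_2d(np.asarray(y_val, dtype=float))
            if y_val.shape[0] == 1 and len(X_val) > 1:
                y_val = y_val.T
        if len(y_train) == 0 or len(y_val) == 0:
            raise ValueError("empty training or validation table")

        params = comp_params + self.head_params_

        def batch_loss(idx):
            return self._loss_tensor(self._batch(X_train, idx), y_train[idx])

        def val_loss():
            chunk, total, count = 512, 0.0, 0
            for start in range(0, len(y_val), chunk):
                sl = slice(start, start + chunk)
                loss = self._loss_tensor(self._batch(X_val[sl]), y_val[sl])
                total += float(loss.data) * (len(y_val[sl]))
                count += len(y_val[sl])
            return total / count

        config = TrainConfig(
            batch_size=self.batch_size, initial_lr=self.learning_rate,
            lr_decay_factor=self.decay_factor, decay_patience=self.decay_patience,
            stop_patience=self.stop_patience, max_epochs=self.max_epochs,
        )
        history = fit_minibatch(params, batch_loss, len(y_train), val_loss, config, rng)
        self.loss_history_ = history
        self.best_val_loss_ = history.best_val_loss
        self.n_epochs_ = len(history.epochs)
        self.compressor_state_.metadata = {
            "epochs": self.n_epochs_, "best_val_loss": history.best_val_loss,
        }
        return self

    def transform(self, X) -> np.ndarray:
        """Learned summaries t(z) for a payload batch; deterministic."""
        out = []
        X_arr = np.asarray(X)
        for start in range(0, len(X_arr), 2048):
            batch = self._batch(X_arr[start:start + 2048])
            out.append(self._forward_summaries(batch).data)
        return np.concatenate(out, axis=0)

    def predict_mixture(self, X) -> MixtureParams:
        pieces = []
        X_arr = np.asarray(X)
        for start in range(0, len(X_arr), 2048):
            batch = self._batch(X_arr[start:start + 2048])
            t = self._forward_summaries(batch)
            pieces.append(self._head.to_mixture(self._head.forward(self.head_params_, t)))
        out = pieces[0]
        for piece in pieces[1:]:
            out.logits = np.concatenate([out.logits, piece.logits])
            for name in ("loc", "log_scale", "log_alpha", "log_beta"):
                a, b = getattr(out, name), getattr(piece, name)
                if a is not None:
                    setattr(out, name, np.concatenate([a, b]))
        return out

    def log_prob(self, X, theta) -> np.ndarray:
        return self.predict_mixture(X).log_prob(theta)

    def sample(self, X, s: int, random_state=None) -> np.ndarray:
        return self.predict_mixture(X).sample(s, random_state)

    def score(self, X, y) -> float:
        """Negative EPE (higher is better), for sklearn model selection."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and len(X) > 1:
            y = y.T
        return float(np.mean(self.log_prob(X, y)))


def train_mdn_compressor(train_table, val_table, estimator: MDNCompressor = None,
                         **kwargs):
    """Functional wrapper: fit an :class:`MDNCompressor` on reference tables."""
    est = estimator if estimator is not None else MDNCompressor(**kwargs)
    est.fit(train_table.payloads, train_table.params,
            validation_data=(val_table.payloads, val_table.params))
    return est
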