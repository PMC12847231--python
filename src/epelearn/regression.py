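"""Posterior-mean regression summaries and partial least squares.

The posterior mean minimizes the quadratic Bayes risk
``E[(theta - t(z))' A (theta - t(z))]`` over predictors ``t``; its estimate
under this loss is itself used as a summary statistic, implicitly choosing
as many summaries as there are parameters.  Linear predictors regress the
parameters on candidate statistics by ordinary least squares; nonlinear
predictors reuse the neural compressor architectures.  Partial least squares
instead projects candidates onto latent directions most covariant with the
parameters and uses the latent *scores* (not predictions) as summaries, with
the component count chosen by cross-validation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from . import _autodiff as ad
from ._training import TrainConfig, fit_minibatch
from .compressors import CompressorConfig, CompressorState, build_compressor

__all__ = [
    "LinearPosteriorMean",
    "NonlinearPosteriorMean",
    "PLSSummaries",
    "fit_linear_posterior_mean",
    "fit_pls",
]


class LinearPosteriorMean(BaseEstimator, TransformerMixin):
    """OLS estimate of the posterior mean from candidate summaries.

    Candidates are standardized internally (training moments); the fit is
    per-output, so with ``A = I`` the quadratic risk decouples and ordinary
    least squares is exact.  Rank-deficient designs fall back to the
    minimum-norm solution (flagged via ``rank_``).
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and len(X) > 1:
            y = y.T
        if len(X) <= X.shape[1] + 1:
            raise ValueError("need m > c + 1 rows to fit the linear predictor")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            self.scale_ = X.std(axis=0, ddof=0)
            self.scale_ = np.where(self.scale_ == 0, 1.0, self.scale_)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        design = np.column_stack([np.ones(len(Xs)), Xs])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef  # (c + 1, p): intercept first
        self.rank_ = rank
        self.rank_deficient_ = rank < design.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return np.column_stack([np.ones(len(Xs)), Xs]) @ self.coef_

    predict = transform


class NonlinearPosteriorMean(BaseEstimator, TransformerMixin):
    """Neural posterior-mean predictor trained on the quadratic loss.

    Uses the same compressor architectures and optimizer schedule as MDN
    compression; the output dimension equals the parameter dimension.  The
    weight matrix ``A`` defaults to the identity.
    """

    def __init__(self, compressor="set_mlp", compressor_hidden=(16, 16),
                 gin_epsilon=0.0, A=None, batch_size=512, learning_rate=1e-2,
                 decay_factor=0.1, decay_patience=10, stop_patience=20,
                 max_epochs=500, random_state=None):
        self.compressor = compressor
        self.compressor_hidden = compressor_hidden
        self.gin_epsilon = gin_epsilon
        self.A = A
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.decay_patience = decay_patience
        self.stop_patience = stop_patience
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and len(X) > 1:
            y = y.T
        rng = np.random.default_rng(self.random_state)
        p = y.shape[1]
        input_dim = 1 if self.compressor == "gin" else np.asarray(X).shape[-1]
        ccfg = CompressorConfig(
            kind=self.compressor, input_dim=input_dim,
            hidden=tuple(self.compressor_hidden), output_dim=p,
            gin_epsilon=self.gin_epsilon,
        )
        self._comp = build_compressor(ccfg)
        params = self._comp.init_params(rng)
        self.compressor_state_ = CompressorState(ccfg, params)
        A = np.eye(p) if self.A is None else np.asarray(self.A, dtype=float)
        if not np.allclose(A, A.T) or np.any(np.linalg.eigvalsh(A) <= 0):
            raise ValueError("A must be symmetric positive-definite")

        X_arr = np.asarray(X)
        if validation_data is None:
            m = len(y)
            n_val = max(1, m // 10)
            perm = rng.permutation(m)
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            X_train, y_train = X_arr[train_idx], y[train_idx]
            X_val, y_val = X_arr[val_idx], y[val_idx]
        else:
            X_train, y_train = X_arr, y
            X_val, y_val = validation_data
            X_val = np.asarray(X_val)
            y_val = np.atleast_2d(np.asarray(y_val, dtype=float))
            if y_val.shape[0] == 1 and len(X_val) > 1:
                y_val = y_val.T

        def loss_tensor(batch, theta):
            t = self._comp.forward(params, batch)
            diff = t - ad.Tensor(theta)
            # (theta - t)' A (theta - t), averaged over the batch
            quad = ad.tensor_sum(ad.mul(ad.matmul(diff, ad.Tensor(A)), diff), axis=1)
            return ad.tensor_mean(quad)

        def batch_loss(idx):
            return loss_tensor(self._comp.prepare_batch(X_train[idx]), y_train[idx])

        def val_loss():
            total, count = 0.0, 0
            for start in range(0, len(y_val), 512):
                sl = slice(start, start + 512)
                loss = loss_tensor(self._comp.prepare_batch(X_val[sl]), y_val[sl])
                total += float(loss.data) * len(y_val[sl])
                count += len(y_val[sl])
            return total / count

        config = TrainConfig(
            batch_size=self.batch_size, initial_lr=self.learning_rate,
            lr_decay_factor=self.decay_factor, decay_patience=self.decay_patience,
            stop_patience=self.stop_patience, max_epochs=self.max_epochs,
        )
        self.loss_history_ = fit_minibatch(
            params, batch_loss, len(y_train), val_loss, config, rng)
        self.best_val_loss_ = self.loss_history_.best_val_loss
        return self

    def transform(self, X) -> np.ndarray:
        out = []
        X_arr = np.asarray(X)
        for start in range(0, len(X_arr), 2048):
            batch = self._comp.prepare_batch(X_arr[start:start + 2048])
            out.append(self._comp.forward(self.compressor_state_.params, batch).data)
        return np.concatenate(out, axis=0)

    predict = transform


class PLSSummaries(BaseEstimator, TransformerMixin):
    """Latent PLS scores of candidate summaries as ABC summaries.

    The number of components minimizing k-fold cross-validated prediction
    error is selected; candidates are standardized internally.
    """

    def __init__(self, max_components: Optional[int] = None, folds: int = 5,
                 random_state=None):
        self.max_components = max_components
        self.folds = folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] == 1 and len(X) > 1:
            y = y.T
        if self.folds < 2:
            raise ValueError("need at least two folds")
        c = X.shape[1]
        max_r = c if self.max_components is None else self.max_components
        if max_r > c:
            raise ValueError("max_components cannot exceed the candidate count")
        cv = KFold(n_splits=self.folds, shuffle=True,
                   random_state=self.random_state)
        errors = np.zeros(max_r)
        for train_idx, test_idx in cv.split(X):
            for r in range(1, max_r + 1):
                pls = PLSRegression(n_components=r, scale=True)
                pls.fit(X[train_idx], y[train_idx])
                pred = pls.predict(X[test_idx])
                errors[r - 1] += float(np.mean((pred - y[test_idx]) ** 2))
        self.cv_errors_ = errors / self.folds
        self.n_components_ = int(np.argmin(self.cv_errors_)) + 1
        self.pls_ = PLSRegression(n_components=self.n_components_, scale=True)
        self.pls_.fit(X, y)
        return self

    def transform(self, X) -> np.ndarray:
        """Latent scores (projections), not predictions."""
        return self.pls_.transform(np.asarray(X, dtype=float))


# -- thin functional wrappers -------------------------------------------

def fit_linear_posterior_mean(candidates, params) -> np.ndarray:
    """OLS coefficients, intercept row first: (c + 1, p)."""
    return LinearPosteriorMean().fit(candidates, params).coef_


def fit_pls(candidates, params, max_components=None, folds=5, random_state=None):
    est = PLSSummaries(max_components, folds, random_state).fit(candidates, params)
    return est.pls_.x_rotations_, est.n_components_
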