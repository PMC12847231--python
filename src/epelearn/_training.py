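"""Mini-batch Adam training with a validation-plateau schedule.

The learning rate starts at 1e-2 and is cut by an order of magnitude when
the validation loss has not improved for ``decay_patience`` consecutive
epochs; training stops after ``stop_patience`` epochs without improvement,
and the parameters with the best validation loss are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ._autodiff import Adam, Tensor


@dataclass
class TrainConfig:
    batch_size: int = 512
    initial_lr: float = 1e-2
    lr_decay_factor: float = 0.1
    decay_patience: int = 10
    stop_patience: int = 20
    max_epochs: int = 500
    seed: Optional[int] = None

    def __post_init__(self):
        if self.decay_patience < 1 or self.stop_patience < self.decay_patience:
            raise ValueError("require stop_patience >= decay_patience >= 1")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_val_loss: float = np.inf
    best_epoch: int = -1


def fit_minibatch(params: list[Tensor], batch_loss: Callable[[np.ndarray], Tensor],
                  m: int, val_loss: Callable[[], float], config: TrainConfig,
                  rng: np.random.Generator) -> TrainHistory:
    """Optimize ``params`` by mini-batch Adam.

    ``batch_loss(indices)`` returns the scalar loss Tensor for a mini-batch of
    training rows; ``val_loss()`` evaluates the current validation loss.
    """
    opt = Adam(params, lr=config.initial_lr)
    history = TrainHistory()
    best_snapshot = [p.data.copy() for p in params]
    since_best = 0
    lr = config.initial_lr
    for epoch in range(config.max_epochs):
        order = rng.permutation(m)
        losses = []
        for start in range(0, m, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = batch_loss(idx)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        current_val = float(val_loss())
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(current_val)
        history.lr.append(lr)
        if current_val < history.best_val_loss:
            history.best_val_loss = current_val
            history.best_epoch = epoch
            best_snapshot = [p.data.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.stop_patience:
                break
            if since_best % config.decay_patience == 0:
                lr *= config.lr_decay_factor
                opt.lr = lr
    for p, best in zip(params, best_snapshot):
        p.data = best.copy()
    return history
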