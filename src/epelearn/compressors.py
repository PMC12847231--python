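"""Trainable compressors mapping raw data payloads to low-dimensional summaries.

Three architectures, matched to the payload type:

* ``set_mlp`` — a multilayer perceptron applied to each row of an i.i.d.
  data matrix, mean-pooled across rows.  Weight sharing across observations
  makes the map permutation invariant and its parameter count independent of
  the sample size, so learned summaries transfer across sample sizes.
* ``tabular_mlp`` — a plain MLP for payloads that are already a fixed vector
  of candidate statistics (no pooling).
* ``gin`` — a graph isomorphism network for trees: each layer updates node
  features ``h_v`` to ``MLP((1 + eps) h_v + sum_{u in N(v)} h_u)``; the final
  node features are mean-pooled into a graph-level summary.  Constant all-ones
  input features are used because nodes carry no attributes.

Forward evaluation is deterministic given the parameters.  Hidden layers use
tanh activations; the final linear layer of each architecture is unactivated
so summaries are unbounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _autodiff as ad
from .simulators import Tree

__all__ = [
    "CompressorConfig",
    "CompressorState",
    "build_compressor",
    "SetCompressor",
    "TabularCompressor",
    "GINCompressor",
    "set_compressor_forward",
    "tabular_compressor_forward",
    "gin_forward",
]


@dataclass(frozen=True)
class CompressorConfig:
    kind: str  # {"set_mlp", "tabular_mlp", "gin"}
    input_dim: int
    hidden: tuple = (16, 16)
    output_dim: int = 1
    gin_epsilon: float = 0.0

    def __post_init__(self):
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")
        if any(w < 1 for w in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.kind not in {"set_mlp", "tabular_mlp", "gin"}:
            raise ValueError(f"unknown compressor kind {self.kind!r}")


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Fan-in-scaled uniform initialization (weight and bias)."""
    bound = 1.0 / np.sqrt(fan_in)
    w = ad.parameter(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
    b = ad.parameter(rng.uniform(-bound, bound, size=fan_out))
    return w, b


class _MLPCore:
    """Shared parameter bookkeeping for stacked affine layers."""

    def __init__(self, config: CompressorConfig):
        self.config = config

    def _layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.config.input_dim, *self.config.hidden, self.config.output_dim]
        return list(zip(dims[:-1], dims[1:]))

    def init_params(self, rng) -> list[ad.Tensor]:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        params = []
        for fan_in, fan_out in self._layer_dims():
            params.extend(_init_linear(rng, fan_in, fan_out))
        return params

    def _mlp(self, params: Sequence[ad.Tensor], x: ad.Tensor) -> ad.Tensor:
        n_layers = len(self._layer_dims())
        for layer in range(n_layers):
            w, b = params[2 * layer], params[2 * layer + 1]
            x = ad.linear(x, w, b)
            if layer < n_layers - 1:
                x = ad.tanh(x)
        return x


class SetCompressor(_MLPCore):
    """Row-wise MLP followed by mean-pooling over observations."""

    def prepare_batch(self, payloads: np.ndarray) -> np.ndarray:
        z = np.asarray(payloads, dtype=float)
        if z.ndim != 3 or z.shape[-1] != self.config.input_dim:
            raise ValueError("expected an (m, n, d) payload batch matching input_dim")
        return z

    def forward(self, params, batch) -> ad.Tensor:
        x = batch if isinstance(batch, ad.Tensor) else ad.Tensor(batch)
        return ad.tensor_mean(self._mlp(params, x), axis=1)


class TabularCompressor(_MLPCore):
    """Plain MLP on a fixed-length vector of candidate statistics."""

    def prepare_batch(self, payloads: np.ndarray) -> np.ndarray:
        v = np.asarray(payloads, dtype=float)
        if v.ndim != 2 or v.shape[-1] != self.config.input_dim:
            raise ValueError("expected an (m, c) payload batch matching input_dim")
        return v

    def forward(self, params, batch) -> ad.Tensor:
        x = batch if isinstance(batch, ad.Tensor) else ad.Tensor(batch)
        return self._mlp(params, x)


class GINCompressor:
    """Two GIN layers whose update MLPs have two affine layers each; the
    second layer's MLP ends at the output width and node features are then
    mean-pooled into the graph summary."""

    def __init__(self, config: CompressorConfig):
        self.config = config

    def _layer_dims(self):
        h = self.config.hidden[0] if self.config.hidden else 8
        # (in -> h -> h) then (h -> h -> q)
        return [(self.config.input_dim, h), (h, h), (h, h), (h, self.config.output_dim)]

    def init_params(self, rng) -> list[ad.Tensor]:
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        params = []
        for fan_in, fan_out in self._layer_dims():
            params.extend(_init_linear(rng, fan_in, fan_out))
        return params

    def prepare_batch(self, payloads, node_count: int | None = None) -> np.ndarray:
        """Dense (m, n, n) adjacency batch from an (m, n-1, 2) edge-list batch
        (all trees in a table share the node count)."""
        edges = np.asarray(payloads)
        if edges.ndim == 2:
            edges = edges[None]
        m, n_edges, _ = edges.shape
        n = node_count if node_count is not None else n_edges + 1
        adj = np.zeros((m, n, n))
        rows = np.repeat(np.arange(m), n_edges)
        a = edges[:, :, 0].ravel()
        b = edges[:, :, 1].ravel()
        adj[rows, a, b] = 1.0
        adj[rows, b, a] = 1.0
        return adj

    def forward(self, params, adjacency) -> ad.Tensor:
        adj = ad.Tensor(np.asarray(adjacency, dtype=float))
        m, n, _ = adj.data.shape
        h = ad.Tensor(np.ones((m, n, self.config.input_dim)))
        scale = 1.0 + self.config.gin_epsilon
        # layer 1: aggregate, two-layer MLP, tanh output
        agg = ad.add(ad.mul(h, ad.Tensor(np.array(scale))), ad.matmul(adj, h))
        w1, b1, w2, b2 = params[0], params[1], params[2], params[3]
        h = ad.tanh(ad.linear(ad.tanh(ad.linear(agg, w1, b1)), w2, b2))
        # layer 2: aggregate, two-layer MLP with linear output at width q
        agg = ad.add(ad.mul(h, ad.Tensor(np.array(scale))), ad.matmul(adj, h))
        w3, b3, w4, b4 = params[4], params[5], params[6], params[7]
        out = ad.linear(ad.tanh(ad.linear(agg, w3, b3)), w4, b4)
        return ad.tensor_mean(out, axis=1)


def build_compressor(config: CompressorConfig):
    cls = {"set_mlp": SetCompressor, "tabular_mlp": TabularCompressor,
           "gin": GINCompressor}[config.kind]
    return cls(config)


@dataclass
class CompressorState:
    """Trained (or freshly initialized) compressor parameters."""

    config: CompressorConfig
    params: list = field(default_factory=list)  # list of ad.Tensor
    metadata: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        """All trainable parameters as one flat vector."""
        return np.concatenate([p.data.ravel() for p in self.params])

    def forward(self, payload_batch) -> np.ndarray:
        comp = build_compressor(self.config)
        batch = comp.prepare_batch(payload_batch)
        return comp.forward(self.params, batch).data

    def save(self, path):
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        cfg = json.dumps(asdict(self.config))
        np.savez(path, config=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CompressorState":
        with np.load(path) as archive:
            cfg = json.loads(bytes(archive["config"]).decode())
            cfg["hidden"] = tuple(cfg["hidden"])
            params = [ad.parameter(archive[f"p{i}"])
                      for i in range(len(archive.files) - 1)]
        return cls(CompressorConfig(**cfg), params)


# -- thin functional wrappers -------------------------------------------

def set_compressor_forward(state: CompressorState, z: np.ndarray) -> np.ndarray:
    """Summary of a single (n, d) matrix payload."""
    return state.forward(np.asarray(z, dtype=float)[None])[0]


def tabular_compressor_forward(state: CompressorState, v: np.ndarray) -> np.ndarray:
    return state.forward(np.asarray(v, dtype=float)[None])[0]


def gin_forward(state: CompressorState, tree: Tree) -> np.ndarray:
    comp = build_compressor(state.config)
    adj = comp.prepare_batch(tree.edges[None], node_count=tree.node_count)
    return comp.forward(state.params, adj).data[0]
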