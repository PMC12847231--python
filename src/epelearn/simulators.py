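"""Prior-predictive simulators and hand-crafted candidate summaries.

Each simulator draws joint samples ``(theta_i, z_i)`` from a generative model
and returns them as a :class:`ReferenceTable` — the basic currency of
rejection ABC and of summary learning.  Four models are provided:

* a conjugate gamma–normal toy (zero-mean normal observations with gamma
  prior on the precision), whose posterior is available in closed form;
* a *reflected* variant where the precision is ``abs(theta)``, making the
  posterior bimodal and the posterior mean uninformative;
* a piecewise likelihood that switches from a variance-coded to a
  location-coded parameter at ``theta = 0``;
* a benchmark tanh-mixture model whose observations all have zero mean and
  unit variance regardless of the parameter, plus a pure-noise distractor
  column; and
* a preferential-attachment model of growing trees with attachment
  probability proportional to ``degree ** theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "PriorSpec",
    "Tree",
    "ReferenceTable",
    "simulate_gamma_toy",
    "second_moment",
    "gamma_posterior",
    "simulate_reflected_gamma_toy",
    "simulate_piecewise",
    "simulate_benchmark",
    "benchmark_candidate_summaries",
    "simulate_tree",
    "simulate_trees",
    "tree_candidate_summaries",
    "tree_degrees",
]

PayloadKind = Literal["matrix", "vector", "tree"]


@dataclass(frozen=True)
class PriorSpec:
    """Description of a univariate-or-product prior over the parameters."""

    family: Literal["normal", "gamma", "reflected_gamma", "uniform"]
    params: tuple
    dimension: int = 1

    def __post_init__(self):
        if self.family == "gamma" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ValueError("gamma prior requires positive shape and rate")
        if self.family == "uniform" and not self.params[0] < self.params[1]:
            raise ValueError("uniform prior requires lo < hi")


@dataclass(frozen=True)
class Tree:
    """Undirected tree on ``node_count`` nodes as a 0-based edge list."""

    node_count: int
    edges: np.ndarray  # (node_count - 1, 2) integer pairs

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64)
        object.__setattr__(self, "edges", edges)
        n = self.node_count
        if n < 1:
            raise ValueError("tree needs at least one node")
        if edges.shape != (n - 1, 2):
            raise ValueError(f"expected {n - 1} edges, got shape {edges.shape}")
        if edges.size and (edges.min() < 0 or edges.max() >= n):
            raise ValueError("node indices out of range")
        # n nodes with n-1 edges is a tree iff connected (then automatically acyclic)
        if not self._connected():
            raise ValueError("edge list does not describe a connected tree")

    def _connected(self) -> bool:
        n = self.node_count
        if n == 1:
            return True
        adj = [[] for _ in range(n)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    count += 1
                    stack.append(w)
        return count == n

    def degrees(self) -> np.ndarray:
        return tree_degrees(self.edges, self.node_count)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.node_count, self.node_count))
        a[self.edges[:, 0], self.edges[:, 1]] = 1.0
        a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def to_edge_csv(self, path):
        import pandas as pd

        pd.DataFrame(self.edges, columns=["source", "target"]).to_csv(path, index=False)


@dataclass
class ReferenceTable:
    """Joint prior-predictive draws ``(theta_i, z_i[, t_i])``.

    ``payloads`` holds the raw data: an ``(m, n, d)`` float array for matrix
    payloads, an ``(m, c)`` float array for vector payloads (pre-computed
    candidate summaries), or an ``(m, n-1, 2)`` integer edge-list array for
    trees.  ``summaries`` is an optional ``(m, q)`` block of extracted
    summaries; it doubles as the ABC reference table.
    """

    params: np.ndarray
    payloads: np.ndarray
    payload_kind: PayloadKind
    summaries: Optional[np.ndarray] = None
    split: Literal["train", "validation", "test"] = "train"
    model: str = ""
    prior: Optional[PriorSpec] = None
    node_count: Optional[int] = None  # trees only
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[0] == 1 and len(self.payloads) > 1:
            self.params = self.params.T
        if len(self.payloads) != len(self.params):
            raise ValueError("params and payloads must share length m")
        if self.summaries is not None:
            self.summaries = np.atleast_2d(np.asarray(self.summaries, dtype=float))
            if self.summaries.shape[0] != len(self.params):
                raise ValueError("summaries must share length m")
            if not np.all(np.isfinite(self.summaries)):
                raise ValueError("summaries must be finite")

    def __len__(self) -> int:
        return len(self.params)

    @property
    def m(self) -> int:
        return len(self.params)

    @property
    def p(self) -> int:
        return self.params.shape[1]

    def tree(self, i: int) -> Tree:
        if self.payload_kind != "tree":
            raise ValueError("not a tree table")
        return Tree(self.node_count, self.payloads[i])

    def subset(self, idx) -> "ReferenceTable":
        return ReferenceTable(
            params=self.params[idx],
            payloads=self.payloads[idx],
            payload_kind=self.payload_kind,
            summaries=None if self.summaries is None else self.summaries[idx],
            split=self.split,
            model=self.model,
            prior=self.prior,
            node_count=self.node_count,
            meta=dict(self.meta),
        )

    # -- HDF5 persistence ------------------------------------------------
    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("params", data=self.params)
            name = "edges" if self.payload_kind == "tree" else "data"
            f.create_dataset(name, data=self.payloads)
            if self.summaries is not None:
                f.create_dataset("summaries", data=self.summaries)
            f.attrs["payload_kind"] = self.payload_kind
            f.attrs["split"] = self.split
            f.attrs["model"] = self.model
            if self.node_count is not None:
                f.attrs["node_count"] = self.node_count

    @classmethod
    def from_hdf5(cls, path) -> "ReferenceTable":
        import h5py

        with h5py.File(path, "r") as f:
            kind = f.attrs["payload_kind"]
            payloads = f["edges" if kind == "tree" else "data"][...]
            return cls(
                params=f["params"][...],
                payloads=payloads,
                payload_kind=kind,
                summaries=f["summaries"][...] if "summaries" in f else None,
                split=f.attrs.get("split", "train"),
                model=f.attrs.get("model", ""),
                node_count=int(f.attrs["node_count"]) if "node_count" in f.attrs else None,
            )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# -- conjugate gamma toy -------------------------------------------------

def second_moment(y) -> float:
    """Raw second moment ``n^{-1} sum(y_i^2)`` — sufficient for the gamma toy."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("second_moment of empty sample")
    return float(np.mean(y ** 2))


def gamma_posterior(a: float, b: float, n: int, t: float) -> tuple[float, float]:
    """Conjugate update: Gamma(a, b) prior, n zero-mean normal observations
    with second moment t, precision-parameterized likelihood."""
    if a <= 0 or b <= 0:
        raise ValueError("shape and rate must be positive")
    if n < 0:
        raise ValueError("sample size must be non-negative")
    if t < 0:
        raise ValueError("second moment must be non-negative")
    return a + n / 2.0, b + n * t / 2.0


def simulate_gamma_toy(a: float, b: float, n: int, m: int, rng=None,
                       with_summaries: bool = True) -> ReferenceTable:
    """Precision theta ~ Gamma(a, b); observations y_i ~ Normal(0, 1/theta)."""
    if a <= 0 or b <= 0:
        raise ValueError("shape and rate must be positive")
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    rng = _as_rng(rng)
    theta = rng.gamma(shape=a, scale=1.0 / b, size=m)
    y = rng.standard_normal((m, n, 1)) / np.sqrt(theta)[:, None, None]
    summaries = np.mean(y[:, :, 0] ** 2, axis=1, keepdims=True) if with_summaries else None
    return ReferenceTable(
        params=theta[:, None], payloads=y, payload_kind="matrix",
        summaries=summaries, model="gamma_toy",
        prior=PriorSpec("gamma", (a, b)), meta={"n": n, "a": a, "b": b},
    )


def simulate_reflected_gamma_toy(a: float, b: float, n: int, m: int, rng=None,
                                 with_summaries: bool = True) -> ReferenceTable:
    """As the gamma toy, but the precision is ``abs(theta)`` with a random
    sign on theta — the posterior is bimodal with mean zero."""
    rng = _as_rng(rng)
    table = simulate_gamma_toy(a, b, n, m, rng, with_summaries=with_summaries)
    signs = rng.choice([-1.0, 1.0], size=table.m)
    table.params = table.params * signs[:, None]
    table.model = "reflected_gamma_toy"
    table.prior = PriorSpec("reflected_gamma", (a, b))
    return table


# -- piecewise model -----------------------------------------------------

def simulate_piecewise(prior_mean: float, prior_sd: float, n: int, m: int,
                       rng=None) -> ReferenceTable:
    """Observations follow Normal(0, exp(theta)) for theta < 0 and
    Normal(theta, 1) for theta >= 0; the density is continuous at 0."""
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    rng = _as_rng(rng)
    theta = prior_mean + prior_sd * rng.standard_normal(m)
    eps = rng.standard_normal((m, n))
    scale = np.where(theta < 0, np.exp(theta / 2.0), 1.0)
    loc = np.where(theta < 0, 0.0, theta)
    y = loc[:, None] + scale[:, None] * eps
    return ReferenceTable(
        params=theta[:, None], payloads=y[:, :, None], payload_kind="matrix",
        model="piecewise",
        prior=PriorSpec("normal", (prior_mean, prior_sd)), meta={"n": n},
    )


# -- benchmark tanh-mixture model ---------------------------------------

def simulate_benchmark(n: int, m: int, rng=None) -> ReferenceTable:
    """theta ~ Normal(0, 1); column 1 is the symmetric two-component normal
    mixture with means ±tanh(theta) and variance 1 - tanh(theta)^2 (unit
    variance marginally for every theta); column 2 is standard-normal noise."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    rng = _as_rng(rng)
    theta = rng.standard_normal(m)
    tau = np.tanh(theta)
    u = rng.choice([-1.0, 1.0], size=(m, n))
    z1 = u * tau[:, None] + np.sqrt(1.0 - tau ** 2)[:, None] * rng.standard_normal((m, n))
    z2 = rng.standard_normal((m, n))
    z = np.stack([z1, z2], axis=2)
    return ReferenceTable(
        params=theta[:, None], payloads=z, payload_kind="matrix",
        model="benchmark", prior=PriorSpec("normal", (0.0, 1.0)), meta={"n": n},
    )


def benchmark_candidate_summaries(z: np.ndarray) -> np.ndarray:
    """First three even raw moments of each column: (m2, m4, m6) of column 1
    followed by column 2.  Accepts a single (n, 2) matrix or an (m, n, 2)
    batch; odd moments are uninformative because the likelihood is symmetric."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 2
    if single:
        z = z[None]
    if z.shape[-1] != 2:
        raise ValueError("expected a two-column data matrix")
    moments = [np.mean(z[:, :, j] ** k, axis=1) for j in (0, 1) for k in (2, 4, 6)]
    out = np.stack(moments, axis=1)
    return out[0] if single else out


# -- growing trees -------------------------------------------------------

def simulate_trees(theta, n: int, rng=None) -> np.ndarray:
    """Grow trees by preferential attachment with kernel ``degree ** theta``.

    All trees share the node count ``n`` so growth is vectorized across the
    batch.  The process starts from a single isolated node; the second node
    attaches deterministically, and thereafter node ``j`` attaches to node
    ``i < j`` with probability proportional to ``k_i ** theta`` where ``k_i``
    is the current degree.  Returns an ``(m, n-1, 2)`` edge-list array with
    rows ``(target, new_node)``.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    m = theta.size
    if n < 2:
        raise ValueError("trees need at least two nodes")
    rng = _as_rng(rng)
    edges = np.zeros((m, n - 1, 2), dtype=np.int64)
    edges[:, 0, 1] = 1  # node 1 attaches to node 0 deterministically
    degrees = np.zeros((m, n), dtype=np.int64)
    degrees[:, :2] = 1
    # incremental kernel weights: only two entries change per step
    weights = np.zeros((m, n))
    weights[:, :2] = 1.0
    rows = np.arange(m)
    for j in range(2, n):
        c = np.cumsum(weights[:, :j], axis=1)
        u = rng.random(m) * c[:, -1]
        target = np.minimum((c <= u[:, None]).sum(axis=1), j - 1)
        edges[:, j - 1, 0] = target
        edges[:, j - 1, 1] = j
        degrees[rows, target] += 1
        degrees[:, j] = 1
        weights[rows, target] = degrees[rows, target] ** theta
        weights[:, j] = 1.0
    return edges


def simulate_tree(theta: float, n: int, rng=None) -> Tree:
    """Single growing tree; see :func:`simulate_trees`."""
    edges = simulate_trees([theta], n, rng)[0]
    return Tree(n, edges)


def simulate_tree_table(prior_lo: float, prior_hi: float, n: int, m: int,
                        rng=None) -> ReferenceTable:
    """Reference table of growing trees with theta ~ Uniform(lo, hi)."""
    rng = _as_rng(rng)
    theta = rng.uniform(prior_lo, prior_hi, size=m)
    edges = simulate_trees(theta, n, rng)
    return ReferenceTable(
        params=theta[:, None], payloads=edges, payload_kind="tree",
        model="growing_tree", prior=PriorSpec("uniform", (prior_lo, prior_hi)),
        node_count=n, meta={"n": n},
    )


def tree_degrees(edges: np.ndarray, n: int) -> np.ndarray:
    edges = np.asarray(edges)
    return np.bincount(edges.ravel(), minlength=n)


def _tree_adjacency_lists(edges: np.ndarray, n: int) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _bfs_farthest(adj, start):
    """(farthest node, eccentricity, parent array) by breadth-first search."""
    n = len(adj)
    dist = np.full(n, -1, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    dist[start] = 0
    frontier = [start]
    far, fdist = start, 0
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    parent[w] = v
                    nxt.append(w)
                    if dist[w] > fdist:
                        far, fdist = w, dist[w]
        frontier = nxt
    return far, fdist, parent


def tree_diameter(tree: Tree) -> int:
    """Longest shortest path (in edges) via the double-BFS identity for trees."""
    adj = _tree_adjacency_lists(tree.edges, tree.node_count)
    a, _, _ = _bfs_farthest(adj, 0)
    _, diam, _ = _bfs_farthest(adj, a)
    return int(diam)


def tree_max_betweenness(tree: Tree) -> float:
    """Maximum unnormalized betweenness centrality.

    Paths in a tree are unique, so the betweenness of node v equals the
    number of node pairs split across different components of T - v:
    ``[(n-1)^2 - sum_b s_b^2] / 2`` with s_b the component sizes.  Subtree
    sizes are accumulated along a BFS order from the root.
    """
    n = tree.node_count
    if n <= 2:
        return 0.0
    adj = _tree_adjacency_lists(tree.edges, n)
    # BFS order and parents from node 0
    order = []
    parent = np.full(n, -1, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    frontier = [0]
    while frontier:
        nxt = []
        for v in frontier:
            order.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    parent[w] = v
                    nxt.append(w)
        frontier = nxt
    size = np.ones(n, dtype=np.int64)
    for v in reversed(order):
        if parent[v] >= 0:
            size[parent[v]] += size[v]
    best = 0.0
    for v in range(n):
        comps = [size[w] for w in adj[v] if parent[w] == v]
        if parent[v] >= 0:
            comps.append(n - size[v])
        total = n - 1
        bet = (total * total - sum(s * s for s in comps)) / 2.0
        best = max(best, bet)
    return float(best)


def tree_candidate_summaries(tree: Tree) -> np.ndarray:
    """(degree std, degree Gini, diameter, max betweenness).

    Degree std uses population normalization; the Gini coefficient is the
    mean absolute pairwise degree difference over twice the mean degree.
    A uniform distractor, when used, is appended by the caller.
    """
    k = tree.degrees().astype(float)
    n = k.size
    std = float(k.std(ddof=0))
    mean = k.mean()
    ks = np.sort(k)
    # Gini = sum_{i,j} |k_i - k_j| / (2 n^2 kbar), via the sorted-rank identity
    i = np.arange(1, n + 1)
    gini = float(np.sum((2 * i - n - 1) * ks) / (n * n * mean))
    return np.array([std, gini, float(tree_diameter(tree)), tree_max_betweenness(tree)])


def tree_candidate_summary_table(table: ReferenceTable, rng=None,
                                 distractor: bool = True) -> np.ndarray:
    """Candidate summaries for every tree in a table, with an optional
    Uniform(0, 1) distractor column resampled per element."""
    rng = _as_rng(rng)
    rows = np.stack([
        tree_candidate_summaries(table.tree(i)) for i in range(table.m)
    ])
    if distractor:
        rows = np.column_stack([rows, rng.random(table.m)])
    return rows
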