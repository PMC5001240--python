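"""Tree-structured Gaussian simulator for directed regulatory networks.

Ground truth is a rooted tree in which every non-root gene is regulated by
exactly one parent.  Expression is generated top-down: the root is standard
normal and each child is

    X_child = rho * X_parent + sqrt(1 - rho^2) * eps,   eps ~ N(0, 1)

so every marginal is standard normal and the parent-child correlation equals
the specified covariance rho.  The population correlation between any two
nodes is rho^L with L the tree-path length, which serves as an analytic
oracle for the samplers.  Measurement noise is mixed in as a convex
combination with uniform noise of amount omega (default 3, support
(-omega/2, omega/2)); the noise arms used throughout are fractions
0, 1/3 and 2/3.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeModel",
    "SimulationConfig",
    "canonical_tree",
    "random_tree",
    "population_correlation",
    "simulate_expression",
    "mix_noise",
]

#: Canonical 10-node topology.  X1 is the root and an ancestor of every node;
#: the constrained edges are X1->X2, X1->X4, X2->X6, X4->X10, with X5 and X7
#: descendants of X2 and {X3, X8, X9} attached to the root.
_TEN_NODE_PARENTS: dict[str, str | None] = {
    "X1": None,
    "X2": "X1",
    "X3": "X1",
    "X4": "X1",
    "X8": "X1",
    "X9": "X1",
    "X6": "X2",
    "X10": "X4",
    "X5": "X6",
    "X7": "X6",
}


@dataclass(frozen=True)
class TreeModel:
    """Rooted regulatory tree plus generative parameters.

    Parameters
    ----------
    parent
        Map node -> parent; exactly one node (the root) maps to ``None``.
    covariance
        Parent-child correlation rho, one global value in (0, 1).
    noise_omega
        Amount of uniform noise omega; support is (-omega/2, omega/2).
    noise_fraction
        Mixing fraction f in [0, 1): observed = (1-f)*signal + f*noise.
    """

    parent: Mapping[str, str | None]
    covariance: float
    noise_omega: float = 3.0
    noise_fraction: float = 0.0

    def __post_init__(self):
        roots = [v for v, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        if not 0.0 < self.covariance < 1.0:
            raise ValueError("covariance must lie in (0, 1)")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise fraction must lie in [0, 1)")
        for v, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of {v!r} is not a node")
        # reject cycles / disconnection: every node must reach the root
        root = roots[0]
        for v in self.parent:
            seen = set()
            while v is not None:
                if v in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(v)
                v = self.parent[v]
            if root not in seen:
                raise ValueError("parent map is disconnected")

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> str:
        return next(v for v, p in self.parent.items() if p is None)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Directed (parent, child) edges."""
        return [(p, v) for v, p in self.parent.items() if p is not None]

    def depth(self, node: str) -> int:
        d = 0
        while (node := self.parent[node]) is not None:
            d += 1
        return d

    def topological_order(self) -> list[str]:
        return sorted(self.nodes, key=self.depth)

    def path_lengths(self) -> pd.DataFrame:
        """All-pairs tree path lengths (undirected), as a labelled frame."""
        adj: dict[str, list[str]] = {v: [] for v in self.parent}
        for p, c in self.edges:
            adj[p].append(c)
            adj[c].append(p)
        nodes = self.nodes
        L = pd.DataFrame(0, index=nodes, columns=nodes, dtype=int)
        for start in nodes:
            dist = {start: 0}
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        queue.append(w)
            L.loc[start] = [dist[v] for v in nodes]
        return L


def canonical_tree(
    n_nodes: int,
    covariance: float = 0.8,
    noise_omega: float = 3.0,
    noise_fraction: float = 0.0,
) -> TreeModel:
    """Canonical simulation topology with ``n_nodes`` genes rooted at X1.

    n = 10 returns the fixed benchmark tree (see module notes); other sizes
    return a deterministic shallow, bushy tree with the same depth profile:
    level sizes ceil((n-1)/2), ceil(rest/2) and the remainder, children
    assigned round-robin.  Shallow bushiness matters: it keeps every edge's
    orientation identifiable from the population correlations, because each
    parent retains more non-descendant correlation mass than its child holds
    in descendants.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_nodes == 10:
        parent = dict(_TEN_NODE_PARENTS)
    else:
        rem = n_nodes - 1
        l1 = (rem + 1) // 2
        rem2 = rem - l1
        l2 = (rem2 + 1) // 2
        l3 = rem2 - l2
        names = [f"X{i}" for i in range(1, n_nodes + 1)]
        level1 = names[1 : 1 + l1]
        level2 = names[1 + l1 : 1 + l1 + l2]
        level3 = names[1 + l1 + l2 :]
        parent = {"X1": None}
        for v in level1:
            parent[v] = "X1"
        for t, v in enumerate(level2):
            parent[v] = level1[t % len(level1)]
        for t, v in enumerate(level3):
            parent[v] = level2[t % len(level2)]
    return TreeModel(
        parent=parent,
        covariance=covariance,
        noise_omega=noise_omega,
        noise_fraction=noise_fraction,
    )


def random_tree(
    n_nodes: int,
    seed: int | np.random.Generator,
    covariance: float = 0.8,
    noise_omega: float = 3.0,
    noise_fraction: float = 0.0,
) -> TreeModel:
    """Seeded random recursive tree rooted at X1 (uniform attachment)."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    parent: dict[str, str | None] = {"X1": None}
    names = [f"X{i}" for i in range(1, n_nodes + 1)]
    for i in range(1, n_nodes):
        parent[names[i]] = names[int(rng.integers(0, i))]
    return TreeModel(
        parent=parent,
        covariance=covariance,
        noise_omega=noise_omega,
        noise_fraction=noise_fraction,
    )


def population_correlation(tree: TreeModel) -> pd.DataFrame:
    """Noise-free population correlation matrix, Corr(u, v) = rho^path(u, v)."""
    L = tree.path_lengths()
    return pd.DataFrame(
        tree.covariance ** L.values.astype(float), index=L.index, columns=L.columns
    )


def simulate_expression(
    tree: TreeModel, m_samples: int, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, TreeModel]:
    """Draw an m x n expression matrix from the tree model.

    Children are generated top-down as rho * parent + sqrt(1-rho^2) * noise;
    if the tree carries a positive noise fraction, uniform noise is mixed in
    afterwards (same random stream).  Returns the matrix together with the
    ground-truth model.
    """
    if m_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    rho = tree.covariance
    values: dict[str, np.ndarray] = {}
    for node in tree.topological_order():
        p = tree.parent[node]
        eps = rng.standard_normal(m_samples)
        if p is None:
            values[node] = eps
        else:
            values[node] = rho * values[p] + np.sqrt(1.0 - rho**2) * eps
    expr = pd.DataFrame(
        {g: values[g] for g in tree.nodes},
        index=[f"S{i + 1}" for i in range(m_samples)],
    )
    if tree.noise_fraction > 0.0:
        expr = mix_noise(
            expr, fraction=tree.noise_fraction, omega=tree.noise_omega, seed=rng
        )
    return expr, tree


def mix_noise(
    expr: pd.DataFrame,
    fraction: float | None = None,
    omega: float = 3.0,
    kappa: float | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mix zero-mean uniform noise into an expression matrix.

    Fraction mode (default): X' = (1-f) * X + f * U with
    U ~ Uniform(-omega/2, omega/2); f = 0 returns the input unchanged.
    Ratio mode (``kappa`` given): X' = X + (omega/kappa) * U, the additive
    reading of noise "weighted by omega/kappa".
    """
    rng = np.random.default_rng(seed)
    if kappa is not None:
        if kappa <= 0:
            raise ValueError("kappa must be > 0 in ratio mode")
        noise = rng.uniform(-omega / 2.0, omega / 2.0, size=expr.shape)
        out = expr.values + (omega / kappa) * noise
    else:
        if fraction is None:
            raise ValueError("give either fraction or kappa")
        if not 0.0 <= fraction < 1.0:
            raise ValueError("fraction must lie in [0, 1)")
        if fraction == 0.0:
            return expr.copy()
        noise = rng.uniform(-omega / 2.0, omega / 2.0, size=expr.shape)
        out = (1.0 - fraction) * expr.values + fraction * noise
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


@dataclass
class SimulationConfig:
    """The full simulation-study grid (4 sizes x 3 noise arms x 6 covariances)."""

    node_sizes: Sequence[int] = (10, 20, 50, 100)
    covariances: Sequence[float] = (0.1, 0.2, 0.4, 0.6, 0.8, 0.9)
    noise_fractions: Sequence[float] = (0.0, 1.0 / 3.0, 2.0 / 3.0)
    m_samples: int = 1000
    replicates: int = 1
    seed: int = 0
    noise_omega: float = 3.0

    def __post_init__(self):
        if any(not 0.0 < c < 1.0 for c in self.covariances):
            raise ValueError("covariances must lie in (0, 1)")
        if self.m_samples < 3:
            raise ValueError("m_samples must be >= 3")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cells(self) -> list[tuple[int, float, float]]:
        """All (n_nodes, covariance, noise_fraction) grid cells."""
        return [
            (n, rho, f)
            for n, f, rho in product(
                self.node_sizes, self.noise_fractions, self.covariances
            )
        ]
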