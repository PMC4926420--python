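"""Mutual-information network among deregulated gene sets.

Pairwise dependence between gene-set GSR profiles is estimated with the Kraskov
k-nearest-neighbor mutual-information estimator (variant 1, Chebyshev metric; k = 3 by
default, estimates in nats, negatives clamped to zero).  Exact ties are resolved by an
index-scaled deterministic jitter, since nearest-neighbor estimators are undefined under
ties.  The estimated MI matrix is pruned with the ARACNE data-processing inequality in
its multiplicative form: edge (i, j) is removed when some third node z satisfies
``mi(i, j) < tau * min(mi(i, z), mi(j, z))``, all removals being judged against the
original matrix rather than sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from . import io as gio

__all__ = [
    "MIMatrix",
    "NetworkConfig",
    "EdgeList",
    "knn_mi",
    "mi_matrix",
    "aracne_prune",
    "largest_component",
]


@dataclass(frozen=True)
class NetworkConfig:
    """k: neighbor count of the MI estimator; tau: multiplicative DPI tolerance."""

    k: int = 3
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")


@dataclass(eq=False)
class MIMatrix:
    """Symmetric non-negative MI estimates (nats) with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(eq=False)
class EdgeList:
    """Weighted undirected edges with endpoints ordered a < b lexicographically."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        normalized = []
        seen = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self edge on {a!r}")
            if w < 0:
                raise ValueError("edge weights must be >= 0")
            a, b = (a, b) if a < b else (b, a)
            if (a, b) in seen:
                raise ValueError(f"duplicate edge {(a, b)}")
            seen.add((a, b))
            normalized.append((a, b, float(w)))
        self.edges = sorted(normalized)

    @property
    def nodes(self) -> list[str]:
        return sorted({n for a, b, _ in self.edges for n in (a, b)})

    def __len__(self) -> int:
        return len(self.edges)

    def to_gml(self, path, isolated_nodes: list[str] | None = None) -> None:
        nodes = sorted(set(self.nodes) | set(isolated_nodes or []))
        gio.write_gml(nodes, self.edges, path)


def _break_ties(a: np.ndarray) -> np.ndarray:
    """Index-scaled epsilon jitter so every marginal value is distinct."""
    a = np.asarray(a, dtype=float)
    if len(np.unique(a)) == a.size:
        return a
    scale = np.ptp(a) or 1.0
    return a + np.arange(a.size) * scale * 1e-10


def _marginal_counts(a: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Number of points j != i with |a_j - a_i| strictly below eps_i."""
    order = np.argsort(a)
    s = a[order]
    hi = np.searchsorted(s, a + eps, side="left")
    lo = np.searchsorted(s, a - eps, side="right")
    return hi - lo - 1  # excludes the point itself


def knn_mi(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """Kraskov variant-1 MI estimate in nats, clamped at zero.

    Symmetric in its arguments and invariant (up to estimator noise) under strictly
    increasing marginal transforms.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2 * k + 2:
        raise ValueError(f"need >= {2 * k + 2} observations for k={k}, got {n}")
    x = _break_ties(x)
    y = _break_ties(y)
    z = np.column_stack([x, y])
    tree = cKDTree(z)
    dist, _ = tree.query(z, k=k + 1, p=np.inf)
    eps = dist[:, k]
    nx_ = _marginal_counts(x, eps)
    ny_ = _marginal_counts(y, eps)
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    return float(max(mi, 0.0))


def mi_matrix(profiles: pd.DataFrame, k: int = 3) -> MIMatrix:
    """All-pairs kNN MI among the rows of ``profiles`` (sets x samples)."""
    labels = list(profiles.index)
    X = profiles.to_numpy(dtype=float)
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = knn_mi(X[i], X[j], k=k)
    return MIMatrix(labels=labels, values=M, k=k)


def aracne_prune(mi: MIMatrix, config: NetworkConfig = NetworkConfig()) -> EdgeList:
    """Multiplicative-model DPI pruning of the MI matrix; zero-weight edges dropped."""
    M = np.asarray(mi.values, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("MI matrix must be symmetric")
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    n = M.shape[0]
    kept = []
    for i in range(n):
        for j in range(i + 1, n):
            w = M[i, j]
            if w <= 0:
                continue
            third = np.minimum(M[i], M[j])
            third[[i, j]] = -np.inf
            if w < config.tau * third.max():
                continue  # an indirect path explains this edge
            kept.append((mi.labels[i], mi.labels[j], w))
    return EdgeList(kept)


def largest_component(edges: EdgeList) -> EdgeList:
    """Edges of the largest connected component; ties go to the component containing the
    lexicographically smallest node label."""
    if not edges.edges:
        return EdgeList([])
    graph = nx.Graph()
    for a, b, w in edges.edges:
        graph.add_edge(a, b, weight=w)
    components = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    keep = components[0]
    sub = [(a, b, w) for a, b, w in edges.edges if a in keep]
    return EdgeList(sub)
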