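"""Binary-graph topology metrics, implemented from first principles.

All measures operate on undirected binary networks: node degree, clustering
coefficient, geodesic distances (vectorized breadth-first search), per-node
and characteristic path length, Brandes betweenness centrality, and global /
nodal / local efficiency.

Disconnected pairs get infinite distance; efficiency terms use 1/inf = 0 and
path lengths average over reachable pairs only, reporting how many pairs were
unreachable.  Nodes with degree < 2 have clustering and local efficiency 0
(not NaN) so network means stay defined on sparse graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import BinaryNetwork

__all__ = [
    "degree",
    "clustering",
    "shortest_paths",
    "char_path_length",
    "betweenness",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "global_metrics",
    "NodalMetrics",
    "GlobalMetrics",
    "PathLengthResult",
    "EfficiencyResult",
]


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.values
    return np.asarray(net, dtype=np.uint8)


def degree(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """k_i = row sum of the adjacency matrix."""
    return _adj(net).sum(axis=1).astype(np.int64)


def clustering(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """C_i = (edges among neighbours of i) / (k_i (k_i - 1) / 2); 0 if k_i < 2."""
    a = _adj(net).astype(np.int64)
    k = a.sum(axis=1)
    # twice the triangle count at i is the i-th diagonal entry of A^3
    tri2 = np.einsum("ij,ij->i", a @ a, a)  # = diag(A^3)
    c = np.zeros(a.shape[0], dtype=float)
    mask = k >= 2
    c[mask] = tri2[mask] / (k[mask] * (k[mask] - 1))
    return c


def shortest_paths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs unweighted geodesic distances by simultaneous BFS.

    Returns an (n, n) float matrix; unreachable pairs are ``inf`` and the
    diagonal is 0.
    """
    a = _adj(net).astype(bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = reached.copy()
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier @ a) & ~reached
        if not nxt.any():
            break
        dist[nxt] = d
        reached |= nxt
        frontier = nxt
    return dist


@dataclass
class PathLengthResult:
    """Per-node and network mean geodesic distances over reachable pairs."""

    per_node: np.ndarray          # l_i; NaN for fully isolated nodes
    network: float                # mean over reachable ordered pairs; NaN if none
    n_unreachable_pairs: int      # unordered pairs with infinite distance
    has_isolated: bool            # True if some node reaches no other node


def char_path_length(net: BinaryNetwork | np.ndarray,
                     dist: np.ndarray | None = None) -> PathLengthResult:
    """l_i = mean_j min{l_ij} over reachable j != i, and the network mean."""
    if dist is None:
        dist = shortest_paths(net)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    counts = finite.sum(axis=1)
    per_node = np.full(n, np.nan)
    ok = counts > 0
    sums = np.where(finite, dist, 0.0).sum(axis=1)
    per_node[ok] = sums[ok] / counts[ok]
    total_pairs = finite.sum()
    network = float(np.where(finite, dist, 0.0).sum() / total_pairs) if total_pairs else float("nan")
    n_unreach = int(((~np.isfinite(dist)) & off).sum() // 2)
    return PathLengthResult(per_node=per_node, network=network,
                            n_unreachable_pairs=n_unreach,
                            has_isolated=bool((~ok).any()))


def betweenness(net: BinaryNetwork | np.ndarray, normalized: bool = False) -> np.ndarray:
    """Geodesic betweenness B_i = sum over unordered pairs (j, m), j, m != i, of
    phi_jm(i) / phi_jm, via Brandes single-source accumulation.

    Raw fractional counts by default; ``normalized=True`` divides by
    (n-1)(n-2)/2 for cross-size comparison.
    """
    a = _adj(net)
    n = a.shape[0]
    nbrs = [np.flatnonzero(a[i]) for i in range(n)]
    b = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=np.int64)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            order.append(v)
            dv = dist[v]
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                b[w] += delta[w]
    b /= 2.0  # each unordered pair counted from both endpoints
    if normalized and n > 2:
        b /= (n - 1) * (n - 2) / 2.0
    return b


@dataclass
class EfficiencyResult:
    network: float
    per_node: np.ndarray


def global_efficiency(net: BinaryNetwork | np.ndarray,
                      dist: np.ndarray | None = None) -> EfficiencyResult:
    """E_glob = mean of 1/l_ij over ordered pairs i != j, with 1/inf = 0.

    The per-node value (mean of 1/l_ij over j != i) is the nodal efficiency
    used for nodal rankings.
    """
    if dist is None:
        dist = shortest_paths(net)
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    if n < 2:
        return EfficiencyResult(network=0.0, per_node=np.zeros(n))
    per_node = inv.sum(axis=1) / (n - 1)
    return EfficiencyResult(network=float(inv.sum() / (n * (n - 1))), per_node=per_node)


def local_efficiency(net: BinaryNetwork | np.ndarray) -> EfficiencyResult:
    """Per-node: global efficiency of the subgraph induced by i's neighbours
    (i excluded); 0 when k_i < 2.  Network value: mean over all nodes."""
    a = _adj(net)
    n = a.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        per_node[i] = global_efficiency(sub).network
    return EfficiencyResult(network=float(per_node.mean()) if n else 0.0,
                            per_node=per_node)


@dataclass
class NodalMetrics:
    """Per-node metric vectors for one binary network."""

    degree: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    betweenness: np.ndarray
    nodal_efficiency: np.ndarray
    local_efficiency: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree.astype(float),
            "clustering": self.clustering,
            "path_length": self.path_length,
            "betweenness": self.betweenness,
            "nodal_efficiency": self.nodal_efficiency,
            "local_efficiency": self.local_efficiency,
        }


@dataclass
class GlobalMetrics:
    """Network-level summary metrics."""

    mean_degree: float
    mean_clustering: float
    char_path_length: float
    global_efficiency: float
    mean_local_efficiency: float
    n_nodes: int
    n_edges: int
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_degree": self.mean_degree,
            "mean_clustering": self.mean_clustering,
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "mean_local_efficiency": self.mean_local_efficiency,
            "n_nodes": float(self.n_nodes),
            "n_edges": float(self.n_edges),
            "n_unreachable_pairs": float(self.n_unreachable_pairs),
        }


def nodal_metrics(net: BinaryNetwork | np.ndarray) -> NodalMetrics:
    dist = shortest_paths(net)
    pl = char_path_length(net, dist=dist)
    ge = global_efficiency(net, dist=dist)
    le = local_efficiency(net)
    return NodalMetrics(
        degree=degree(net),
        clustering=clustering(net),
        path_length=pl.per_node,
        betweenness=betweenness(net),
        nodal_efficiency=ge.per_node,
        local_efficiency=le.per_node,
    )


def global_metrics(net: BinaryNetwork | np.ndarray) -> GlobalMetrics:
    a = _adj(net)
    dist = shortest_paths(a)
    pl = char_path_length(a, dist=dist)
    ge = global_efficiency(a, dist=dist)
    le = local_efficiency(a)
    k = degree(a)
    return GlobalMetrics(
        mean_degree=float(k.mean()) if k.size else 0.0,
        mean_clustering=float(clustering(a).mean()) if k.size else 0.0,
        char_path_length=pl.network,
        global_efficiency=ge.network,
        mean_local_efficiency=le.network,
        n_nodes=int(a.shape[0]),
        n_edges=int(a.sum()) // 2,
        n_unreachable_pairs=pl.n_unreachable_pairs,
    )
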