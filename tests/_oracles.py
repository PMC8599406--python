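"""Independent brute-force oracles used to check the package's computations.

These deliberately avoid the implementation paths they verify: centralities
come from explicit all-pairs BFS with shortest-path counting and a dense
eigendecomposition; regression references use normal equations.
"""

from collections import deque

import networkx as nx
import numpy as np


def bfs_distances_and_counts(g: nx.Graph, source):
    """Distances and number of distinct shortest paths from ``source``."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def closeness_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        dist, _ = bfs_distances_and_counts(g, v)
        total = sum(dist.values())
        r = len(dist)
        out[v] = (r - 1) / total if total > 0 else 0.0
    return out


def betweenness_oracle(g: nx.Graph) -> dict:
    """Unordered-pair betweenness with endpoints excluded, path multiplicity."""
    nodes = list(g.nodes)
    out = {v: 0.0 for v in nodes}
    info = {s: bfs_distances_and_counts(g, s) for s in nodes}
    for i, s in enumerate(nodes):
        dist_s, sig_s = info[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            sig_st = sig_s[t]
            dist_t, sig_t = info[t]
            for v in nodes:
                if v is s or v is t or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    out[v] += sig_s[v] * sig_t[v] / sig_st
    return out


def eigenvector_oracle(g: nx.Graph) -> dict:
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = vec / vec.max()
    return {n: float(x) for n, x in zip(nodes, vec)}


def degree_oracle(g: nx.Graph) -> dict:
    return {v: float(sum(1 for _ in g.neighbors(v))) for v in g.nodes}


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 7) -> nx.Graph:
    """Random connected graph: a random spanning tree plus random extra edges."""
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[int(rng.integers(i))]
        g.add_edge(int(order[i]), int(j))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    return g


def ols_predictions(X_train, y_train, X_new) -> np.ndarray:
    """Ordinary least squares via the pseudo-inverse of the centred design."""
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    xm = X_train.mean(axis=0)
    beta = np.linalg.pinv(X_train - xm) @ (y_train - y_train.mean())
    return y_train.mean() + (np.asarray(X_new, float) - xm) @ beta


def pcor_one_covariate(x, y, z) -> float:
    """Recursive partial-correlation formula on ranks (single covariate)."""
    from scipy.stats import rankdata

    xr, yr, zr = rankdata(x), rankdata(y), rankdata(z)

    def r(a, b):
        return np.corrcoef(a, b)[0, 1]

    rxy, rxz, ryz = r(xr, yr), r(xr, zr), r(yr, zr)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
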