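"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions, avoiding the code paths it
checks: truncated power series instead of `expm`, exhaustive enumeration
instead of vectorised argmin/argmax, Floyd-Warshall instead of Dijkstra,
boolean matrix powers instead of csgraph reachability, and explicit set
partitions instead of greedy community search.
"""

from __future__ import annotations

import math


import numpy as np
import networkx as nx

from wavewire import RewiringConfig, init_random_digraph
from wavewire.graph_core import SpatialDigraph


def make_graph(n: int, m: int, seed: int = 0, **kw) -> SpatialDigraph:
    return init_random_digraph(RewiringConfig(n=n, m=m, seed=seed, **kw))


def to_networkx(G: SpatialDigraph) -> nx.DiGraph:
    H = nx.DiGraph()
    H.add_nodes_from(range(G.n))
    for s, t, w in G.edges():
        H.add_edge(s, t, weight=w)
    return H


def series_expm(M: np.ndarray, terms: int = 50) -> np.ndarray:
    """Truncated power series sum_{k<=terms} M^k / k!."""
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, terms + 1):
        term = term @ M / k
        out = out + term
    return out


def adaptive_choice_oracle(G, v, direction, kernel):
    """Exhaustively score every legal (remove, add) pair, lowest index on ties."""
    if direction == "in":
        nbrs = [u for u in range(G.n) if G.weights[v, u] > 0]
        cands = [u for u in range(G.n) if u != v and G.weights[v, u] == 0]
        k = min(nbrs, key=lambda u: (kernel[v, u], u))
        l = max(cands, key=lambda u: (kernel[v, u], -u))
        return (k, v), (l, v)
    nbrs = [u for u in range(G.n) if G.weights[u, v] > 0]
    cands = [u for u in range(G.n) if u != v and G.weights[u, v] == 0]
    k = min(nbrs, key=lambda u: (kernel[u, v], u))
    l = max(cands, key=lambda u: (kernel[u, v], -u))
    return (v, k), (v, l)


def proximity_choice_oracle(G, v, direction):
    d = G.distances()
    if direction == "in":
        nbrs = [u for u in range(G.n) if G.weights[v, u] > 0]
        cands = [u for u in range(G.n) if u != v and G.weights[v, u] == 0]
        k = max(nbrs, key=lambda u: (d[u, v], -u))
        l = min(cands, key=lambda u: (d[u, v], u))
        return (k, v), (l, v)
    nbrs = [u for u in range(G.n) if G.weights[u, v] > 0]
    cands = [u for u in range(G.n) if u != v and G.weights[u, v] == 0]
    k = max(nbrs, key=lambda u: (d[v, u], -u))
    l = min(cands, key=lambda u: (d[v, u], u))
    return (v, k), (v, l)


def floyd_warshall_efficiency(G) -> float:
    """Average efficiency from an explicit Floyd-Warshall on lengths 1/w."""
    n = G.n
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for s, t, w in G.edges():
        d[s, t] = 1.0 / w
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i, j]) and d[i, j] > 0
    )
    return total / (n * (n - 1))


def closure_reachability(G) -> np.ndarray:
    """Boolean transitive closure (with reflexive self-pairs) by matrix powers."""
    adj = np.zeros((G.n, G.n), dtype=bool)
    for s, t, _ in G.edges():
        adj[s, t] = True
    reach = adj | np.eye(G.n, dtype=bool)
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            return reach
        reach = nxt


def hub_oracle(G, threshold):
    din = G.in_degrees()
    dout = G.out_degrees()
    conv = [v for v in range(G.n) if din[v] > threshold and dout[v] >= 1]
    div = [v for v in range(G.n) if dout[v] > threshold and din[v] >= 1]
    return conv, div


def cdu_oracle(G, threshold):
    """CDUs from networkx reachability plus simple-path interiors.

    Returns {(C, D): (reachability-intermediates, simple-path-union)}.
    """
    H = to_networkx(G)
    conv, div = hub_oracle(G, threshold)
    units = {}
    for C in conv:
        for D in div:
            if C == D or not nx.has_path(H, C, D):
                continue
            desc = nx.descendants(H, C)
            anc = nx.ancestors(H, D)
            mids = (desc & anc) - {C, D}
            interior = set()
            for path in nx.all_simple_paths(H, C, D):
                interior.update(path[1:-1])
            units[(C, D)] = (mids, interior)
    return units


def modularity_sum_oracle(G, labels, convention="printed") -> float:
    """Literal double sum over node pairs."""
    W = G.weights
    w = W.sum()
    w_in = W.sum(axis=1)
    w_out = W.sum(axis=0)
    if convention == "printed":
        pref = null = 1.0 / (2 * w)
    else:
        pref = null = 1.0 / w
    total = 0.0
    for i in range(G.n):
        for j in range(G.n):
            if labels[i] == labels[j]:
                total += W[i, j] - null * w_in[i] * w_out[j]
    return pref * total


def set_partitions(nodes):
    """All set partitions of a list (Bell-number many)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def best_partition_exhaustive(G, convention="printed"):
    best_q, best_labels = -np.inf, None
    for p in set_partitions(list(range(G.n))):
        labels = np.zeros(G.n, dtype=int)
        for k, blk in enumerate(p):
            labels[blk] = k
        q = modularity_sum_oracle(G, labels, convention)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels
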