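"""Brute-force reference implementations used only by the tests.

Everything here is written for transparency, not speed: exhaustive
simple-path enumeration for shortest paths and betweenness, direct
double/triple loops for the weighted clustering coefficient. Intended
for graphs of at most ~7 nodes.
"""

import numpy as np

TIE_RTOL = 1e-9


def all_simple_paths(adj, s, t):
    """Yield (path, length) over all simple s-t paths; edge length 1/w."""
    n = adj.shape[0]

    def rec(path, length):
        u = path[-1]
        if u == t:
            yield list(path), length
            return
        for v in range(n):
            if adj[u, v] > 0 and v not in path:
                path.append(v)
                yield from rec(path, length + 1.0 / adj[u, v])
                path.pop()

    yield from rec([s], 0.0)


def shortest_paths(adj, s, t):
    """(distance, list of tied-shortest paths) by exhaustive enumeration."""
    best = np.inf
    paths = []
    for path, length in all_simple_paths(adj, s, t):
        tol = TIE_RTOL * max(length, best if np.isfinite(best) else 0.0, 1.0)
        if length < best - tol:
            best = length
            paths = [path]
        elif abs(length - best) <= tol:
            paths.append(path)
    return best, paths


def distance_matrix(adj):
    n = adj.shape[0]
    d = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                d[s, t] = shortest_paths(adj, s, t)[0]
    return d


def clustering(adj, i):
    n = adj.shape[0]
    num = den = 0.0
    for k in range(n):
        if k == i:
            continue
        for l in range(n):
            if l in (i, k):
                continue
            num += adj[i, k] * adj[i, l] * adj[k, l]
            den += adj[i, k] * adj[i, l]
    return num / den if den > 0 else 0.0


def char_path_length(adj):
    d = distance_matrix(adj)
    off = d[~np.eye(adj.shape[0], dtype=bool)]
    finite = off[np.isfinite(off)]
    return finite.mean() if finite.size else np.inf


def global_efficiency(adj):
    d = distance_matrix(adj)
    off = d[~np.eye(adj.shape[0], dtype=bool)]
    return np.mean([1.0 / v if np.isfinite(v) else 0.0 for v in off])


def local_efficiency(adj, i):
    nbrs = np.nonzero(adj[i] > 0)[0]
    if nbrs.size < 2:
        return 0.0
    return global_efficiency(adj[np.ix_(nbrs, nbrs)])


def betweenness(adj, i):
    """Standard: sum over unordered pairs of the through fraction."""
    n = adj.shape[0]
    total = 0.0
    for m in range(n):
        for t in range(m + 1, n):
            if i in (m, t):
                continue
            _, paths = shortest_paths(adj, m, t)
            if not paths:
                continue
            total += sum(i in p[1:-1] for p in paths) / len(paths)
    return total


def random_graph(rng, n, zero_prob=0.2):
    """Random symmetric weighted adjacency with some absent edges."""
    w = rng.uniform(0.2, 1.0, size=(n, n))
    mask = rng.random((n, n)) < zero_prob
    w[mask] = 0.0
    w = np.triu(w, 1)
    return w + w.T
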