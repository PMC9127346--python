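"""Weighted functional-connectivity graphs and their metrics.

The PLV matrix is read as a weighted undirected adjacency c_ij (diagonal
zeroed). Shortest paths use edge length 1/c_ij — the standard convention
for synchrony-weighted brain graphs, where a strong connection is a short
functional distance — with a hop-count option that treats every nonzero
edge as length 1.

Metrics: weighted clustering coefficient (closed over open weighted
triples), characteristic path length (mean pairwise shortest-path
length), global efficiency (mean reciprocal shortest-path length), local
efficiency (global efficiency of each node's neighbor subgraph) and
shortest-path betweenness centrality.

Disconnected-pair policy: such pairs contribute 1/L_ij = 0 to the
efficiencies and are excluded from the characteristic-path-length mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .phase import PLVMatrix

#: relative tolerance under which two path lengths count as tied shortest
TIE_RTOL = 1e-9


@dataclass
class BrainNetwork:
    """Weighted undirected graph over EEG channels."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...]
    length_mode: str = "reciprocal"  # or "hops"
    _lengths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.min() < 0:
            raise ValueError("adjacency entries must be non-negative")
        a = a.copy()
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        self.node_labels = tuple(self.node_labels)
        if len(self.node_labels) != a.shape[0]:
            raise ValueError("label count disagrees with adjacency size")
        if self.length_mode not in ("reciprocal", "hops"):
            raise ValueError("length_mode must be 'reciprocal' or 'hops'")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def node_index(self, node: str) -> int:
        try:
            return self.node_labels.index(node)
        except ValueError:
            raise KeyError(
                f"unknown node {node!r}; have {self.node_labels}"
            ) from None

    def edge_lengths(self) -> np.ndarray:
        """Per-edge lengths (inf where no edge)."""
        with np.errstate(divide="ignore"):
            if self.length_mode == "reciprocal":
                lengths = np.where(self.adjacency > 0,
                                   1.0 / self.adjacency, np.inf)
            else:
                lengths = np.where(self.adjacency > 0, 1.0, np.inf)
        np.fill_diagonal(lengths, np.inf)  # no self loops
        return lengths

    def path_lengths(self) -> np.ndarray:
        """All-pairs shortest-path length matrix L_ij (inf if disconnected,
        0 on the diagonal); cached."""
        if self._lengths is None:
            el = self.edge_lengths()
            finite = np.isfinite(el)
            graph = csr_array(
                (el[finite], np.nonzero(finite)), shape=el.shape
            )
            self._lengths = dijkstra(graph, directed=False)
        return self._lengths


def from_plv(plv: PLVMatrix, length_mode: str = "reciprocal") -> BrainNetwork:
    """Build the weighted brain graph from a PLV matrix (diagonal zeroed)."""
    return BrainNetwork(plv.values, plv.channel_labels, length_mode=length_mode)


def clustering_coefficient(net: BrainNetwork, node: str) -> float:
    """Weighted clustering of one node: closed / open weighted triples,
    0 when the node has no open triples."""
    if net.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    i = net.node_index(node)
    return float(_clustering_all(net)[i])


def _clustering_all(net: BrainNetwork) -> np.ndarray:
    w = net.adjacency
    num = np.diag(w @ w @ w)  # sum_{k!=l} c_ik c_kl c_li (diag of w is 0)
    s = w.sum(axis=1)
    den = s**2 - (w**2).sum(axis=1)
    out = np.zeros(net.n_nodes)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def characteristic_path_length(net: BrainNetwork) -> float:
    """Mean shortest-path length over ordered node pairs; disconnected
    pairs are excluded from the mean (inf if every pair is disconnected)."""
    if net.n_nodes < 2:
        raise ValueError("path length needs at least 2 nodes")
    lengths = net.path_lengths()
    mask = ~np.eye(net.n_nodes, dtype=bool)
    vals = lengths[mask]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("inf")
    return float(finite.mean())


def global_efficiency(net: BrainNetwork) -> float:
    """Mean reciprocal shortest-path length over ordered pairs, counting
    disconnected pairs as 0."""
    if net.n_nodes < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    lengths = net.path_lengths()
    mask = ~np.eye(net.n_nodes, dtype=bool)
    vals = lengths[mask]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals), 1.0 / vals, 0.0)
    return float(inv.mean())


def local_efficiency(net: BrainNetwork, node: str) -> float:
    """Global efficiency of the subgraph induced by the node's neighbors
    (the node itself excluded); 0 with fewer than two neighbors."""
    i = net.node_index(node)
    nbrs = np.nonzero(net.adjacency[i] > 0)[0]
    if nbrs.size < 2:
        return 0.0
    sub = BrainNetwork(
        net.adjacency[np.ix_(nbrs, nbrs)],
        tuple(net.node_labels[j] for j in nbrs),
        length_mode=net.length_mode,
    )
    return global_efficiency(sub)


def _shortest_path_dag(net: BrainNetwork, source: int):
    """Single-source shortest paths with tied-path counting.

    Returns (dist, sigma, preds): distances, number of shortest paths
    (ties within TIE_RTOL relative tolerance all count), and predecessor
    lists on shortest paths.
    """
    el = net.edge_lengths()
    n = net.n_nodes
    finite = np.isfinite(el)
    graph = csr_array((el[finite], np.nonzero(finite)), shape=el.shape)
    dist = dijkstra(graph, directed=False, indices=source)
    order = np.argsort(dist, kind="stable")
    sigma = np.zeros(n)
    sigma[source] = 1.0
    preds: list[list[int]] = [[] for _ in range(n)]
    for v in order:
        if v == source or not np.isfinite(dist[v]):
            continue
        for u in np.nonzero(finite[v])[0]:
            if not np.isfinite(dist[u]):
                continue
            target = dist[u] + el[u, v]
            tol = TIE_RTOL * max(abs(target), abs(dist[v]), 1.0)
            if abs(target - dist[v]) <= tol:
                sigma[v] += sigma[u]
                preds[v].append(int(u))
    return dist, sigma, preds


def _through_counts(net: BrainNetwork) -> np.ndarray:
    """delta[i] = sum over unordered pairs (m, n), m != i != n, of
    sigma_mn(i) / sigma_mn  (Brandes accumulation halved)."""
    n = net.n_nodes
    delta_total = np.zeros(n)
    for s in range(n):
        dist, sigma, preds = _shortest_path_dag(net, s)
        delta = np.zeros(n)
        order = np.argsort(dist, kind="stable")[::-1]
        for w in order:
            if w == s or not np.isfinite(dist[w]):
                continue
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
        delta[s] = 0.0
        delta_total += delta
    return delta_total / 2.0  # each unordered pair visited from both ends


def betweenness(net: BrainNetwork, node: str,
                normalization: str = "standard") -> float:
    """Shortest-path betweenness centrality of one node.

    standard
        Sum over unordered pairs (m, n), m != i != n, of the fraction of
        shortest m-n paths through i (tied lengths within 1e-9 relative
        tolerance all count as shortest).
    traffic_share
        The node's mean per-pair share of shortest-path traffic: over
        endpoint pairs whose shortest paths traverse at least one
        intermediary, average sigma_mn(i)/sigma_mn divided by the total
        fractional through-count of all intermediaries for that pair. On
        the two-branch relay network this reproduces the worked value
        b2 = (0.5 + 0.5) / (0.5 + 0.5 + 1.0) = 1/2.
    """
    i = net.node_index(node)
    if normalization == "standard":
        return float(_through_counts(net)[i])
    if normalization != "traffic_share":
        raise ValueError("normalization must be 'standard' or 'traffic_share'")
    return float(_traffic_share(net)[i])


def _traffic_share(net: BrainNetwork) -> np.ndarray:
    n = net.n_nodes
    shares = np.zeros(n)
    counts = np.zeros(n)
    for m in range(n):
        dist, sigma, preds = _shortest_path_dag(net, m)
        # per-pair through-fractions from source m via Brandes-style sweeps
        for t in range(m + 1, n):
            if not np.isfinite(dist[t]) or sigma[t] == 0:
                continue
            frac = np.zeros(n)
            stack = [(t, 1.0)]
            while stack:
                w, f = stack.pop()
                for v in preds[w]:
                    g = f * sigma[v] / sigma[w]
                    if v != m:
                        frac[v] += g
                    stack.append((v, g))
            total = frac.sum()
            if total <= 0:
                continue  # direct edge only; no intermediaries
            for i in range(n):
                if i in (m, t):
                    continue
                shares[i] += frac[i] / total
                counts[i] += 1.0
    out = np.zeros(n)
    nz = counts > 0
    out[nz] = shares[nz] / counts[nz]
    return out


@dataclass
class NetworkMetrics:
    """The five graph metrics, per node where applicable."""

    clustering: np.ndarray
    char_path_length: float
    global_efficiency: float
    local_efficiency: np.ndarray
    betweenness: np.ndarray
    node_labels: tuple[str, ...]


def compute_metrics(net: BrainNetwork,
                    betweenness_mode: str = "standard") -> NetworkMetrics:
    """All metrics of a network in one pass."""
    if betweenness_mode == "standard":
        btw = _through_counts(net)
    elif betweenness_mode == "traffic_share":
        btw = _traffic_share(net)
    else:
        raise ValueError("betweenness_mode must be 'standard' or 'traffic_share'")
    return NetworkMetrics(
        clustering=_clustering_all(net),
        char_path_length=characteristic_path_length(net),
        global_efficiency=global_efficiency(net),
        local_efficiency=np.array(
            [local_efficiency(net, lbl) for lbl in net.node_labels]
        ),
        betweenness=btw,
        node_labels=net.node_labels,
    )


def network_feature_vector(net: BrainNetwork,
                           betweenness_mode: str = "standard") -> np.ndarray:
    """Deterministic feature layout [C_1..C_N, L, G, Le_1..Le_N, b_1..b_N]
    (length 3N + 2) for the PE classifier branch."""
    m = compute_metrics(net, betweenness_mode=betweenness_mode)
    L = m.char_path_length if np.isfinite(m.char_path_length) else 0.0
    return np.concatenate([
        m.clustering,
        [L, m.global_efficiency],
        m.local_efficiency,
        m.betweenness,
    ])
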