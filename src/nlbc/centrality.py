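"""Node-limited betweenness centrality (nlBC).

Classical betweenness centrality of a node v sums, over *all* node pairs
(s, t), the fraction of s-t shortest paths on which v lies interior:

    BC(v) = sum_{s != v != t in V} sigma_st(v) / sigma_st

nlBC restricts the endpoint pairs to a user-supplied input gene set U and
weights each pair's contribution by the sum of its endpoint weights:

    nlBC(v) = (1/w) * sum_{ {s,t} subset U, s != t } (w(s) + w(t))
                                                     * sigma_st(v) / sigma_st
    w       = sum_{ {s,t} subset U, s != t } (w(s) + w(t))
            = (|U| - 1) * sum_{x in U} w(x)

with v counted only as an interior node (v not in {s, t}), the same
convention as BC.  Values lie in [0, 1]; nlBC(v) = 1 iff v sits on every
shortest path of every input pair.  Because the normalizer carries the
same weights as the numerator, rescaling all weights by a common factor
leaves every value unchanged; with uniform weights nlBC reduces to the
pair-averaged endpoint-restricted betweenness, and with U = V it is
BC(v) / C(|V|, 2).

The production implementation is a Brandes-style dependency accumulation
restricted to input-pair targets, run for every source s in U and carrying
two dependency vectors per source: the plain restricted dependency
(multiplied by w(s)) and a target-weight-carrying one.  All sources are
advanced simultaneously as dense (nodes x |U|) matrix columns driven by
sparse adjacency products, which keeps the Monte-Carlo significance loop
fast.  A literal path-enumeration oracle (:func:`brute_force_nlbc`) backs
it in the test suite.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "InputGeneSet",
    "ShortestPathDAG",
    "CentralityTable",
    "read_gene_list",
    "bfs_shortest_paths",
    "compute_nlbc",
    "brute_force_nlbc",
    "standard_bc",
]


@dataclass
class InputGeneSet:
    """The user gene list U mapped onto network nodes, with weights.

    ``weights`` maps each mapped node to its strictly positive weight
    w(x); ``dropped`` records input symbols absent from the network
    (kept for the run log, not an error — real gene lists always contain
    unmapped symbols).
    """

    weights: dict[str, float]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.weights) < 2:
            raise ValueError(
                "input gene set must map to at least 2 network nodes "
                f"(got {len(self.weights)})"
            )
        bad = [g for g, w in self.weights.items() if not w > 0]
        if bad:
            raise ValueError(f"non-positive weights for: {sorted(bad)}")

    @classmethod
    def from_weights(
        cls, net: MolecularNetwork, weights: dict[str, float]
    ) -> "InputGeneSet":
        """Map a symbol->weight table onto the network, dropping misses."""
        mapped = {g: float(w) for g, w in weights.items() if g in net}
        dropped = sorted(g for g in weights if g not in net)
        if dropped:
            logger.warning(
                "%d input symbol(s) not in the network, dropped: %s",
                len(dropped),
                ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        return cls(mapped, dropped)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.weights)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ShortestPathDAG:
    """Single-source BFS shortest-path structure.

    ``dist`` holds hop counts, ``sigma`` the number of distinct shortest
    paths from the source, and ``preds`` the shortest-path predecessors
    (neighbours one hop closer to the source).  Nodes unreachable from the
    source are absent from all three mappings.
    """

    source: str
    dist: dict[str, int]
    sigma: dict[str, int]
    preds: dict[str, list[str]]


@dataclass
class CentralityTable:
    """nlBC per node, plus the endpoint-weight normalizer w.

    ``values`` covers every node of the network (zero for nodes interior
    to no input-pair shortest path).  ``pair_convention`` records that
    unordered endpoint pairs define the contract.
    """

    values: dict[str, float]
    normalizer: float
    pair_convention: str = "unordered"

    def nonzero(self) -> dict[str, float]:
        return {v: c for v, c in self.values.items() if c > 0.0}

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return sorted(self.values.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def read_gene_list(path) -> dict[str, float]:
    """Read a two-column gene-list file (gene <tab> optional weight).

    Missing weights default to 1.0.  Duplicate symbols keep the last
    weight seen.
    """
    weights: dict[str, float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            gene = fields[0].strip()
            if not gene:
                continue
            if len(fields) >= 2 and fields[1].strip():
                try:
                    w = float(fields[1])
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: bad weight {fields[1]!r}"
                    ) from exc
            else:
                w = 1.0
            weights[gene] = w
    return weights


def bfs_shortest_paths(net: MolecularNetwork, source: str) -> ShortestPathDAG:
    """Breadth-first shortest-path counts and predecessors from one source.

    The background graph is unweighted, so hop-count BFS is exact.
    """
    if source not in net:
        raise KeyError(f"source node {source!r} is not in the network")
    g = net.graph
    dist: dict[str, int] = {source: 0}
    sigma: dict[str, int] = {source: 1}
    preds: dict[str, list[str]] = {source: []}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for nb in g[u]:
            if nb not in dist:
                dist[nb] = dist[u] + 1
                sigma[nb] = 0
                preds[nb] = []
                queue.append(nb)
            if dist[nb] == dist[u] + 1:
                sigma[nb] += sigma[u]
                preds[nb].append(u)
    return ShortestPathDAG(source, dist, sigma, preds)


# ---------------------------------------------------------------------------
# Batched restricted Brandes accumulation
# ---------------------------------------------------------------------------


def _adjacency(net: MolecularNetwork) -> tuple[sp.csr_array, list[str]]:
    """CSR adjacency and the node ordering it uses (sorted symbols)."""
    order = sorted(net.graph.nodes)
    index = {g: i for i, g in enumerate(order)}
    n = len(order)
    rows, cols = [], []
    for u, v in net.graph.edges:
        iu, iv = index[u], index[v]
        rows.extend((iu, iv))
        cols.extend((iv, iu))
    adj = sp.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    return adj, order


def _restricted_dependencies(
    adj: sp.csr_array, source_idx: np.ndarray, target_weight: np.ndarray
) -> np.ndarray:
    """Weighted restricted Brandes dependencies for a batch of sources.

    For each source s (column j, node index ``source_idx[j]``) computes

        delta_s(v) = sum_{t : target_weight[t, j] > 0, t != s, t != v}
                     target_weight[t, j] * sigma_st(v) / sigma_st

    i.e. the dependency of s on v restricted to the given targets, with
    each target's contribution scaled by its weight.  Sources never
    receive dependency.  All columns advance in lockstep: BFS levels via
    sparse-dense products, then a backward level sweep.

    Parameters
    ----------
    adj : (n, n) CSR adjacency (symmetric 0/1).
    source_idx : (k,) node indices of the batch sources.
    target_weight : (n, k) per-column target weights (0 = not a target).

    Returns
    -------
    (n, k) dependency matrix.
    """
    n = adj.shape[0]
    k = len(source_idx)
    cols = np.arange(k)

    dist = np.full((n, k), -1, dtype=np.int32)
    sigma = np.zeros((n, k), dtype=np.float64)
    dist[source_idx, cols] = 0
    sigma[source_idx, cols] = 1.0

    # forward sweep: frontier-by-frontier sigma accumulation
    frontier = np.zeros((n, k), dtype=np.float64)
    frontier[source_idx, cols] = 1.0
    level = 0
    levels: list[np.ndarray] = [frontier.astype(bool)]
    while True:
        pushed = adj @ (sigma * frontier)
        newmask = (pushed > 0) & (dist < 0)
        if not newmask.any():
            break
        level += 1
        dist[newmask] = level
        sigma[newmask] = pushed[newmask]
        frontier = newmask.astype(np.float64)
        levels.append(newmask)

    # backward sweep: delta(v) += sigma(v)/sigma(u) * (delta(u) + wt(u))
    # for each successor u of v (dist(u) = dist(v)+1)
    delta = np.zeros((n, k), dtype=np.float64)
    wt = target_weight.astype(np.float64, copy=True)
    wt[source_idx, cols] = 0.0  # a source is never its own target
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sigma = np.where(sigma > 0, 1.0 / np.where(sigma > 0, sigma, 1.0), 0.0)
    for d in range(level, 0, -1):
        mask = levels[d]
        coef = np.where(mask, (delta + wt) * inv_sigma, 0.0)
        spread = adj @ coef
        prev = levels[d - 1]
        delta[prev] += (sigma * spread)[prev]
    delta[source_idx, cols] = 0.0
    return delta


def compute_nlbc(
    net: MolecularNetwork, inputs: InputGeneSet
) -> CentralityTable:
    """Node-limited betweenness centrality of every network node.

    Runs the restricted Brandes accumulation once per input source,
    batched; per source s the unweighted dependency (targets U \\ {s},
    weight 1) scaled by w(s) and the target-weight-carrying dependency
    are summed, which over all ordered source-target pairs double-counts
    the unordered-pair numerator exactly as the ordered normalizer
    double-counts w, so the unordered contract value emerges unchanged.
    """
    adj, order = _adjacency(net)
    index = {g: i for i, g in enumerate(order)}
    missing = [g for g in inputs.weights if g not in index]
    if missing:
        raise KeyError(f"input nodes not in network: {sorted(missing)}")

    u_nodes = inputs.nodes
    u_idx = np.array([index[g] for g in u_nodes], dtype=np.intp)
    u_w = np.array([inputs.weights[g] for g in u_nodes], dtype=np.float64)

    numerator = _nlbc_numerator(adj, u_idx, u_w)
    w_total = (len(u_nodes) - 1) * float(u_w.sum())
    values = {
        g: float(x) for g, x in zip(order, numerator / (2.0 * w_total))
    }
    return CentralityTable(values=values, normalizer=w_total)


def _nlbc_numerator(
    adj: sp.csr_array, u_idx: np.ndarray, u_w: np.ndarray
) -> np.ndarray:
    """Ordered-pair nlBC numerator (twice the unordered-pair sum).

    The backward accumulation is linear in the target weights, so the
    source-weight term w(s)*delta^1 and the target-weight term delta^w
    collapse into one pass carrying the pair weight w(s) + w(t) directly.
    """
    n = adj.shape[0]
    k = len(u_idx)
    pair_w = np.zeros((n, k), dtype=np.float64)
    pair_w[u_idx, :] = u_w[:, None] + u_w[None, :]
    delta = _restricted_dependencies(adj, u_idx, pair_w)
    return delta.sum(axis=1)


def brute_force_nlbc(
    net: MolecularNetwork,
    inputs: InputGeneSet,
    *,
    max_nodes: int = 200,
) -> CentralityTable:
    """Literal nlBC by enumerating every shortest path of every input pair.

    Test-only oracle; guarded to small networks because path enumeration
    is exponential in the worst case.
    """
    if net.n_nodes > max_nodes:
        raise ValueError(
            f"brute-force oracle limited to {max_nodes} nodes "
            f"(got {net.n_nodes})"
        )
    u_nodes = inputs.nodes
    totals: dict[str, float] = {g: 0.0 for g in net.nodes}
    normalizer = 0.0
    for i, s in enumerate(u_nodes):
        dag = bfs_shortest_paths(net, s)
        for t in u_nodes[i + 1 :]:
            pair_w = inputs.weights[s] + inputs.weights[t]
            normalizer += pair_w
            if t not in dag.dist:
                continue  # disconnected pair: zero paths, w still counted
            paths = _enumerate_paths(dag, t)
            n_paths = len(paths)
            for path in paths:
                for v in path[1:-1]:  # interior nodes only
                    totals[v] += pair_w / n_paths
    values = {g: c / normalizer for g, c in totals.items()}
    return CentralityTable(values=values, normalizer=normalizer)


def _enumerate_paths(dag: ShortestPathDAG, t: str) -> list[list[str]]:
    """All shortest paths source->t by walking predecessors backward."""
    if t == dag.source:
        return [[t]]
    out: list[list[str]] = []
    for p in dag.preds[t]:
        for prefix in _enumerate_paths(dag, p):
            out.append(prefix + [t])
    return out


def standard_bc(net: MolecularNetwork) -> dict[str, float]:
    """Classical unnormalized betweenness over unordered pairs of all nodes.

    Serves as the global-limit reference: with U = V and uniform weights,
    nlBC(v) = BC(v) / C(|V|, 2).  Delegates to the networkx Brandes
    implementation, which is an independent code path from the restricted
    accumulation above.
    """
    import networkx as nx

    return dict(
        nx.betweenness_centrality(net.graph, normalized=False, weight=None)
    )
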