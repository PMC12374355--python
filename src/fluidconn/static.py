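"""Static phase-lag-index connectivity and null-normalized global graph metrics.

The static branch summarizes each subject's full-length band-limited phase
series as one weighted, undirected graph (pairwise phase-lag index, PLI) and
four global topology measures:

* average node strength — mean over nodes of the summed incident weights;
* Louvain modularity Q — greedy multi-level community detection followed by
  iterative single-node fine-tuning until Q stops improving;
* average weighted clustering coefficient (Onnela: geometric mean of triangle
  weights, weights normalized by the graph maximum);
* characteristic path length — mean shortest-path distance over ordered node
  pairs with edge length 1/weight.

Clustering and path length are reported normalized by their means over an
ensemble of null networks that preserve the binary degree sequence and the
weight multiset exactly and node strengths approximately (rank-matched weight
reassignment, the convention of weighted null-model rewiring). PLI graphs are
dense, so degree preservation is vacuous there and the null model reduces to
strength-aware weight shuffling.

The PLI convention is Stam's: ``|mean sign(delta phi)|`` with sign(0) = 0, so
identical (zero-lag) signals score 0 — the index is deliberately blind to
volume-conduction-like instantaneous coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

try:  # jit-compiled strength-repair loop; numpy fallback is exact but slower
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

from .signals import PhaseMatrix, wrap_phase

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityGraph",
    "GraphMetrics",
    "pli",
    "sfc_graph",
    "average_node_strength",
    "modularity_q",
    "louvain_modularity",
    "clustering_and_path",
    "null_model",
    "normalized_metrics",
]


@dataclass
class ConnectivityGraph:
    """Symmetric weighted graph with zero diagonal and weights in [0, 1]."""

    weights: np.ndarray
    region_labels: list[str] | None = None
    band: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = (w + w.T) / 2.0

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class GraphMetrics:
    """Global metrics of one subject x band connectivity graph."""

    av_node_strength: float
    modularity: float
    norm_cluster: float
    norm_path: float
    raw_cluster: float
    raw_path: float
    disconnected: bool
    n_null: int
    null_seed: int | None


def pli(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Phase-lag index: absolute mean sign of the wrapped phase difference."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1 or phase_i.size < 2:
        raise ValueError("phase vectors must be 1-D, equal length >= 2")
    diff = wrap_phase(phase_i - phase_j)
    return float(abs(np.mean(np.sign(diff))))


def sfc_graph(phases: PhaseMatrix) -> ConnectivityGraph:
    """Pairwise PLI matrix over all regions (zero diagonal).

    Channels flagged in ``phases.excluded`` get zero rows/columns, with a log
    record, rather than fabricated coupling values.
    """
    n = phases.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    w = np.zeros((n, n))
    for i in range(n - 1):
        diff = wrap_phase(phases.phases[i] - phases.phases[i + 1 :])
        w[i, i + 1 :] = np.abs(np.mean(np.sign(diff), axis=1))
    w = w + w.T
    if phases.excluded:
        logger.warning("zeroing excluded channels %s in sFC graph", phases.excluded)
        w[phases.excluded, :] = 0.0
        w[:, phases.excluded] = 0.0
    return ConnectivityGraph(
        weights=w,
        region_labels=list(phases.region_labels),
        band=phases.band,
        subject_id=phases.subject_id,
    )


def average_node_strength(g: ConnectivityGraph) -> float:
    """Mean over nodes of the summed incident edge weights."""
    return float(g.weights.sum(axis=1).mean())


def modularity_q(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity Q of a node-to-community assignment."""
    w_total = weights.sum()  # = 2m for an undirected matrix
    if w_total == 0:
        raise ValueError("zero total weight")
    strengths = weights.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += weights[np.ix_(idx, idx)].sum() / w_total
        q -= (strengths[idx].sum() / w_total) ** 2
    return float(q)


def _finetune(weights: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
              max_passes: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Iterative single-node fine-tuning: move nodes between communities while
    Q increases; stops when a full pass yields no improvement above ``tol``."""
    labels = labels.copy()
    n = len(labels)
    w_total = weights.sum()
    strengths = weights.sum(axis=1)
    for _ in range(max_passes):
        improved = False
        order = rng.permutation(n)
        for node in order:
            current = labels[node]
            # strength of node toward each community, excluding itself
            comms, inv = np.unique(labels, return_inverse=True)
            k_to = np.zeros(len(comms))
            np.add.at(k_to, inv, weights[node])
            k_to[inv[node]] -= weights[node, node]  # diagonal is zero anyway
            sum_s = np.zeros(len(comms))
            np.add.at(sum_s, inv, strengths)
            own = np.flatnonzero(comms == current)[0]
            # Delta Q of moving node from its community to community c
            # (the last candidate is a fresh singleton community)
            base = k_to[own] - strengths[node] * (sum_s[own] - strengths[node]) / w_total
            gains = np.append(k_to - strengths[node] * sum_s / w_total, 0.0)
            gains[own] = base
            best = int(np.argmax(gains))
            if best != own and gains[best] > base + tol * w_total:
                labels[node] = comms[best] if best < len(comms) else labels.max() + 1
                improved = True
        # merge pass: single-node moves cannot merge two whole communities
        comms = np.unique(labels)
        if len(comms) > 1:
            sum_s = np.array([strengths[labels == c].sum() for c in comms])
            best_gain, best_pair = tol * w_total, None
            for a in range(len(comms)):
                ia = labels == comms[a]
                for b in range(a + 1, len(comms)):
                    ib = labels == comms[b]
                    between = weights[np.ix_(ia, ib)].sum()
                    gain = between - sum_s[a] * sum_s[b] / w_total
                    if gain > best_gain:
                        best_gain, best_pair = gain, (comms[a], comms[b])
            if best_pair is not None:
                labels[labels == best_pair[1]] = best_pair[0]
                improved = True
        if not improved:
            break
    return labels


def louvain_modularity(
    g: ConnectivityGraph, seed: int = 0, n_restarts: int = 5
) -> tuple[np.ndarray, float]:
    """Louvain community detection plus iterative single-node fine-tuning.

    Runs ``n_restarts`` seeded Louvain passes, fine-tunes each, and returns
    the labeling with the highest weighted Newman Q (resolution 1).
    """
    w = g.weights
    if w.sum() == 0:
        raise ValueError("zero total weight: modularity undefined")
    graph = nx.from_numpy_array(w)
    ss = np.random.SeedSequence(seed)
    best_labels, best_q = None, -np.inf
    for k, child in enumerate(ss.spawn(n_restarts)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        if k % 2 == 0:
            communities = nx.community.louvain_communities(
                graph, weight="weight", seed=sub_seed
            )
            labels = np.empty(g.n_nodes, dtype=int)
            for c, nodes in enumerate(communities):
                labels[list(nodes)] = c
        else:
            # random initial partition: diversifies the search basins that
            # greedy Louvain aggregation cannot leave
            labels = rng.integers(0, int(rng.integers(2, 5)), size=g.n_nodes)
        labels = _finetune(w, labels, rng)
        q = modularity_q(w, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, float(best_q)


def _onnela_clustering(weights: np.ndarray) -> float:
    """Average Onnela weighted clustering (weights normalized by the max)."""
    wmax = weights.max()
    if wmax == 0:
        return 0.0
    cube = np.cbrt(weights / wmax)
    triangles = np.diag(cube @ cube @ cube)
    degree = (weights > 0).sum(axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_node = np.where(denom > 0, triangles / denom, 0.0)
    return float(per_node.mean())


def clustering_and_path(g: ConnectivityGraph):
    """(average Onnela clustering, characteristic path length, disconnected).

    Path length uses edge distance 1/weight. For disconnected graphs the mean
    is taken over reachable ordered pairs only, with a logged warning and the
    ``disconnected`` flag set.
    """
    w = g.weights
    clustering = _onnela_clustering(w)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(g.n_nodes, dtype=bool)
    finite = np.isfinite(dist[off])
    disconnected = not finite.all()
    if disconnected:
        logger.warning("graph disconnected: path length over reachable pairs only")
    cpl = float(dist[off][finite].mean()) if finite.any() else float("inf")
    return clustering, cpl, disconnected


@njit(cache=True)
def _repair_strengths(edges, w, s_cur, s_target, n_iter, seed):
    """Zero-temperature acceptance: swap edge weights only when the swap
    reduces the summed squared node-strength error."""
    np.random.seed(seed)
    n_edges = edges.shape[0]
    nodes = np.empty(4, dtype=np.int64)
    deltas = np.empty(4)
    for _ in range(n_iter):
        a = np.random.randint(n_edges)
        b = np.random.randint(n_edges)
        if a == b:
            continue
        d = w[b] - w[a]
        if d == 0.0:
            continue
        nodes[0], nodes[1] = edges[a, 0], edges[a, 1]
        nodes[2], nodes[3] = edges[b, 0], edges[b, 1]
        deltas[0] = deltas[1] = d
        deltas[2] = deltas[3] = -d
        old_err = 0.0
        new_err = 0.0
        for i in range(4):
            # merge duplicate nodes: only the first occurrence accumulates
            dup = False
            for j in range(i):
                if nodes[j] == nodes[i]:
                    deltas[j] += deltas[i]
                    dup = True
                    break
            if dup:
                deltas[i] = 0.0
        for i in range(4):
            seen = False
            for j in range(i):
                if nodes[j] == nodes[i]:
                    seen = True
                    break
            if seen:
                continue
            err = s_cur[nodes[i]] - s_target[nodes[i]]
            old_err += err * err
            err_new = err + deltas[i]
            new_err += err_new * err_new
        if new_err < old_err:
            w[a], w[b] = w[b], w[a]
            s_cur[edges[a, 0]] += d
            s_cur[edges[a, 1]] += d
            s_cur[edges[b, 0]] -= d
            s_cur[edges[b, 1]] -= d


def null_model(g: ConnectivityGraph, seed: int = 0, rewire_factor: int = 10,
               repair_factor: int = 40) -> ConnectivityGraph:
    """Randomized graph preserving degrees, the weight multiset, and
    (approximately) node strengths.

    Topology: degree-preserving double-edge swaps on the binary graph (a no-op
    for complete graphs, where every swap is blocked). Weights: the original
    weight multiset is reassigned to the randomized edges by picking a random
    edge and giving it the weight whose rank matches the edge's rank by
    expected strength (product of residual strengths), which keeps node
    strengths close to the originals.
    """
    n = g.n_nodes
    if n < 4:
        raise ValueError("graph too small to rewire (n < 4)")
    rng = np.random.default_rng(seed)
    w = g.weights
    strengths = w.sum(axis=1)
    iu = np.triu_indices(n, k=1)
    present = w[iu] > 0
    edges = np.column_stack((iu[0][present], iu[1][present]))
    weights_pool = w[iu][present]
    n_edges = len(edges)
    max_edges = n * (n - 1) // 2
    if n_edges < max_edges:  # sparse: randomize topology, keep degrees
        graph = nx.from_numpy_array((w > 0).astype(int))
        try:
            nx.double_edge_swap(
                graph,
                nswap=rewire_factor * n_edges,
                max_tries=100 * rewire_factor * n_edges,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXException:
            # near-complete graphs run out of swappable pairs; completed
            # swaps are kept (each one already preserved the degrees)
            pass
        edges = np.array(graph.edges(), dtype=int)
    # stage 1: rank-matched weight reassignment (random edge pick, weight
    # whose rank matches the edge's expected-strength rank)
    pool_left = np.sort(weights_pool)[::-1]  # descending
    residual = strengths.astype(float).copy()
    edge_list = np.asarray(edges, dtype=np.int64)
    n_edges_final = len(edge_list)
    assigned = np.empty(n_edges_final)
    alive = np.ones(n_edges_final, dtype=bool)
    for pick in rng.permutation(n_edges_final):
        live = np.flatnonzero(alive)
        expected = residual[edge_list[live, 0]] * residual[edge_list[live, 1]]
        pos = int(np.searchsorted(live, pick))
        rank = int((expected > expected[pos]).sum())
        wgt = pool_left[rank]
        pool_left = np.delete(pool_left, rank)
        assigned[pick] = wgt
        residual[edge_list[pick, 0]] -= wgt
        residual[edge_list[pick, 1]] -= wgt
        alive[pick] = False
    # stage 2: strength-matching acceptance (error-reducing weight swaps)
    s_cur = np.zeros(n)
    np.add.at(s_cur, edge_list[:, 0], assigned)
    np.add.at(s_cur, edge_list[:, 1], assigned)
    _repair_strengths(
        edge_list,
        assigned,
        s_cur,
        strengths.astype(float),
        int(repair_factor * n_edges_final),
        int(rng.integers(2**31)),
    )
    new_w = np.zeros((n, n))
    new_w[edge_list[:, 0], edge_list[:, 1]] = assigned
    new_w[edge_list[:, 1], edge_list[:, 0]] = assigned
    return ConnectivityGraph(
        weights=new_w,
        region_labels=g.region_labels,
        band=g.band,
        subject_id=g.subject_id,
    )


def normalized_metrics(
    g: ConnectivityGraph, n_null: int = 100, seed: int = 0
) -> GraphMetrics:
    """All four global metrics, with clustering and path length divided by
    their means over ``n_null`` null networks."""
    raw_cluster, raw_path, disconnected = clustering_and_path(g)
    _, q = louvain_modularity(g, seed=seed)
    strength = average_node_strength(g)
    ss = np.random.SeedSequence(seed)
    null_clusters = np.empty(n_null)
    null_paths = np.empty(n_null)
    for k, child in enumerate(ss.spawn(n_null)):
        null = null_model(g, seed=int(child.generate_state(1)[0] % (2**31)))
        null_clusters[k], null_paths[k], _ = clustering_and_path(null)
    mean_c, mean_p = null_clusters.mean(), null_paths.mean()
    if mean_c == 0 or mean_p == 0 or not np.isfinite(mean_p):
        logger.warning("undefined normalization (null mean zero or infinite)")
        norm_c = float("nan") if mean_c == 0 else raw_cluster / mean_c
        norm_p = float("nan") if (mean_p == 0 or not np.isfinite(mean_p)) else raw_path / mean_p
    else:
        norm_c = raw_cluster / mean_c
        norm_p = raw_path / mean_p
    return GraphMetrics(
        av_node_strength=strength,
        modularity=q,
        norm_cluster=float(norm_c),
        norm_path=float(norm_p),
        raw_cluster=raw_cluster,
        raw_path=raw_path,
        disconnected=disconnected,
        n_null=n_null,
        null_seed=seed,
    )
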