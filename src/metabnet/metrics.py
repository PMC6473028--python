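"""Graph-theoretic network parameters on binary adjacency matrices.

Implements the standard small-world battery on undirected, unweighted graphs:
clustering coefficient C, characteristic path length L, global and local
efficiency, shortest-path betweenness centrality, and the normalized indices
gamma = C/C_null, lambda = L/L_null, sigma = gamma/lambda against
degree-preserving rewired surrogates (Maslov–Sneppen double edge swaps).

Conventions for disconnected graphs: node pairs with no connecting path are
excluded from L's mean (their count is reported) and contribute 0 to
efficiency, keeping both finite.  Metrics are computed with dense
numpy/scipy kernels for speed inside permutation and bootstrap loops;
networkx is used for betweenness and cross-checks the kernels in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "clustering_coefficient",
    "characteristic_path_length",
    "efficiencies",
    "betweenness_table",
    "small_world_indices",
    "SmallWorldResult",
    "metric_curve",
    "hub_table",
    "is_connected",
]

HUB_BI_THRESHOLD = 1.5


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency must be 0/1")
    return adj.astype(np.int8)


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths; inf where disconnected.

    Breadth-first search by boolean matrix powers — fast on the dense,
    small-diameter graphs this package produces.
    """
    n = adj.shape[0]
    a = adj.astype(bool)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reached = a | np.eye(n, dtype=bool)
    d[a] = 1.0
    step = 1
    while True:
        step += 1
        new = (reached @ a) & ~reached
        if not new.any():
            break
        d[new] = step
        reached |= new
    return d


def is_connected(adj: np.ndarray) -> bool:
    adj = _check_adjacency(adj)
    if adj.shape[0] <= 1:
        return True
    return bool(np.isfinite(_distances(adj)).all())


def clustering_coefficient(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its mean over all nodes.

    C_i = triangles_i / (k_i (k_i − 1) / 2); nodes of degree < 2 get C_i = 0.
    """
    adj = _check_adjacency(adj)
    a = adj.astype(float)
    k = a.sum(axis=1)
    # diag(A^3) counts twice the triangles through each node
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path length over connected node pairs.

    Returns (L, number of disconnected unordered pairs).  A graph with no
    edges has no connected pairs and is rejected.
    """
    adj = _check_adjacency(adj)
    if adj.sum() == 0:
        raise ValueError("graph has no edges; path length undefined")
    d = _distances(adj)
    off = ~np.eye(adj.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_disconnected = int((off & ~np.isfinite(d)).sum() // 2)
    return float(d[finite].mean()), n_disconnected


def _global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def efficiencies(adj: np.ndarray) -> tuple[float, float]:
    """(global efficiency, local efficiency).

    Eglob is the mean of 1/d(i,j) over ordered pairs (0 for disconnected
    pairs).  Eloc averages, over nodes, the global efficiency of each node's
    neighbour-induced subgraph; nodes with fewer than two neighbours
    contribute 0.
    """
    adj = _check_adjacency(adj)
    eglob = _global_efficiency(adj)
    n = adj.shape[0]
    eloc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) >= 2:
            eloc_terms[i] = _global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return eglob, float(eloc_terms.mean())


def betweenness_table(
    adj: np.ndarray, node_names: list[str] | None = None
) -> pd.DataFrame:
    """Shortest-path betweenness, normalized betweenness bi, and hub flags.

    bi = BC / mean(BC) over all nodes; a node is a candidate hub when
    bi > 1.5.  Equal-length shortest paths split the count evenly.  With a
    zero mean BC (e.g. a complete graph) bi is undefined and no hubs are
    flagged.
    """
    adj = _check_adjacency(adj)
    g = nx.from_numpy_array(adj)
    bc_dict = nx.betweenness_centrality(g, normalized=False)
    bc = np.array([bc_dict[i] for i in range(adj.shape[0])])
    mean_bc = bc.mean()
    if mean_bc == 0:
        warnings.warn("mean betweenness is zero; bi undefined, no hubs flagged")
        bi = np.full_like(bc, np.nan)
        hub = np.zeros(len(bc), dtype=bool)
    else:
        bi = bc / mean_bc
        hub = bi > HUB_BI_THRESHOLD
    names = node_names if node_names is not None else list(range(adj.shape[0]))
    return pd.DataFrame({"node": names, "BC": bc, "bi": bi, "hub": hub})


def _maslov_sneppen_rewire(
    adj: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Degree-preserving double edge swaps; returns (rewired adjacency, accepted)."""
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    edge_set = set(edges)
    m = len(edges)
    accepted = 0
    tries = 0
    max_tries = 100 * max(n_swaps, 1)
    block = 4096
    while accepted < n_swaps and tries < max_tries:
        # draw proposals in blocks: per-call RNG overhead dominates otherwise
        pairs = rng.integers(0, m, size=(block, 2))
        flips = rng.random(block) < 0.5
        for (e1, e2), flip in zip(pairs.tolist(), flips.tolist()):
            tries += 1
            if accepted >= n_swaps or tries >= max_tries:
                break
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip:
                c, d = d, c
            # proposed replacement: (a,b),(c,d) -> (a,c),(b,d)
            if a == c or a == d or b == c or b == d:
                continue
            new1 = (a, c) if a < c else (c, a)
            new2 = (b, d) if b < d else (d, b)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            accepted += 1
    out = np.zeros_like(adj)
    for i, j in edges:
        out[i, j] = 1
        out[j, i] = 1
    return out, accepted


@dataclass
class SmallWorldResult:
    C: float
    L: float
    C_null: float
    L_null: float
    gamma: float
    lam: float
    sigma: float
    n_null: int
    swaps_per_edge: float
    seed: int


def small_world_indices(
    adj: np.ndarray,
    n_null: int = 100,
    swaps_per_edge: float = 10.0,
    seed: int = 0,
) -> SmallWorldResult:
    """Small-world indices against degree-preserving random surrogates.

    gamma = C/C_null and lambda = L/L_null, with C_null and L_null averaged
    over ``n_null`` Maslov–Sneppen rewired surrogates (``swaps_per_edge × |E|``
    accepted swaps each); sigma = gamma/lambda.  Seeded and reproducible.

    A graph whose degree sequence admits no rewiring (e.g. complete) returns
    gamma = lambda = sigma = 1 with a warning.
    """
    adj = _check_adjacency(adj)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    _, c = clustering_coefficient(adj)
    length, _ = characteristic_path_length(adj)
    n_edges = int(adj.sum() // 2)
    n_swaps = int(round(swaps_per_edge * n_edges))
    rng = np.random.default_rng(seed)
    c_nulls, l_nulls = [], []
    total_accepted = 0
    for _ in range(n_null):
        surrogate, accepted = _maslov_sneppen_rewire(adj, n_swaps, rng)
        total_accepted += accepted
        _, cn = clustering_coefficient(surrogate)
        ln, _ = characteristic_path_length(surrogate)
        c_nulls.append(cn)
        l_nulls.append(ln)
    if total_accepted == 0:
        warnings.warn("degree sequence admits no rewiring; gamma=lambda=sigma=1")
        return SmallWorldResult(c, length, c, length, 1.0, 1.0, 1.0,
                                n_null, swaps_per_edge, seed)
    c_null = float(np.mean(c_nulls))
    l_null = float(np.mean(l_nulls))
    gamma = c / c_null if c_null > 0 else np.inf
    lam = length / l_null
    return SmallWorldResult(
        C=c, L=length, C_null=c_null, L_null=l_null,
        gamma=gamma, lam=lam, sigma=gamma / lam,
        n_null=n_null, swaps_per_edge=swaps_per_edge, seed=seed,
    )


CURVE_METRICS = ("C", "L", "Eglob", "Eloc", "gamma", "lambda", "sigma")


def metric_curve(
    stack,
    n_null: int = 100,
    swaps_per_edge: float = 10.0,
    seed: int = 0,
    include_small_world: bool = True,
) -> pd.DataFrame:
    """All network parameters across a sparsity sweep, one row per sparsity.

    Columns: sparsity, C, L, Eglob, Eloc and, when ``include_small_world``,
    gamma, lambda, sigma (plus the null means).  The per-sparsity null seed is
    derived deterministically from ``seed``.
    """
    rows = []
    for idx, s in enumerate(stack.sparsities):
        adj = stack[float(s)]
        _, c = clustering_coefficient(adj)
        length, n_disc = characteristic_path_length(adj)
        eglob, eloc = efficiencies(adj)
        row = {
            "sparsity": float(s), "C": c, "L": length,
            "Eglob": eglob, "Eloc": eloc, "disconnected_pairs": n_disc,
        }
        if include_small_world:
            sw = small_world_indices(
                adj, n_null=n_null, swaps_per_edge=swaps_per_edge,
                seed=(seed * 1000 + idx) % (2**31),
            )
            row.update({"gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma,
                        "C_null": sw.C_null, "L_null": sw.L_null})
        rows.append(row)
    df = pd.DataFrame(rows)
    if getattr(stack, "group_label", ""):
        df.insert(0, "group", stack.group_label)
    return df


def hub_table(
    adj: np.ndarray, node_names: list[str] | None = None
) -> pd.DataFrame:
    """Betweenness/hub table with a connectivity check first.

    Hub analysis is meaningful on a fully connected network (no region
    isolated); a disconnected input triggers a warning but is still analysed.
    """
    if not is_connected(adj):
        warnings.warn("network is disconnected; hub analysis covers all components")
    return betweenness_table(adj, node_names)
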