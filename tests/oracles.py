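"""Brute-force reference implementations used only by the test suite.

Everything here is deliberately naive — explicit loops, full path
enumeration — and independent of the package's vectorized kernels.
"""

import numpy as np


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by explicit triple loop over neighbour pairs."""
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    tri += 1
        out[i] = tri / (k * (k - 1) / 2)
    return out


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by plain queue-based BFS per source."""
    n = len(adj)
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        queue = [s]
        while queue:
            u = queue.pop(0)
            for v in range(n):
                if adj[u, v] and d[s, v] == np.inf:
                    d[s, v] = d[s, u] + 1
                    queue.append(v)
    return d


def oracle_path_length(adj: np.ndarray) -> tuple[float, int]:
    d = oracle_distances(adj)
    vals, n_disc = [], 0
    n = len(adj)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(d[i, j]):
                vals.append(d[i, j])
            else:
                n_disc += 1
    return float(np.mean(vals)), n_disc // 2


def oracle_global_efficiency(adj: np.ndarray) -> float:
    d = oracle_distances(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) >= 2:
            sub = adj[np.ix_(nbrs, nbrs)]
            total += oracle_global_efficiency(sub)
    return total / n


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration of every shortest path."""
    n = len(adj)
    d = oracle_distances(adj)
    bc = np.zeros(n)

    def all_shortest_paths(s, t):
        if not np.isfinite(d[s, t]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in range(n):
                if adj[u, v] and d[s, v] == len(path) and d[v, t] == d[s, t] - len(path):
                    extend(path + [v])

        extend([s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for path in paths:
                for u in path[1:-1]:
                    bc[u] += 1.0 / len(paths)
    return bc


def oracle_bh_fdr(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg by explicit sort-and-scan; returns discovery flags."""
    p = np.asarray(pvalues, dtype=float)
    mtot = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / mtot:
            k_max = rank
    flags = np.zeros(mtot, dtype=bool)
    flags[order[:k_max]] = True
    return flags
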