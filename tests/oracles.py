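"""Independent brute-force oracles for the graph measures.

Everything here is deliberately naive (exhaustive enumeration over
paths, pairs and partitions) and shares no code with the package's
implementations; it is only usable on tiny graphs.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_simple_paths(a: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All simple s-t paths by exhaustive DFS on an adjacency matrix."""
    n = a.shape[0]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in range(n):
            if a[u, v] and v not in path:
                extend(path + [v])

    extend([s])
    return paths


def bf_distances_and_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise shortest-path lengths and counts via path enumeration."""
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        for t in range(n):
            if s == t:
                continue
            paths = all_simple_paths(a, s, t)
            if not paths:
                continue
            lengths = [len(p) - 1 for p in paths]
            d = min(lengths)
            dist[s, t] = d
            sigma[s, t] = sum(1 for L in lengths if L == d)
    return dist, sigma


def bf_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    dist, _ = bf_distances_and_counts(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for x, y in itertools.combinations(nbrs, 2) if a[x, y]
        )
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def bf_flow(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    f = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        open_pairs = sum(
            1 for x, y in itertools.combinations(nbrs, 2) if not a[x, y]
        )
        f[i] = open_pairs / (k * (k - 1) / 2.0)
    return f


def bf_betweenness(a: np.ndarray) -> np.ndarray:
    """Unordered-pair betweenness by enumerating all shortest paths."""
    n = a.shape[0]
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_simple_paths(a, s, t)
        if not paths:
            continue
        lengths = [len(p) - 1 for p in paths]
        d = min(lengths)
        shortest = [p for p, L in zip(paths, lengths) if L == d]
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in shortest if i in p[1:-1])
            if through:
                b[i] += through / len(shortest)
    return b


def bf_participation(a: np.ndarray, partition: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    p = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(partition):
            k_im = sum(1 for j in range(n) if a[i, j] and partition[j] == m)
            acc += (k_im / k) ** 2
        p[i] = 1.0 - acc
    return p


def bf_modularity(a: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] == partition[j]:
                q += a[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def best_partition_exhaustive(a: np.ndarray, gamma: float = 1.0):
    """Globally optimal modularity partition by enumerating all set
    partitions (feasible for <= ~8 nodes)."""
    n = a.shape[0]

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best = -np.inf, None
    for part in partitions(list(range(n))):
        assignment = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            assignment[block] = c
        q = bf_modularity(a, assignment, gamma)
        if q > best_q:
            best_q, best = q, assignment
    return best, best_q


def random_connected_graph(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random connected graph: a random spanning tree plus random edges."""
    a = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for idx in range(1, n):
        u = order[idx]
        v = order[rng.integers(0, idx)]
        a[u, v] = a[v, u] = 1
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.3:
            a[i, j] = a[j, i] = 1
    return a
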