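"""Independent brute-force oracles used by the test suite.

Deliberately implemented from first principles (hand-rolled BFS, explicit
path enumeration, exact rational arithmetic) without touching the package's
own code paths or networkx, so they can serve as ground truth.
"""

from collections import deque
from fractions import Fraction
from itertools import combinations
from math import comb


def bfs_distances(adjacency, source):
    """Hop distances from ``source`` over an adjacency dict."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adjacency, source, target):
    """All shortest paths source -> target, by backtracking BFS predecessors."""
    dist = bfs_distances(adjacency, source)
    if target not in dist:
        return []
    paths = []

    def backtrack(node, suffix):
        if node == source:
            paths.append([source] + suffix)
            return
        for prev in adjacency[node]:
            if dist.get(prev, -2) == dist[node] - 1:
                backtrack(prev, [node] + suffix)

    backtrack(target, [])
    return paths


def oracle_locate(adjacency, signature_nodes, n, min_nodes):
    """Reference subpathway location: BFS distances + explicit path
    enumeration + union-find over signature pairs at distance <= n.

    Returns a set of (frozenset(node_ids), frozenset(signature_ids)).
    """
    signature = sorted(signature_nodes)
    dist = {s: bfs_distances(adjacency, s) for s in signature}

    parent = {s: s for s in signature}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s, t in combinations(signature, 2):
        if t in dist[s] and dist[s][t] <= n:
            parent[find(s)] = find(t)

    components = {}
    for s in signature:
        components.setdefault(find(s), set()).add(s)

    out = set()
    for comp in components.values():
        nodes = set(comp)
        for s, t in combinations(sorted(comp), 2):
            for path in enumerate_shortest_paths(adjacency, s, t):
                nodes.update(path)
        if len(nodes) >= min_nodes:
            out.add((frozenset(nodes), frozenset(comp)))
    return out


def exact_hypergeom_tail(x, N, K, m):
    """P(X >= x) as an exact rational: sum of C(K,i) C(N-K,m-i) / C(N,m)."""
    if x <= 0:
        return Fraction(1)
    total = Fraction(0)
    for i in range(x, min(m, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, m - i), comb(N, m))
    return total


def exact_hypergeom_tail_by_enumeration(x, N, K, m):
    """Same tail by enumerating all C(N, m) draws (tiny N only)."""
    population = [1] * K + [0] * (N - K)
    favorable = sum(1 for draw in combinations(range(N), m)
                    if sum(population[i] for i in draw) >= x)
    return Fraction(favorable, comb(N, m))


def bh_stepup(p_values, family_size):
    """Benjamini-Hochberg step-up by the definition, without vectorization."""
    indexed = sorted(enumerate(p_values), key=lambda t: t[1])
    q = [None] * len(p_values)
    running = None
    for rank in range(len(indexed), 0, -1):
        idx, p = indexed[rank - 1]
        value = p * family_size / rank
        running = value if running is None else min(running, value)
        q[idx] = min(running, 1.0)
    return q


def brute_betweenness(adjacency):
    """Betweenness by explicit enumeration of every pair's shortest paths."""
    nodes = sorted(adjacency)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = enumerate_shortest_paths(adjacency, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def permutation_rank_sum_p(a, b, rng, n_permutations):
    """Two-sided permutation p-value for the rank-sum statistic."""
    import numpy as np

    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    center = n_a * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - center)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ranks)
        if abs(perm[:n_a].sum() - center) >= obs_dev - 1e-12:
            hits += 1
    return hits / n_permutations


def _midranks(values):
    import numpy as np

    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def numpy_logrank_chi2(time, event, in_group_a):
    """Log-rank chi-square from scratch on numpy arrays (for permutations)."""
    import numpy as np

    o = e = v = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_group_a).sum()
        dying = event & (time == t)
        d = dying.sum()
        o += (dying & in_group_a).sum()
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return (o - e) ** 2 / v
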