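"""Independent brute-force oracles used across the test suite.

These deliberately re-derive quantities from first principles (pair
enumeration, exhaustive partition search, dense distance matrices) and
never call the code paths they check.
"""

import itertools

import numpy as np


def modularity(edges, weights, n, labels):
    """Weighted Newman–Girvan modularity of a labeling, from the definition."""
    m = float(np.sum(weights))
    if m == 0:
        return 0.0
    deg = np.zeros(n)
    for (u, v), w in zip(edges, weights):
        deg[u] += w
        deg[v] += w
    q = 0.0
    for c in set(labels):
        nodes = {i for i in range(n) if labels[i] == c}
        w_in = sum(w for (u, v), w in zip(edges, weights) if u in nodes and v in nodes)
        d_c = sum(deg[i] for i in nodes)
        q += w_in / m - (d_c / (2 * m)) ** 2
    return q


def best_two_partition(edges, weights, n):
    """Exhaustive modularity-optimal 2-partition.

    Returns (labels, is_unique); uniqueness at 1e-12 modularity tolerance.
    """
    best, best_q, unique = None, -np.inf, True
    for size in range(1, n // 2 + 1):
        for comb in itertools.combinations(range(n), size):
            if 2 * size == n and 0 not in comb:
                continue  # skip complements of already-seen halvings
            lab = np.array([0 if i in comb else 1 for i in range(n)])
            q = modularity(edges, weights, n, lab)
            if q > best_q + 1e-12:
                best_q, best, unique = q, lab, True
            elif abs(q - best_q) <= 1e-12:
                unique = False
    return best, unique


def is_connected(nodes, edges):
    """Whether `nodes` induce a connected subgraph of `edges`."""
    nodes = set(int(x) for x in nodes)
    if not nodes:
        return False
    adj = {i: set() for i in nodes}
    for u, v in edges:
        if u in nodes and v in nodes:
            adj[u].add(v)
            adj[v].add(u)
    seen = {next(iter(nodes))}
    frontier = list(seen)
    while frontier:
        x = frontier.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                frontier.append(y)
    return seen == nodes


def pair_counting_ari(a, b):
    """Adjusted Rand index by direct enumeration of all element pairs."""
    a, b = list(a), list(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0 if sd == 0 and ds == 0 else 0.0
    return (ss - expected) / (max_index - expected)


def random_connected_weighted_graph(rng, n_lo=4, n_hi=8):
    """A connected Erdős–Rényi-style graph with uniform edge weights."""
    while True:
        n = int(rng.integers(n_lo, n_hi + 1))
        p = rng.uniform(0.3, 0.8)
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if edges and is_connected(range(n), edges):
            weights = rng.uniform(0.05, 1.0, size=len(edges))
            return n, np.array(edges), weights
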