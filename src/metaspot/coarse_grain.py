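"""Agglomerate the weighted spatial graph into a merge tree; cut at any γ.

Two agglomeration schemes build a full merge history over the graph:

* walktrap — communities are merged in the order that minimizes the
  increase of the mean squared random-walk distance (Ward-style criterion
  on short random-walk profiles, walk length `steps`, default 4);
* greedy — Clauset–Newman–Moore-style agglomeration maximizing the
  weighted-modularity gain at each step.

Both schemes only ever merge communities joined by at least one retained
edge, so every cut of the tree yields spatially connected metaspots.
Zero-weight edges count for this adjacency but carry zero random-walk
probability / zero modularity gain, which makes them operationally
equivalent to absence for the merge order. All tie-breaks are by lowest
community index, so the tree is fully deterministic.

The graining level γ = n_spots / n_metaspots selects a cut: the tree is
replayed until max(n_components, round_half_up(n_spots/γ)) communities
remain, so different γ never require re-clustering.
"""

from __future__ import annotations

import heapq
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .preprocess import lognormalize
from .spatial_io import SpotMatrix
from .metaspot_graph import SpatialGraph

__all__ = [
    "MergeTree",
    "MetaspotPartition",
    "MetaspotMatrix",
    "walktrap_tree",
    "greedy_tree",
    "cut_tree",
    "aggregate",
    "round_half_up",
    "save_tree",
    "load_tree",
]

logger = logging.getLogger(__name__)

DEFAULT_STEPS = 4


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (2.5 → 3)."""
    return math.floor(x + 0.5)


@dataclass
class MergeTree:
    """Full agglomeration history of a graph.

    Leaves are spots 0..n_leaves−1; merge step t creates community
    n_leaves+t from two existing communities. Each community is merged at
    most once, so the merges form a forest; replaying a prefix of the list
    realizes any cut without re-clustering.
    """

    n_leaves: int
    merges: list  # [(community_a, community_b, new_community), ...]
    method: str = "walktrap"
    steps: Optional[int] = DEFAULT_STEPS

    def __post_init__(self) -> None:
        if self.method not in ("walktrap", "greedy"):
            raise ValueError(f"unknown method {self.method!r}")
        seen = set()
        for t, (a, b, c) in enumerate(self.merges):
            if a in seen or b in seen:
                raise ValueError("a community was merged twice")
            if c != self.n_leaves + t:
                raise ValueError("merge products must be numbered sequentially")
            seen.add(a)
            seen.add(b)

    @property
    def n_components(self) -> int:
        """Communities remaining after all merges (graph components)."""
        return self.n_leaves - len(self.merges)


@dataclass
class MetaspotPartition:
    """Spot → metaspot membership at one cut of the merge tree."""

    membership: np.ndarray
    gamma_requested: float
    gamma_effective: float = field(init=False)
    n_metaspots: int = field(init=False)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)
        if len(self.membership) == 0:
            raise ValueError("empty membership")
        labels = np.unique(self.membership)
        if labels[0] != 0 or labels[-1] != len(labels) - 1:
            raise ValueError("metaspot indices must be contiguous from 0")
        self.n_metaspots = int(len(labels))
        self.gamma_effective = len(self.membership) / self.n_metaspots

    @property
    def n_spots(self) -> int:
        return len(self.membership)

    @staticmethod
    def compact(raw_labels, gamma_requested: float) -> "MetaspotPartition":
        """Build a partition from arbitrary labels, renumbering metaspots
        contiguously in order of first appearance along the spot order."""
        seen: dict = {}
        membership = np.empty(len(raw_labels), dtype=np.int64)
        for i, lab in enumerate(raw_labels):
            if lab not in seen:
                seen[lab] = len(seen)
            membership[i] = seen[lab]
        return MetaspotPartition(membership, gamma_requested)

    def members(self) -> list:
        """List of member-index arrays, one per metaspot."""
        order = np.argsort(self.membership, kind="stable")
        bounds = np.searchsorted(
            self.membership[order], np.arange(self.n_metaspots + 1)
        )
        return [order[bounds[j] : bounds[j + 1]] for j in range(self.n_metaspots)]


@dataclass
class MetaspotMatrix:
    """Aggregated counts and centroid coordinates of a metaspot partition."""

    counts: sp.csc_matrix  # genes × metaspots, raw-count sums
    centroids: np.ndarray  # metaspots × 2
    sizes: np.ndarray  # members per metaspot
    normalized: Optional[sp.csc_matrix] = None
    purity: Optional[np.ndarray] = None
    spot_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        n_meta = self.counts.shape[1]
        if self.centroids.shape != (n_meta, 2):
            raise ValueError("centroids shape does not match metaspot count")
        if len(self.sizes) != n_meta:
            raise ValueError("sizes length does not match metaspot count")


# ---------------------------------------------------------------------------
# agglomeration


def _heap_loop(n: int, adj: list, delta_fn, merge_fn) -> list:
    """Shared agglomeration driver.

    adj: list of neighbor-id sets per community (mutated). delta_fn(a, b)
    returns the merge criterion (smaller = merged earlier). merge_fn(a, b,
    c) updates per-community state after c = a ∪ b. Ties pop as the
    lexicographically smallest (delta, a, b) tuple, i.e. lowest community
    indices first.
    """
    merges = []
    alive = [True] * n
    heap = [(delta_fn(a, b), a, b) for a in range(n) for b in adj[a] if a < b]
    heapq.heapify(heap)
    current = {(a, b): d for d, a, b in heap}
    next_id = n
    while heap:
        d, a, b = heapq.heappop(heap)
        key = (a, b)
        if (
            a >= len(alive)
            or b >= len(alive)
            or not alive[a]
            or not alive[b]
            or current.get(key) != d
        ):
            continue
        c = next_id
        next_id += 1
        merges.append((a, b, c))
        alive[a] = alive[b] = False
        alive.append(True)
        nbrs = (adj[a] | adj[b]) - {a, b}
        adj.append(nbrs)
        for x in nbrs:
            adj[x].discard(a)
            adj[x].discard(b)
            adj[x].add(c)
        adj[a] = adj[b] = set()
        merge_fn(a, b, c)
        for x in sorted(nbrs):
            dn = delta_fn(min(c, x), max(c, x))
            current[(min(c, x), max(c, x))] = dn
            heapq.heappush(heap, (dn, min(c, x), max(c, x)))
    return merges


def _adjacency_sets(g: SpatialGraph) -> list:
    adj: list = [set() for _ in range(g.n_spots)]
    for u, v in g.edges:
        adj[u].add(int(v))
        adj[v].add(int(u))
    return adj


def walktrap_tree(g: SpatialGraph, steps: int = DEFAULT_STEPS) -> MergeTree:
    """Walktrap agglomeration of the weighted spatial graph.

    Random-walk transition probabilities use the transcriptomic weights
    (nodes whose incident weights are all zero are absorbing). At each step
    the adjacent community pair minimizing the Ward-style increase of the
    mean squared walk-profile distance is merged; ties go to the lowest
    community indices. An edgeless graph yields a tree with no merges.
    """
    if steps < 1:
        raise ValueError("steps must be at least 1")
    n = g.n_spots
    if g.n_edges == 0:
        return MergeTree(n_leaves=n, merges=[], method="walktrap", steps=steps)
    w = g.weight if g.weight is not None else np.ones(g.n_edges)
    A = sp.coo_matrix(
        (
            np.r_[w, w],
            (np.r_[g.edges[:, 0], g.edges[:, 1]], np.r_[g.edges[:, 1], g.edges[:, 0]]),
        ),
        shape=(n, n),
    ).tocsr()
    wdeg = np.asarray(A.sum(axis=1)).ravel()
    absorbing = wdeg == 0
    inv_deg = np.where(absorbing, 0.0, 1.0 / np.where(absorbing, 1.0, wdeg))
    P = sp.diags(inv_deg) @ A
    if absorbing.any():  # zero-weighted-degree nodes: walk stays put
        P = P + sp.diags(absorbing.astype(float))
    Pt = P.copy()
    for _ in range(steps - 1):
        Pt = Pt @ P
    # profile metric: ||P^t_i - P^t_j|| with columns scaled by 1/sqrt(d)
    dcol = np.where(absorbing, 1.0, wdeg)
    M = np.asarray((Pt @ sp.diags(1.0 / np.sqrt(dcol))).todense())

    sums = {i: M[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}

    def delta(a: int, b: int) -> float:
        sa, sb = sizes[a], sizes[b]
        diff = sums[a] / sa - sums[b] / sb
        return (sa * sb) / ((sa + sb) * n) * float(diff @ diff)

    def merge(a: int, b: int, c: int) -> None:
        sums[c] = sums.pop(a) + sums.pop(b)
        sizes[c] = sizes.pop(a) + sizes.pop(b)

    merges = _heap_loop(n, _adjacency_sets(g), delta, merge)
    return MergeTree(n_leaves=n, merges=merges, method="walktrap", steps=steps)


def greedy_tree(g: SpatialGraph) -> MergeTree:
    """Greedy modularity agglomeration (Clauset–Newman–Moore style).

    At each step the adjacent community pair with the largest weighted
    modularity gain ΔQ = e_ab/m − d_a·d_b/(2m²) is merged (e_ab: weight
    between the pair, d: community weighted degree, m: total edge weight).
    Merging continues past the modularity maximum so the full tree can be
    cut at any γ. A graph whose total weight is zero degenerates to
    ΔQ = 0 everywhere and merges purely by index order.
    """
    n = g.n_spots
    if g.n_edges == 0:
        return MergeTree(n_leaves=n, merges=[], method="greedy", steps=None)
    w = g.weight if g.weight is not None else np.ones(g.n_edges)
    m_tot = float(w.sum())

    between: dict = {i: {} for i in range(n)}
    wdeg = np.zeros(n)
    for (u, v), wi in zip(g.edges, w):
        between[int(u)][int(v)] = float(wi)
        between[int(v)][int(u)] = float(wi)
        wdeg[u] += wi
        wdeg[v] += wi
    deg = {i: float(wdeg[i]) for i in range(n)}

    def delta(a: int, b: int) -> float:
        if m_tot == 0:
            return 0.0
        e_ab = between[a].get(b, 0.0)
        # negated gain: the driver pops the smallest value first
        return -(e_ab / m_tot - deg[a] * deg[b] / (2.0 * m_tot**2))

    def merge(a: int, b: int, c: int) -> None:
        deg[c] = deg.pop(a) + deg.pop(b)
        acc: dict = {}
        for old in (a, b):
            for x, val in between.pop(old).items():
                if x in (a, b):
                    continue
                acc[x] = acc.get(x, 0.0) + val
        between[c] = acc
        for x, val in acc.items():
            bx = between[x]
            bx.pop(a, None)
            bx.pop(b, None)
            bx[c] = val

    merges = _heap_loop(n, _adjacency_sets(g), delta, merge)
    return MergeTree(n_leaves=n, merges=merges, method="greedy", steps=None)


# ---------------------------------------------------------------------------
# cutting and aggregation


def cut_tree(tree: MergeTree, gamma: float) -> MetaspotPartition:
    """Cut the merge tree at graining level γ (no re-clustering).

    The target metaspot count is max(n_components, round_half_up(n_leaves/γ));
    the merge list is replayed until that many communities remain. γ = 1 is
    the identity partition. A warning is logged when the connected-component
    count clamps the request.
    """
    if gamma < 1:
        raise ValueError(f"gamma must be at least 1, got {gamma}")
    n = tree.n_leaves
    target = round_half_up(n / gamma)
    if target < tree.n_components:
        logger.warning(
            "requested gamma=%s implies %d metaspots but the graph has %d "
            "connected components; clamping",
            gamma,
            target,
            tree.n_components,
        )
        target = tree.n_components
    n_merges = n - target
    parent: dict = {}
    for a, b, c in tree.merges[:n_merges]:
        parent[a] = c
        parent[b] = c
    roots = np.empty(n, dtype=np.int64)
    for leaf in range(n):
        r = leaf
        while r in parent:
            r = parent[r]
        roots[leaf] = r
    return MetaspotPartition.compact(roots, gamma_requested=gamma)


def _membership_indicator(p: MetaspotPartition) -> sp.csr_matrix:
    n = p.n_spots
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), p.membership)), shape=(n, p.n_metaspots)
    )


def aggregate(sm: SpotMatrix, p: MetaspotPartition) -> MetaspotMatrix:
    """Aggregate a SpotMatrix into metaspots.

    Metaspot counts are the elementwise sums of the members' raw counts
    (count conservation is integer-exact); centroids are the arithmetic
    means of member coordinates; `normalized` is the aggregated matrix
    re-normalized at the metaspot level.
    """
    if p.n_spots != sm.n_spots:
        raise ValueError(
            f"partition covers {p.n_spots} spots but matrix has {sm.n_spots}"
        )
    if p.membership.min() < 0 or p.membership.max() >= p.n_metaspots:
        raise ValueError("membership index out of range")
    S = _membership_indicator(p)
    counts = sp.csc_matrix(sm.counts @ S)
    counts = counts.astype(sm.counts.dtype)
    sizes = np.asarray(S.sum(axis=0)).ravel().astype(np.int64)
    centroids = (S.T @ sm.coords) / sizes[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty metaspots cannot occur here
        normalized = lognormalize(counts) if counts.sum() > 0 else None
    return MetaspotMatrix(
        counts=counts,
        centroids=centroids,
        sizes=sizes,
        normalized=normalized,
        spot_ids=sm.spot_ids,
    )


# ---------------------------------------------------------------------------
# persistence


def save_tree(tree: MergeTree, path) -> None:
    """Serialize a merge tree to JSON so later cuts skip re-clustering."""
    payload = {
        "n_leaves": tree.n_leaves,
        "method": tree.method,
        "steps": tree.steps,
        "merges": [[int(a), int(b), int(c)] for a, b, c in tree.merges],
    }
    Path(path).write_text(json.dumps(payload))


def load_tree(path) -> MergeTree:
    payload = json.loads(Path(path).read_text())
    return MergeTree(
        n_leaves=payload["n_leaves"],
        merges=[tuple(m) for m in payload["merges"]],
        method=payload["method"],
        steps=payload["steps"],
    )
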