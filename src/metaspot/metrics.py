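"""Metaspot quality metrics.

Covers annotation purity, chance-corrected partition agreement (ARI),
sparsity reduction (detected genes per unit, nonzero fraction), spatial
size/distance diagnostics, and the variability of per-spot cell-type
proportions within metaspots against a size-matched random-aggregation
null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist
from sklearn.metrics.cluster import pair_confusion_matrix

from .coarse_grain import MetaspotPartition

__all__ = [
    "purity",
    "adjusted_rand_index",
    "sparsity_report",
    "max_intra_distance",
    "proportion_variability",
    "PartitionReport",
    "partition_report",
]


def purity(p: MetaspotPartition, labels) -> np.ndarray:
    """Per-metaspot fraction of members carrying the modal label."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != p.n_spots:
        raise ValueError("labels must cover all spots")
    out = np.empty(p.n_metaspots)
    for m, members in enumerate(p.members()):
        _, counts = np.unique(labels[members].astype(str), return_counts=True)
        out[m] = counts.max() / len(members)
    return out


def _as_labels(p) -> np.ndarray:
    if isinstance(p, MetaspotPartition):
        return p.membership
    return np.asarray(p)


def adjusted_rand_index(p1, p2) -> float:
    """Adjusted Rand index between two partitions of the same spots.

    1 for identical partitions (up to relabeling); expectation 0 for
    independent random labelings. Degenerate inputs for which the
    chance-corrected denominator vanishes return 1 if the partitions
    agree on every pair and 0 (with a warning) otherwise.
    """
    a, b = _as_labels(p1), _as_labels(p2)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same spots")
    (tn, fp), (fn, tp) = pair_confusion_matrix(a, b).astype(float)
    denom = (tp + fn) * (fn + tn) + (tp + fp) * (fp + tn)
    if denom == 0:
        if fp == 0 and fn == 0:
            return 1.0
        warnings.warn("ARI undefined for these degenerate partitions; returning 0")
        return 0.0
    return 2.0 * (tp * tn - fn * fp) / denom


def sparsity_report(m) -> tuple[np.ndarray, float]:
    """Per-column detected (nonzero) gene counts and overall nonzero fraction."""
    m = sp.csc_matrix(m)
    rows, cols = m.shape
    if rows == 0 or cols == 0:
        raise ValueError("empty matrix")
    m.eliminate_zeros()
    detected = np.diff(m.indptr)
    return detected, m.nnz / (rows * cols)


def max_intra_distance(p: MetaspotPartition, coords) -> np.ndarray:
    """Maximum pairwise Euclidean distance among each metaspot's members.

    Singletons score 0.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) != p.n_spots:
        raise ValueError("coords must cover all spots")
    out = np.zeros(p.n_metaspots)
    for m, members in enumerate(p.members()):
        if len(members) > 1:
            out[m] = pdist(coords[members]).max()
    return out


def _proportion_stat(props: np.ndarray, sizes: np.ndarray, order: np.ndarray) -> float:
    """Size-weighted mean over groups (size ≥ 2) of the mean-over-celltypes
    sample SD of member proportion vectors. `order` lists spot indices
    grouped consecutively into blocks of the given sizes."""
    total_w = 0.0
    acc = 0.0
    start = 0
    for s in sizes:
        block = order[start : start + s]
        start += s
        if s < 2:
            continue
        sd = props[block].std(axis=0, ddof=1)
        acc += s * sd.mean()
        total_w += s
    if total_w == 0:
        raise ValueError(
            "all metaspots are singletons; proportion variability undefined"
        )
    return acc / total_w


def proportion_variability(
    props, p: MetaspotPartition, n_random: int = 100, seed: int = 0
) -> tuple[float, float, float]:
    """Within-metaspot variability of cell-type proportions vs a random null.

    observed: size-weighted mean, over metaspots with ≥ 2 members, of the
    per-celltype sample standard deviation of the members' proportion
    vectors, averaged over cell types. The null repeats the statistic on
    `n_random` random partitions preserving the metaspot size multiset.
    Returns (observed, null_mean, null_sd); deterministic given seed.
    """
    props = np.asarray(props, dtype=float)
    if props.shape[0] != p.n_spots:
        raise ValueError("proportions must have one row per spot")
    if np.abs(props.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("proportion rows must sum to 1")
    sizes = np.asarray([len(m) for m in p.members()])
    if (sizes < 2).all():
        raise ValueError(
            "all metaspots are singletons; proportion variability undefined"
        )
    order = np.argsort(p.membership, kind="stable")
    observed = _proportion_stat(props, sizes, order)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for r in range(n_random):
        null[r] = _proportion_stat(props, sizes, rng.permutation(p.n_spots))
    return observed, float(null.mean()), float(null.std(ddof=1))


@dataclass
class PartitionReport:
    """Per-metaspot diagnostics plus matrix-level sparsity summaries."""

    purity: np.ndarray | None
    sizes: np.ndarray
    singleton_count: int
    max_intra_distance: np.ndarray
    detected_genes: np.ndarray
    nonzero_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_metaspots": int(len(self.sizes)),
            "singleton_count": int(self.singleton_count),
            "mean_purity": None
            if self.purity is None
            else float(np.mean(self.purity)),
            "mean_size": float(np.mean(self.sizes)),
            "mean_max_intra_distance": float(np.mean(self.max_intra_distance)),
            "mean_detected_genes": float(np.mean(self.detected_genes)),
            "nonzero_fraction": float(self.nonzero_fraction),
        }


def partition_report(
    p: MetaspotPartition, coords, counts, labels=None
) -> PartitionReport:
    """Assemble the standard diagnostics for one metaspot partition.

    `counts` is the aggregated genes × metaspots matrix (its sparsity shows
    the reduction relative to the spot-level matrix).
    """
    sizes = np.asarray([len(m) for m in p.members()])
    detected, nnz_frac = sparsity_report(counts)
    return PartitionReport(
        purity=None if labels is None else purity(p, labels),
        sizes=sizes,
        singleton_count=int((sizes == 1).sum()),
        max_intra_distance=max_intra_distance(p, coords),
        detected_genes=detected,
        nonzero_fraction=nnz_frac,
    )
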