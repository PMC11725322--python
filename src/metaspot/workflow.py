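"""End-to-end convenience wrapper: counts + coordinates → metaspots.

Wires the stages in their canonical order — drop zero-count spots,
log-normalize, PCA, spatial KNN, long-edge pruning, transcriptomic
weighting, agglomeration — and exposes the merge tree so further γ values
are a cheap re-cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import metrics, refine
from .coarse_grain import (
    MergeTree,
    MetaspotMatrix,
    MetaspotPartition,
    aggregate,
    cut_tree,
    greedy_tree,
    walktrap_tree,
    DEFAULT_STEPS,
)
from .metaspot_graph import (
    SpatialGraph,
    platform_defaults,
    prune_long_edges,
    spatial_knn,
    weight_edges,
)
from .preprocess import DEFAULT_N_PCS, drop_zero_spots, lognormalize, pca_embed
from .spatial_io import SpotMatrix

__all__ = ["MetaspotResult", "build_graph", "build_metaspots"]


@dataclass
class MetaspotResult:
    """Everything one coarse-graining run produces."""

    sm: SpotMatrix  # input after zero-count spot removal
    graph: SpatialGraph
    tree: MergeTree
    partition: MetaspotPartition
    msm: MetaspotMatrix
    dropped_spots: list

    def recut(self, gamma: float) -> "MetaspotResult":
        """Cut the existing tree at a new γ without re-clustering."""
        partition = cut_tree(self.tree, gamma)
        msm = aggregate(self.sm, partition)
        if self.sm.annotation is not None:
            msm.purity = metrics.purity(partition, self.sm.annotation)
        return MetaspotResult(
            sm=self.sm,
            graph=self.graph,
            tree=self.tree,
            partition=partition,
            msm=msm,
            dropped_spots=self.dropped_spots,
        )

    def split(self, labels=None, graph: Optional[SpatialGraph] = None) -> "MetaspotResult":
        """Annotation-purity split followed by the connectivity split."""
        labels = labels if labels is not None else self.sm.annotation
        if labels is None:
            raise ValueError("splitting requires a per-spot annotation")
        p = refine.split_by_annotation(self.partition, labels)
        p = refine.split_disconnected(p, graph if graph is not None else self.graph)
        msm = aggregate(self.sm, p)
        msm.purity = metrics.purity(p, labels)
        return MetaspotResult(
            sm=self.sm,
            graph=self.graph,
            tree=self.tree,
            partition=p,
            msm=msm,
            dropped_spots=self.dropped_spots,
        )


def build_graph(
    sm: SpotMatrix,
    k: Optional[int] = None,
    f_prune: Optional[float] = None,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
) -> SpatialGraph:
    """Weighted spatial graph for a SpotMatrix (platform presets by default)."""
    preset_k, preset_f = platform_defaults(sm.platform)
    k = preset_k if k is None else k
    f_prune = preset_f if f_prune is None else f_prune
    norm = lognormalize(sm)
    emb = pca_embed(norm, n_pcs=min(n_pcs, min(norm.shape) - 1), seed=seed)
    g = spatial_knn(sm.coords, k=k)
    g = prune_long_edges(g, f=f_prune)
    return weight_edges(g, emb)


def build_metaspots(
    sm: SpotMatrix,
    gamma: float,
    k: Optional[int] = None,
    f_prune: Optional[float] = None,
    n_pcs: int = DEFAULT_N_PCS,
    method: str = "walktrap",
    steps: int = DEFAULT_STEPS,
    seed: int = 0,
) -> MetaspotResult:
    """Full pipeline at graining level γ.

    Zero-count spots are removed first (they cannot be normalized); their
    IDs are reported in the result.
    """
    sm, dropped = drop_zero_spots(sm)
    g = build_graph(sm, k=k, f_prune=f_prune, n_pcs=n_pcs, seed=seed)
    if method == "walktrap":
        tree = walktrap_tree(g, steps=steps)
    elif method == "greedy":
        tree = greedy_tree(g)
    else:
        raise ValueError(f"unknown method {method!r}")
    partition = cut_tree(tree, gamma)
    msm = aggregate(sm, partition)
    if sm.annotation is not None:
        msm.purity = metrics.purity(partition, sm.annotation)
    return MetaspotResult(
        sm=sm,
        graph=g,
        tree=tree,
        partition=partition,
        msm=msm,
        dropped_spots=dropped,
    )
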