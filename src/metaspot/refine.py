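"""Split metaspots to guarantee annotation purity and spatial coherence.

When a per-spot categorical annotation (cell types, niches, layers) is
available, metaspots mixing categories are first split so each piece
carries a single label, and the pieces are then split again wherever they
form disconnected components of the spatial KNN graph. Both steps only
refine the partition, so the effective graining level γ = n_spots /
n_metaspots can only decrease.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .coarse_grain import MetaspotPartition
from .metaspot_graph import SpatialGraph
from .spatial_io import normalize_annotation

__all__ = ["split_by_annotation", "split_disconnected", "effective_gamma"]


def split_by_annotation(p: MetaspotPartition, labels) -> MetaspotPartition:
    """Split each metaspot by annotation category.

    Every output metaspot contains exactly one label category; already-pure
    metaspots are unchanged (up to index recompaction). Missing labels are
    treated as the reserved "Unknown" category, which is split away from
    annotated neighbors like any other category.
    """
    labels = normalize_annotation(labels, p.n_spots)
    keys = [(int(m), labels[i]) for i, m in enumerate(p.membership)]
    return MetaspotPartition.compact(keys, gamma_requested=p.gamma_requested)


def split_disconnected(p: MetaspotPartition, g: SpatialGraph) -> MetaspotPartition:
    """Split metaspots that are disconnected in the spatial graph.

    Each output metaspot induces a connected subgraph of g; connected
    metaspots pass through unchanged. Connectivity is topological: edges
    count regardless of their transcriptomic weight.
    """
    if g.n_spots != p.n_spots:
        raise ValueError(
            f"graph has {g.n_spots} nodes but partition covers {p.n_spots} spots"
        )
    adj = g.adjacency(weighted=False)
    keys = np.empty(p.n_spots, dtype=object)
    for m, members in enumerate(p.members()):
        if len(members) == 1:
            keys[members[0]] = (m, 0)
            continue
        sub = adj[members][:, members]
        _, comp = connected_components(sub, directed=False)
        for local, spot in enumerate(members):
            keys[spot] = (m, int(comp[local]))
    return MetaspotPartition.compact(keys, gamma_requested=p.gamma_requested)


def effective_gamma(p: MetaspotPartition) -> float:
    """Graining level n_spots / n_metaspots at full precision.

    Summaries report it rounded to 2 decimals.
    """
    return p.n_spots / p.n_metaspots
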