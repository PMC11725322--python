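"""Count normalization and PCA embedding for transcriptomic distances.

Edge weights in the spatial graph are derived from Euclidean distances in
the top principal components of the log-normalized count matrix. All genes
are used by default (centered per gene, no unit-variance scaling); an
optional highly-variable-gene cutoff is available for parity experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .spatial_io import MAX_DENSE_ENTRIES, SpotMatrix

__all__ = ["Embedding", "lognormalize", "pca_embed", "drop_zero_spots"]

DEFAULT_N_PCS = 30
DEFAULT_SCALE_TOTAL = 1e4

#: Below this min-dimension the exact (full SVD) solver is used.
EXACT_SOLVER_MAX_DIM = 500


@dataclass
class Embedding:
    """Spots × n_pcs principal-component scores."""

    matrix: np.ndarray
    n_pcs: int
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.matrix.shape[1] != self.n_pcs:
            raise ValueError("embedding width does not match n_pcs")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained_variance must be non-increasing")


def lognormalize(sm, scale_total: float = DEFAULT_SCALE_TOTAL) -> sp.csc_matrix:
    """Library-size normalize to `scale_total` counts per spot, then log1p.

    Accepts a SpotMatrix or a raw genes × spots sparse/dense matrix. Spots
    with zero total counts cannot be normalized: they are excluded with a
    warning (callers that need aligned shapes should run drop_zero_spots
    first). Zeros stay zero, so sparsity is preserved.
    """
    counts = sm.counts if isinstance(sm, SpotMatrix) else sm
    counts = sp.csc_matrix(counts, dtype=float)
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        ids = (
            list(sm.spot_ids[zero])
            if isinstance(sm, SpotMatrix)
            else list(np.flatnonzero(zero))
        )
        warnings.warn(
            f"excluding {int(zero.sum())} spot(s) with zero total counts: "
            f"{ids[:5]}{'...' if len(ids) > 5 else ''}"
        )
        counts = counts[:, ~zero]
        totals = totals[~zero]
    out = counts.multiply(scale_total / totals).tocsc()
    out.data = np.log1p(out.data)
    return out


def drop_zero_spots(sm: SpotMatrix):
    """Remove spots with zero library size; return (subset, dropped_ids)."""
    totals = np.asarray(sm.counts.sum(axis=0)).ravel()
    keep = totals > 0
    dropped = list(sm.spot_ids[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-count spot(s)")
        sm = sm.subset_spots(np.flatnonzero(keep))
    return sm, dropped


def pca_embed(
    norm,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
    n_hvg: int | None = None,
) -> Embedding:
    """Top-`n_pcs` PCA scores of a genes × spots normalized matrix.

    Genes are centered inside the operation (no unit-variance scaling).
    The exact SVD solver is used when the smaller matrix dimension is at
    most 500; otherwise the seeded randomized solver. Deterministic given
    the seed.

    Parameters
    ----------
    n_hvg
        Optional number of highly variable genes (by per-gene variance of
        the normalized values) to restrict to before PCA. Default: all genes.
    """
    X = norm.T  # spots × genes
    if sp.issparse(X):
        if X.shape[0] * X.shape[1] > MAX_DENSE_ENTRIES:
            raise ValueError(
                f"refusing to densify a {X.shape} matrix "
                f"(> {MAX_DENSE_ENTRIES:.0e} entries)"
            )
        X = np.asarray(X.todense())
    else:
        X = np.asarray(X, dtype=float)
    if n_hvg is not None and n_hvg < X.shape[1]:
        var = X.var(axis=0)
        order = np.argsort(-var, kind="stable")[:n_hvg]
        X = X[:, np.sort(order)]
    max_pcs = min(X.shape) - 1
    if n_pcs > max_pcs:
        raise ValueError(
            f"n_pcs={n_pcs} too large; admissible maximum is {max_pcs} "
            f"for a {X.shape[0]} × {X.shape[1]} matrix"
        )
    solver = "full" if min(X.shape) <= EXACT_SOLVER_MAX_DIM else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(X)
    return Embedding(
        matrix=scores,
        n_pcs=n_pcs,
        explained_variance=pca.explained_variance_,
    )
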