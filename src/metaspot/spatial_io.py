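"""Read and write spot-level and metaspot-level spatial transcriptomics data.

Input conventions follow the 10x Space Ranger layout (Matrix Market counts +
features/barcodes tables + tissue positions CSV) and generic delimited
tables for imaging-based platforms. Metaspot results are written back as a
small directory of plain-text files (Matrix Market counts, centroid CSV,
membership TSV, run-summary JSON).
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "SpotMatrix",
    "UNKNOWN_LABEL",
    "normalize_annotation",
    "read_10x_dir",
    "read_tables",
    "write_10x_dir",
    "write_metaspot_dir",
    "read_metaspot_dir",
]

#: Reserved category for unannotated spots.
UNKNOWN_LABEL = "Unknown"

#: Densifying a sparse matrix with more entries than this is refused.
MAX_DENSE_ENTRIES = 10**8

PLATFORMS = ("visium", "visiumhd", "imaging", "generic")


def normalize_annotation(labels: Sequence, n_spots: int) -> np.ndarray:
    """Coerce per-spot labels to strings, mapping missing values to "Unknown".

    Missing means None, NaN, or empty string. The reserved category is an
    ordinary category afterwards (purity splitting treats it like any other).
    """
    arr = np.asarray(labels, dtype=object)
    if arr.shape != (n_spots,):
        raise ValueError(
            f"annotation has shape {arr.shape}, expected ({n_spots},)"
        )
    out = np.empty(n_spots, dtype=object)
    for i, v in enumerate(arr):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            out[i] = UNKNOWN_LABEL
        else:
            out[i] = str(v)
    return out


@dataclass
class SpotMatrix:
    """Gene × spot raw counts with 2-D spatial coordinates.

    The atomic unit of input: one column per spot (Visium spot, VisiumHD bin
    or segmented cell), one row per gene. Coordinates are in a single length
    unit throughout (full-resolution pixels or µm).
    """

    counts: sp.csc_matrix  # genes × spots, non-negative integers
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: np.ndarray  # spots × 2
    annotation: Optional[np.ndarray] = None
    platform: str = "generic"

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.spot_ids) != n_spots:
            raise ValueError("spot_ids length does not match counts columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.spot_ids)) != n_spots:
            raise ValueError("spot_ids must be unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n_spots, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({n_spots}, 2)"
            )
        if np.isnan(self.coords).any():
            raise ValueError("coords contain NaN")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"platform {self.platform!r} not one of {PLATFORMS}"
            )
        if self.annotation is not None:
            self.annotation = normalize_annotation(self.annotation, n_spots)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, idx: np.ndarray) -> "SpotMatrix":
        """Return a new SpotMatrix restricted to the given spot indices."""
        idx = np.asarray(idx)
        return SpotMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            spot_ids=self.spot_ids[idx],
            coords=self.coords[idx],
            annotation=None if self.annotation is None else self.annotation[idx],
            platform=self.platform,
        )


def _find_file(path: Path, stem: str) -> Path:
    """Locate `stem` or `stem`.gz inside `path`; raise naming the file."""
    for cand in (path / stem, path / (stem + ".gz")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"required file {stem}[.gz] not found in {path}")


def _read_tsv_column(fn: Path, column: int = 0) -> np.ndarray:
    opener = gzip.open if fn.suffix == ".gz" else open
    with opener(fn, "rt") as fh:
        vals = [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]
    return np.asarray(vals, dtype=object)


def read_10x_dir(
    path, annotation: Optional[pd.Series] = None, in_tissue_only: bool = False
) -> SpotMatrix:
    """Read a 10x-style directory into a SpotMatrix.

    Expects matrix.mtx(.gz), features.tsv(.gz), barcodes.tsv(.gz) and
    tissue_positions.csv(.gz) with header columns (barcode, in_tissue,
    array_row, array_col, pxl_row_in_fullres, pxl_col_in_fullres). Spots are
    returned in positions-file order, restricted to barcodes present in both
    the matrix and the positions file; coordinates are taken from the
    full-resolution pixel columns as (x, y) = (pxl_col, pxl_row).

    Parameters
    ----------
    annotation
        Optional per-barcode labels (index = barcode) attached after matching.
    in_tissue_only
        If True, drop positions rows with in_tissue == 0 before matching.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"input directory not found: {path}")
    mtx_fn = _find_file(path, "matrix.mtx")
    feat_fn = _find_file(path, "features.tsv")
    bc_fn = _find_file(path, "barcodes.tsv")
    pos_fn = _find_file(path, "tissue_positions.csv")

    try:
        counts = sp.csc_matrix(mmread(mtx_fn))
    except Exception as exc:
        raise ValueError(f"could not parse matrix file {mtx_fn}: {exc}") from exc
    gene_ids = _read_tsv_column(feat_fn)
    barcodes = _read_tsv_column(bc_fn)
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match features "
            f"({len(gene_ids)}) × barcodes ({len(barcodes)})"
        )

    pos = pd.read_csv(pos_fn)
    required = {"barcode", "pxl_row_in_fullres", "pxl_col_in_fullres"}
    missing = required - set(pos.columns)
    if missing:
        raise ValueError(f"{pos_fn} lacks columns {sorted(missing)}")
    if in_tissue_only and "in_tissue" in pos.columns:
        pos = pos[pos["in_tissue"] == 1]

    bc_index = {b: i for i, b in enumerate(barcodes)}
    keep = pos["barcode"].isin(bc_index).to_numpy()
    matched = pos[keep]
    if len(matched) == 0:
        raise ValueError(
            f"no barcodes shared between {mtx_fn.name} and {pos_fn.name}"
        )
    n_unmatched = (len(pos) - len(matched)) + (len(barcodes) - len(matched))
    if n_unmatched > 0:
        warnings.warn(
            f"dropped {n_unmatched} barcodes absent from either the matrix "
            "or the positions file"
        )
    col_idx = np.asarray([bc_index[b] for b in matched["barcode"]], dtype=int)
    coords = matched[["pxl_col_in_fullres", "pxl_row_in_fullres"]].to_numpy(float)

    ann = None
    if annotation is not None:
        ann = annotation.reindex(matched["barcode"]).to_numpy(dtype=object)

    platform = "visium"
    summary_fn = path / "platform.json"
    if summary_fn.exists():
        platform = json.loads(summary_fn.read_text()).get("platform", "visium")

    return SpotMatrix(
        counts=counts[:, col_idx],
        gene_ids=gene_ids,
        spot_ids=matched["barcode"].to_numpy(dtype=object),
        coords=coords,
        annotation=ann,
        platform=platform,
    )


def read_tables(
    counts_path,
    coords_path,
    annotation_col: Optional[str] = None,
    platform: str = "generic",
    sep: Optional[str] = None,
) -> SpotMatrix:
    """Read a genes × spots counts table plus a spot/x/y coordinate table.

    The counts table header holds spot IDs and the first column gene IDs.
    The coordinate table's first column holds spot IDs and must contain
    numeric columns "x" and "y" (or the 2nd/3rd columns positionally).
    Spots are ordered as in the coordinate table.
    """
    counts_path, coords_path = Path(counts_path), Path(coords_path)
    for fn in (counts_path, coords_path):
        if not fn.exists():
            raise FileNotFoundError(f"input file not found: {fn}")
    counts_df = pd.read_csv(counts_path, sep=sep, index_col=0, engine="python")
    coords_df = pd.read_csv(coords_path, sep=sep, index_col=0, engine="python")

    missing = [s for s in coords_df.index if s not in counts_df.columns]
    if missing:
        raise ValueError(
            f"spot IDs in coordinates absent from counts table: {missing[:5]}"
        )
    if {"x", "y"}.issubset(coords_df.columns):
        xy = coords_df[["x", "y"]]
    else:
        xy = coords_df.iloc[:, :2]
    try:
        coords = xy.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric coordinates in {coords_path}: {exc}") from exc
    if np.isnan(coords).any():
        raise ValueError(f"non-numeric or missing coordinates in {coords_path}")

    counts = counts_df[list(coords_df.index)]
    ann = None
    if annotation_col is not None:
        if annotation_col not in coords_df.columns:
            raise ValueError(
                f"annotation column {annotation_col!r} not in {coords_path}"
            )
        ann = coords_df[annotation_col].to_numpy(dtype=object)
    return SpotMatrix(
        counts=sp.csc_matrix(counts.to_numpy()),
        gene_ids=counts_df.index.to_numpy(dtype=object),
        spot_ids=coords_df.index.to_numpy(dtype=object),
        coords=coords,
        annotation=ann,
        platform=platform,
    )


def write_10x_dir(sm: SpotMatrix, path) -> None:
    """Write a SpotMatrix as a 10x-style directory (inverse of read_10x_dir).

    Coordinates are stored in the full-resolution pixel columns; array
    row/col are filled with -1 placeholders for non-lattice platforms.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "matrix.mtx", sp.coo_matrix(_as_integer(sm.counts)))
    (path / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in sm.gene_ids)
    )
    (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in sm.spot_ids))
    pos = pd.DataFrame(
        {
            "barcode": sm.spot_ids,
            "in_tissue": 1,
            "array_row": -1,
            "array_col": -1,
            "pxl_row_in_fullres": sm.coords[:, 1],
            "pxl_col_in_fullres": sm.coords[:, 0],
        }
    )
    pos.to_csv(path / "tissue_positions.csv", index=False)
    (path / "platform.json").write_text(json.dumps({"platform": sm.platform}))
    if sm.annotation is not None:
        pd.DataFrame({"barcode": sm.spot_ids, "label": sm.annotation}).to_csv(
            path / "labels.csv", index=False
        )


def _as_integer(m: sp.spmatrix) -> sp.spmatrix:
    """Cast to int64 when all stored values are integral (mmwrite round-trip)."""
    if m.nnz == 0 or np.all(np.mod(m.data, 1) == 0):
        return m.astype(np.int64)
    return m


def write_metaspot_dir(msm, partition, path, params: Optional[dict] = None) -> None:
    """Write a metaspot result directory.

    Emits aggregated counts (Matrix Market), centroids/sizes/purity CSV,
    spot → metaspot membership TSV, and a run-summary JSON with the
    parameters plus requested and effective γ.
    """
    from .coarse_grain import MetaspotMatrix, MetaspotPartition  # local to avoid cycle

    assert isinstance(msm, MetaspotMatrix) and isinstance(partition, MetaspotPartition)
    if partition.n_metaspots == 0 or len(partition.membership) == 0:
        raise ValueError("empty partition: nothing to write")
    if msm.counts.shape[1] != partition.n_metaspots:
        raise ValueError("metaspot matrix and partition disagree on metaspot count")
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {path}: {exc}") from exc

    mmwrite(path / "metaspot_matrix.mtx", sp.coo_matrix(_as_integer(msm.counts)))
    meta = pd.DataFrame(
        {
            "metaspot": np.arange(partition.n_metaspots),
            "x": msm.centroids[:, 0],
            "y": msm.centroids[:, 1],
            "size": msm.sizes,
        }
    )
    if msm.purity is not None:
        meta["purity"] = msm.purity
    # 18 significant digits: float64 round-trips bit-exactly
    meta.to_csv(path / "metaspots.csv", index=False, float_format="%.17e")

    spot_ids = (
        msm.spot_ids
        if msm.spot_ids is not None
        else np.arange(len(partition.membership)).astype(object)
    )
    with open(path / "membership.tsv", "w") as fh:
        fh.write("spot\tmetaspot\n")
        for s, m in zip(spot_ids, partition.membership):
            fh.write(f"{s}\t{m}\n")

    summary = {
        "n_spots": int(len(partition.membership)),
        "n_metaspots": int(partition.n_metaspots),
        "gamma_requested": float(partition.gamma_requested),
        "gamma_effective": float(partition.gamma_effective),
        "parameters": params or {},
    }
    (path / "summary.json").write_text(json.dumps(summary, indent=2))


def read_metaspot_dir(path):
    """Re-read a directory written by write_metaspot_dir.

    Returns (MetaspotMatrix, MetaspotPartition, summary dict).
    """
    from .coarse_grain import MetaspotMatrix, MetaspotPartition

    path = Path(path)
    counts = sp.csc_matrix(mmread(path / "metaspot_matrix.mtx"))
    meta = pd.read_csv(path / "metaspots.csv", float_precision="round_trip")
    membership_df = pd.read_csv(path / "membership.tsv", sep="\t")
    summary = json.loads((path / "summary.json").read_text())
    partition = MetaspotPartition(
        membership=membership_df["metaspot"].to_numpy(int),
        gamma_requested=summary["gamma_requested"],
    )
    msm = MetaspotMatrix(
        counts=counts,
        centroids=meta[["x", "y"]].to_numpy(float),
        sizes=meta["size"].to_numpy(int),
        purity=meta["purity"].to_numpy(float) if "purity" in meta else None,
        spot_ids=membership_df["spot"].to_numpy(dtype=object),
    )
    return msm, partition, summary
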