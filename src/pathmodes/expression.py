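"""Count-matrix ingestion, log-normalization and activity-matrix I/O.

Counts are held genes x cells (sparse-friendly).  Normalization follows the
common single-cell convention: per-cell depth scaling to a fixed factor
(default 10,000) followed by log1p, i.e.

    value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor)

Supported inputs are 10x-style MatrixMarket triplet directories
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``,
optionally gzipped) and dense delimited text with gene rows.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .modes import ActivityMatrix

LAYER_RAW = "raw_counts"
LAYER_LOGNORM = "lognorm"

DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with identifier lists.

    ``layer`` records whether the values are raw counts or log-normalized.
    """

    values: sparse.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = LAYER_RAW

    def __post_init__(self) -> None:
        if self.layer not in (LAYER_RAW, LAYER_LOGNORM):
            raise ValueError(f"unknown layer {self.layer!r}")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {shape} inconsistent with {len(self.gene_ids)} "
                f"genes x {len(self.cell_ids)} cells"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label} identifiers")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense_submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Dense (genes x cells) block for the requested genes, in order."""
        idx = [self._gene_index[g] for g in genes]
        if sparse.issparse(self.values):
            return np.asarray(self.values.tocsr()[idx].todense(), dtype=float)
        return np.asarray(self.values[idx], dtype=float)

    def to_dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


def _make_unique(ids: Sequence[str]) -> list[str]:
    """Disambiguate duplicate symbols by suffixing ``-1``, ``-2``, ..."""
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}-{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def _find_triplet_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def _read_id_column(path: Path, column: int | None = None) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if column is None:
        # 10x features files carry (id, symbol, type); prefer the symbol
        column = 1 if rows and len(rows[0]) >= 2 else 0
    return [r[column] for r in rows]


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Load raw counts from a triplet directory or dense delimited text.

    Orientation is normalized to genes x cells; duplicate gene symbols are
    made unique by suffixing.
    """
    path = Path(path)
    if path.is_dir():
        mtx_path = _find_triplet_file(path, ["matrix.mtx"])
        features_path = _find_triplet_file(path, ["features.tsv", "genes.tsv"])
        barcodes_path = _find_triplet_file(path, ["barcodes.tsv"])
        opener = gzip.open if mtx_path.suffix == ".gz" else open
        with opener(mtx_path, "rb") as fh:
            mat = spio.mmread(fh).tocsr()
        genes = _read_id_column(features_path)
        cells = _read_id_column(barcodes_path, column=0)
        if mat.shape == (len(genes), len(cells)):
            pass
        elif mat.shape == (len(cells), len(genes)):
            mat = mat.T.tocsr()
        else:
            raise ValueError(
                f"{mtx_path}: matrix shape {mat.shape} matches neither "
                f"{len(genes)} features x {len(cells)} barcodes nor its transpose"
            )
        return ExpressionMatrix(
            values=mat, gene_ids=_make_unique(genes), cell_ids=list(cells)
        )
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=_make_unique([str(g) for g in df.index]),
        cell_ids=[str(c) for c in df.columns],
    )


def lognormalize(
    m: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionMatrix:
    """Depth-normalize to ``scale_factor`` per cell, then log1p.

    Cells with zero total counts cannot be normalized and are rejected with
    their barcodes listed.  Applying the transform twice is refused.
    """
    if m.layer != LAYER_RAW:
        raise ValueError("lognormalize expects raw counts (layer='raw_counts')")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if sparse.issparse(m.values):
        totals = np.asarray(m.values.sum(axis=0)).ravel()
    else:
        totals = np.asarray(m.values).sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [m.cell_ids[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} cell(s) with zero total counts cannot be "
            f"log-normalized: {bad}{'...' if zero.size > 10 else ''}"
        )
    factors = scale_factor / totals
    if sparse.issparse(m.values):
        out = m.values.tocsc().astype(float)
        out.data = out.data * np.repeat(factors, np.diff(out.indptr))
        out.data = np.log1p(out.data)
        out = out.tocsr()
    else:
        out = np.log1p(np.asarray(m.values, dtype=float) * factors[None, :])
    return ExpressionMatrix(
        values=out,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        layer=LAYER_LOGNORM,
    )


def write_activity(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write an activity matrix as a TSV (modes as rows, cells as columns).

    Values round-trip to at least 6 significant digits.
    """
    if matrix.n_modes == 0:
        warnings.warn("writing an empty activity matrix (0 modes)", stacklevel=2)
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.10g", index_label="mode")


def read_activity(path: str | Path) -> ActivityMatrix:
    """Read an activity matrix written by :func:`write_activity`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ActivityMatrix(
        values=df.to_numpy(dtype=float),
        mode_names=[str(i) for i in df.index],
        cell_ids=[str(c) for c in df.columns],
    )


def read_cell_metadata(path: str | Path, cell_id_col: str | None = None) -> pd.DataFrame:
    """Read a per-cell annotation table keyed by barcode.

    The barcode column is the first column unless ``cell_id_col`` names one.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if cell_id_col is None:
        cell_id_col = df.columns[0]
    if cell_id_col not in df.columns:
        raise ValueError(f"{path}: missing cell id column {cell_id_col!r}")
    if df[cell_id_col].duplicated().any():
        raise ValueError(f"{path}: duplicate cell identifiers")
    return df.set_index(cell_id_col)
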