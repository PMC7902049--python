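"""Core data types and readers/writers for the tab-separated file dialect.

The on-disk dialect follows the DREAM single-cell spatial-reconstruction
challenge files: an expression matrix with genes as rows and cells as
columns (``dge_raw.txt`` / ``dge_normalized.txt``), a binary in-situ atlas
with spatial bins as rows and atlas genes as columns, and a coordinates
table with one (x, y, z) row per bin.  Bin indices are 0-based in memory
and 1-based in every file (the source data originated from 1-based
tooling); all output headers say so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spatialsel")

N_PREDICTED_BINS = 10  # locations reported per cell

_COORD_SYNONYMS = {
    "x": {"x", "xcoord", "x_coord", "xcoordinate"},
    "y": {"y", "ycoord", "y_coord", "ycoordinate"},
    "z": {"z", "zcoord", "z_coord", "zcoordinate"},
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SpatialBinAtlas:
    """Binary in-situ reference: which atlas gene is 'on' in which spatial bin.

    Parameters
    ----------
    gene_names
        Unique atlas ("in-situ") gene names, one per column of ``insitu``.
    insitu
        Binary array of shape (n_bins, n_genes); row order is file order.
    coords
        Real (x, y, z) coordinates per bin, shape (n_bins, 3).
    """

    gene_names: list[str]
    insitu: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.insitu = np.asarray(self.insitu)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DataError("atlas gene names are not unique")
        if not np.isin(self.insitu, (0, 1)).all():
            raise DataError("atlas contains non-binary values")
        self.insitu = self.insitu.astype(np.int8)
        if self.coords.shape != (self.insitu.shape[0], 3):
            raise DataError(
                f"coordinate rows ({self.coords.shape[0]}) do not match "
                f"atlas bins ({self.insitu.shape[0]})"
            )
        if not np.isfinite(self.coords).all():
            raise DataError("non-finite bin coordinates")

    @property
    def n_bins(self) -> int:
        return self.insitu.shape[0]

    @property
    def bin_ids(self) -> np.ndarray:
        """0-based bin identifiers in file row order."""
        return np.arange(self.n_bins)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise DataError(f"genes absent from atlas: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix (raw counts or normalized values)."""

    gene_names: list[str]
    cell_names: list[str]
    values: np.ndarray  # (n_genes, n_cells)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise DataError("duplicate gene names in expression matrix")
        if len(set(self.cell_names)) != len(self.cell_names):
            raise DataError("duplicate cell names in expression matrix")
        if self.values.shape != (len(self.gene_names), len(self.cell_names)):
            raise DataError("expression shape does not match names")
        if np.isnan(self.values).any():
            raise DataError("missing values in expression matrix")
        if (self.values < 0).any():
            raise DataError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise DataError(f"genes absent from expression matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.cell_names), self.values[idx])

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_names)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise DataError(f"cells absent from expression matrix: {missing}")
        idx = np.array([pos[c] for c in cells], dtype=int)
        return ExpressionMatrix(list(self.gene_names), list(cells), self.values[:, idx])


@dataclass
class GeneList:
    """Ordered selection of genes with the requested target size N."""

    genes: list[str]
    target_size: int

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise DataError("target_size must be positive")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("gene list contains duplicates")
        if len(self.genes) > self.target_size:
            raise DataError("gene list longer than target size")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class FeatureRanking:
    """Per-gene selection statistics and the final ordered top-N list.

    ``stability`` counts the models (or folds) selecting each gene;
    ``score`` is the method's magnitude statistic (mean |coefficient| for
    the lasso route, mean VIP for the network route); ``ranksum`` combines
    the two ranks where applicable.
    """

    genes: list[str]                 # final ordered selection, best first
    target_size: int
    stability: dict[str, float] = field(default_factory=dict)
    score: dict[str, float] = field(default_factory=dict)
    ranksum: dict[str, float] = field(default_factory=dict)

    def as_gene_list(self) -> GeneList:
        return GeneList(list(self.genes), self.target_size)


@dataclass
class LocationPredictions:
    """Per cell, the 10 predicted bins ordered by descending MCC."""

    cell_names: list[str]
    bin_indices: np.ndarray  # (n_cells, 10), 0-based
    coords: np.ndarray       # (n_cells, 10, 3)

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.cell_names)
        if self.bin_indices.shape != (n, N_PREDICTED_BINS):
            raise DataError(
                f"each cell needs exactly {N_PREDICTED_BINS} predicted bins, "
                f"got shape {self.bin_indices.shape}"
            )
        if self.coords.shape != (n, N_PREDICTED_BINS, 3):
            raise DataError("prediction coordinates shape mismatch")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate row names")
    if df.columns.has_duplicates:
        raise DataError(f"{path}: duplicate column names")
    if df.isna().any().any():
        raise DataError(f"{path}: missing values")
    return df


def _read_coords(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    # drop an index-like unnamed first column if present
    if df.columns[0].lower().startswith("unnamed"):
        df = df.iloc[:, 1:]
    mapping = {}
    for canonical, synonyms in _COORD_SYNONYMS.items():
        hits = [c for c in df.columns if c.strip().lower() in synonyms]
        if len(hits) != 1:
            raise DataError(
                f"{path}: expected exactly one column for '{canonical}', "
                f"found {hits or 'none'}"
            )
        mapping[canonical] = hits[0]
    logger.info("coordinate column mapping: %s", mapping)
    coords = df[[mapping["x"], mapping["y"], mapping["z"]]].to_numpy(dtype=float)
    return coords


def load_dataset(
    expr_path: str | Path, atlas_path: str | Path, coords_path: str | Path
) -> tuple[ExpressionMatrix, SpatialBinAtlas]:
    """Load expression (genes x cells), binary atlas (bins x genes) and bin
    coordinates; the three files must agree on dimensions.

    Bin order is file row order and is never changed: bin ``k`` of the atlas
    always maps to coordinate row ``k``.
    """
    expr_df = _read_tsv_matrix(expr_path)
    atlas_df = _read_tsv_matrix(atlas_path)
    coords = _read_coords(coords_path)

    expr = ExpressionMatrix(
        gene_names=[str(g) for g in expr_df.index],
        cell_names=[str(c) for c in expr_df.columns],
        values=expr_df.to_numpy(dtype=float),
    )
    atlas_vals = atlas_df.to_numpy()
    # orientation check: atlas columns must be gene names; if the transpose
    # matches the expression gene set instead, the file is flipped.
    expr_genes = set(expr.gene_names)
    col_hits = sum(str(g) in expr_genes for g in atlas_df.columns)
    row_hits = sum(str(g) in expr_genes for g in atlas_df.index)
    if col_hits == 0 and row_hits > 0:
        raise DataError(
            f"{atlas_path}: atlas appears transposed (genes found in rows, "
            "expected bins as rows / genes as columns)"
        )
    atlas = SpatialBinAtlas(
        gene_names=[str(g) for g in atlas_df.columns],
        insitu=atlas_vals,
        coords=coords,
    )
    return expr, atlas


def write_selection(ranking: FeatureRanking, path: str | Path) -> None:
    """Write the ordered gene list (one per line) plus a ``.stats.tsv``
    sidecar with stability / score / ranksum columns."""
    if not ranking.genes:
        raise DataError("cannot write an empty ranking")
    path = Path(path)
    path.write_text("\n".join(ranking.genes) + "\n")
    stats = pd.DataFrame(
        {
            "gene": ranking.genes,
            "rank": np.arange(1, len(ranking.genes) + 1),
            "stability": [ranking.stability.get(g, np.nan) for g in ranking.genes],
            "score": [ranking.score.get(g, np.nan) for g in ranking.genes],
            "ranksum": [ranking.ranksum.get(g, np.nan) for g in ranking.genes],
        }
    )
    stats.to_csv(path.with_suffix(path.suffix + ".stats.tsv"), sep="\t", index=False)


def read_selection(path: str | Path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]


def write_predictions(preds: LocationPredictions, path: str | Path) -> None:
    """CSV with header ``cell,bin_1..bin_10``; bin indices are 1-based to
    match file row order of the atlas."""
    cols = [f"bin_{i}" for i in range(1, N_PREDICTED_BINS + 1)]
    df = pd.DataFrame(preds.bin_indices + 1, columns=cols)
    df.insert(0, "cell", preds.cell_names)
    df.to_csv(path, index=False)


def read_predictions(path: str | Path, atlas: SpatialBinAtlas) -> LocationPredictions:
    df = pd.read_csv(path)
    cols = [f"bin_{i}" for i in range(1, N_PREDICTED_BINS + 1)]
    bins = df[cols].to_numpy(dtype=int) - 1
    if bins.min() < 0 or bins.max() >= atlas.n_bins:
        raise DataError("prediction file contains bin indices outside the atlas")
    return LocationPredictions(
        cell_names=[str(c) for c in df["cell"]],
        bin_indices=bins,
        coords=atlas.coords[bins],
    )
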