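"""MCC-based mapping of cells to spatial bins.

The mapping works in two steps.  First, each atlas gene's continuous
expression is binarized with a per-gene threshold chosen so that the
fraction of 'on' cells matches the fraction of 'on' bins in the binary
atlas (a quantile is selected per gene from a grid).  Second, every
(cell, bin) pair is scored with the Matthews correlation coefficient
between the cell's binarized gene vector and the bin's atlas column.
High-MCC bins are a cell's likely positions; they provide the training
labels for the feature-selection methods and the final top-10 location
predictions.

Leakage safety: threshold fitting uses training cells only, and
prediction for held-out cells reuses those frozen thresholds
(:func:`predict_top10` enforces train/test disjointness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    DataError,
    ExpressionMatrix,
    GeneList,
    LocationPredictions,
    N_PREDICTED_BINS,
    SpatialBinAtlas,
)

logger = logging.getLogger("spatialsel")

DEFAULT_QUANTILE_GRID = np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 10)
WEAK_LABEL_TAU = 0.95  # fraction of row-max MCC a bin must reach to be a label


@dataclass
class BinarizationParams:
    """Per-gene binarization threshold and the quantile that produced it."""

    gene_names: list[str]
    quantiles: np.ndarray   # chosen quantile q per gene
    thresholds: np.ndarray  # q-quantile of training expression, per gene

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if not (len(self.gene_names) == len(self.quantiles) == len(self.thresholds)):
            raise DataError("binarization parameter lengths disagree")


@dataclass
class MccMap:
    """Cells x bins matrix of Matthews correlation coefficients."""

    cell_names: list[str]
    mcc: np.ndarray          # (n_cells, n_bins), values in [-1, 1]
    genes: list[str]         # gene set the map was computed from
    unique_max: np.ndarray   # per cell, True iff exactly one bin attains the max

    def cell_index(self, cell: str) -> int:
        try:
            return self.cell_names.index(cell)
        except ValueError:
            raise DataError(f"cell {cell!r} not in MCC map") from None


@dataclass
class TrainingLabels:
    """(cell, bin, x, y, z) observations; possibly several bins per cell."""

    cell_names: list[str]    # one entry per observation (repeats allowed)
    bin_indices: np.ndarray  # (n_obs,)
    coords: np.ndarray       # (n_obs, 3)

    @property
    def n_obs(self) -> int:
        return len(self.cell_names)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------


def fit_binarization(
    train_expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    quantile_grid: np.ndarray = DEFAULT_QUANTILE_GRID,
) -> BinarizationParams:
    """Choose one quantile/threshold per atlas gene from training cells.

    For each gene, every grid quantile ``q`` yields a candidate threshold
    ``t(q)``; the chosen ``q`` minimizes the gap between the fraction of
    training cells with expression >= t(q) and the fraction of atlas bins
    where the gene is on.  Ties break toward smaller ``q``.
    """
    grid = np.asarray(quantile_grid, dtype=float)
    if grid.size == 0:
        raise DataError("empty quantile grid")
    grid = np.sort(grid)
    gidx_expr = train_expr.gene_index(train_expr.gene_names)
    gidx_atlas = atlas.gene_index(train_expr.gene_names)  # errors name the gene

    on_frac = atlas.insitu[:, gidx_atlas].mean(axis=0)
    values = train_expr.values[gidx_expr]  # (n_genes, n_cells)

    # candidate thresholds for all genes at once: (n_grid, n_genes)
    cand = np.quantile(values, grid, axis=1)
    # fraction of training cells >= threshold, per (q, gene)
    frac_on = (values[None, :, :] >= cand[:, :, None]).mean(axis=2)
    gap = np.abs(frac_on - on_frac[None, :])
    best = np.argmin(gap, axis=0)  # argmin returns first (smallest q) on ties

    thresholds = cand[best, np.arange(len(gidx_expr))]
    for g, vals in zip(train_expr.gene_names, values):
        if np.ptp(vals) == 0:
            logger.warning("gene %s has constant expression; binarization is degenerate", g)
    return BinarizationParams(list(train_expr.gene_names), grid[best], thresholds)


def binarize_cells(expr: ExpressionMatrix, params: BinarizationParams) -> np.ndarray:
    """Binary (cells x genes) matrix: 1 iff expression >= threshold."""
    idx = expr.gene_index(params.gene_names)
    vals = expr.values[idx]  # (n_genes, n_cells)
    return (vals >= params.thresholds[:, None]).T.astype(np.int8)


# ---------------------------------------------------------------------------
# Matthews correlation
# ---------------------------------------------------------------------------


def mcc(a: np.ndarray, b: np.ndarray) -> float:
    """MCC of two equal-length binary vectors; 0 when any contingency
    margin is empty (undefined case treated as no correlation)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise DataError("mcc requires two equal-length 1-D vectors")
    tp = float(np.sum((a == 1) & (b == 1)))
    tn = float(np.sum((a == 0) & (b == 0)))
    fp = float(np.sum((a == 1) & (b == 0)))
    fn = float(np.sum((a == 0) & (b == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def compute_mcc_map(
    bin_cells: np.ndarray,
    atlas: SpatialBinAtlas,
    genes: GeneList | list[str],
    cell_names: list[str] | None = None,
) -> MccMap:
    """MCC for every (cell, bin) pair over the listed genes.

    ``bin_cells`` is the (cells x genes) binary matrix from
    :func:`binarize_cells`, with columns in ``genes`` order.
    """
    gene_list = list(genes)
    if not gene_list:
        raise DataError("empty gene list")
    B = np.asarray(bin_cells, dtype=np.float64)
    if B.shape[1] != len(gene_list):
        raise DataError("binarized matrix width does not match gene list")
    A = atlas.insitu[:, atlas.gene_index(gene_list)].astype(np.float64)

    tp = B @ A.T
    fp = B @ (1.0 - A).T
    fn = (1.0 - B) @ A.T
    tn = (1.0 - B) @ (1.0 - A).T
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)

    row_max = m.max(axis=1, keepdims=True)
    unique = (m == row_max).sum(axis=1) == 1
    if cell_names is None:
        cell_names = [f"cell_{i}" for i in range(B.shape[0])]
    elif len(cell_names) != B.shape[0]:
        raise DataError("cell_names length does not match binarized matrix")
    return MccMap(cell_names=list(cell_names), mcc=m, genes=gene_list, unique_max=unique)


# ---------------------------------------------------------------------------
# Labels and predictions
# ---------------------------------------------------------------------------


def top_location(mcc_map: MccMap, cell: str, atlas: SpatialBinAtlas) -> tuple[int, float, float, float]:
    """Bin with maximal MCC for the cell; ties go to the smallest bin index
    (file order)."""
    row = mcc_map.mcc[mcc_map.cell_index(cell)]
    b = int(np.argmax(row))  # argmax picks the first of tied maxima
    x, y, z = atlas.coords[b]
    return b, float(x), float(y), float(z)


def top_locations(mcc_map: MccMap, atlas: SpatialBinAtlas) -> TrainingLabels:
    """Vectorized :func:`top_location` over all cells of the map."""
    bins = np.argmax(mcc_map.mcc, axis=1)
    return TrainingLabels(list(mcc_map.cell_names), bins, atlas.coords[bins])


def weak_labels(
    mcc_map: MccMap, atlas: SpatialBinAtlas, tau: float = WEAK_LABEL_TAU
) -> TrainingLabels:
    """All bins with MCC >= tau * (row max) per cell, as label observations.

    With ``tau = 1`` and a unique row maximum this reduces to
    :func:`top_locations`.  When a cell's max MCC is not positive the
    relative threshold is ill-posed and only the maximal bins are kept.
    """
    if not (0 < tau <= 1):
        raise DataError("tau must be in (0, 1]")
    m = mcc_map.mcc
    row_max = m.max(axis=1)
    thr = np.where(row_max > 0, tau * row_max, row_max)
    keep = m >= thr[:, None]
    cell_idx, bin_idx = np.nonzero(keep)
    names = [mcc_map.cell_names[i] for i in cell_idx]
    return TrainingLabels(names, bin_idx, atlas.coords[bin_idx])


def write_binarization_params(params: BinarizationParams, path) -> None:
    """Persist per-gene quantile/threshold as TSV."""
    import pandas as pd

    pd.DataFrame(
        {"gene": params.gene_names, "quantile": params.quantiles,
         "threshold": params.thresholds}
    ).to_csv(path, sep="\t", index=False)


def read_binarization_params(path) -> BinarizationParams:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return BinarizationParams(
        [str(g) for g in df["gene"]],
        df["quantile"].to_numpy(float),
        df["threshold"].to_numpy(float),
    )


def write_mcc_map(mcc_map: MccMap, path) -> None:
    """Persist the cells x bins MCC matrix as TSV (bins 1-based in header)."""
    import pandas as pd

    pd.DataFrame(
        mcc_map.mcc, index=mcc_map.cell_names,
        columns=[f"bin_{i+1}" for i in range(mcc_map.mcc.shape[1])],
    ).to_csv(path, sep="\t")


def predict_top10(
    train_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    genes: GeneList | list[str],
    quantile_grid: np.ndarray = DEFAULT_QUANTILE_GRID,
) -> LocationPredictions:
    """Leakage-safe two-step prediction of the 10 most likely bins per test
    cell: fit binarization on training cells and selected genes only, apply
    the frozen thresholds to test cells, rank bins by MCC (descending, ties
    by ascending bin index)."""
    gene_list = list(genes)
    overlap = set(train_expr.cell_names) & set(test_expr.cell_names)
    if overlap:
        raise DataError(
            f"leakage guard: {len(overlap)} cells appear in both train and test"
        )
    params = fit_binarization(train_expr.subset_genes(gene_list), atlas, quantile_grid)
    bin_test = binarize_cells(test_expr, params)
    mcc_map = compute_mcc_map(bin_test, atlas, gene_list, cell_names=list(test_expr.cell_names))

    order = np.argsort(-mcc_map.mcc, axis=1, kind="stable")[:, :N_PREDICTED_BINS]
    return LocationPredictions(
        cell_names=list(test_expr.cell_names),
        bin_indices=order,
        coords=atlas.coords[order],
    )
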