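"""Blind Euclidean metric, random baseline, outer cross-validation harness,
feature-stability reports and the data-leakage diagnostic.

The blind metric scores a prediction by the mean Euclidean distance of a
cell's 10 predicted bins from the cell's reference location (the bin with
its maximum MCC under the full atlas; among ties, the first bin in file
order).  Per-fold and overall values are plain means of means, exactly as
defined by their names: MeanEuclDistPerCell -> MeanEuclDistPerFold ->
MeanEuclDistAllFold.

The outer CV wraps the *entire* pipeline: feature selection and
binarization fitting see only the nine training folds; predictions and
the blind metric are computed on the held-out fold.  A hash of the
held-out expression is checked before and after selection as an
instrumented leakage guard.

The "PB" mode (provided-binarized) deliberately reuses a binarization
fitted on all cells and all genes — the leaky shortcut the harness exists
to expose; it is labelled leaky in every output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distmap import (
    DEFAULT_QUANTILE_GRID,
    BinarizationParams,
    MccMap,
    binarize_cells,
    compute_mcc_map,
    fit_binarization,
    predict_top10,
    top_locations,
    weak_labels,
)
from .io import (
    DataError,
    ExpressionMatrix,
    GeneList,
    LocationPredictions,
    N_PREDICTED_BINS,
    SpatialBinAtlas,
)

logger = logging.getLogger("spatialsel")

Selector = Callable[[ExpressionMatrix, SpatialBinAtlas, int, int], GeneList]


@dataclass
class EvaluationReport:
    """Blind-metric results at cell, fold and overall granularity."""

    per_cell: dict[str, float]
    per_fold: list[float]
    method: str
    mode: str = "selGenes"  # or "PB" (leaky diagnostic)

    @property
    def mean_eucl_dist_all_fold(self) -> float:
        return float(np.mean(self.per_fold))


@dataclass
class StabilityReport:
    """How often each gene was selected across the outer folds."""

    fold_counts: dict[str, int]
    n_folds: int
    histogram: dict[int, int] = field(default_factory=dict)
    overlap_fractions: list[float] = field(default_factory=list)

    @property
    def mean_overlap(self) -> float:
        return float(np.mean(self.overlap_fractions)) if self.overlap_fractions else np.nan


# ---------------------------------------------------------------------------
# Blind metric
# ---------------------------------------------------------------------------


def mean_eucl_dist_per_cell(
    preds: LocationPredictions,
    truth_coords: dict[str, np.ndarray],
    atlas: SpatialBinAtlas,
) -> dict[str, float]:
    """Per cell, mean Euclidean distance of the 10 predicted bins to the
    cell's reference coordinate."""
    out: dict[str, float] = {}
    for i, cell in enumerate(preds.cell_names):
        if cell not in truth_coords:
            raise DataError(f"no reference location for cell {cell!r}")
        d = np.linalg.norm(preds.coords[i] - truth_coords[cell], axis=1)
        out[cell] = float(d.mean())
    return out


def reference_locations(
    expr: ExpressionMatrix, atlas: SpatialBinAtlas
) -> dict[str, np.ndarray]:
    """Reference location per cell: max-MCC bin under the full atlas gene
    set fitted on all cells (first bin in file order among ties)."""
    insitu = [g for g in atlas.gene_names if g in set(expr.gene_names)]
    params = fit_binarization(expr.subset_genes(insitu), atlas)
    mcc_map = compute_mcc_map(
        binarize_cells(expr, params), atlas, insitu, cell_names=list(expr.cell_names)
    )
    labels = top_locations(mcc_map, atlas)
    return {c: xyz for c, xyz in zip(labels.cell_names, labels.coords)}


# ---------------------------------------------------------------------------
# Baselines and the outer CV
# ---------------------------------------------------------------------------


def random_feature_baseline(
    insitu_genes: GeneList | list[str], n_features: int, seed: int
) -> GeneList:
    """Uniform sample of N genes without replacement from the atlas pool."""
    pool = list(insitu_genes)
    if n_features > len(pool):
        raise DataError("cannot sample more genes than the pool holds")
    rng = np.random.default_rng(seed)
    picked = [str(g) for g in rng.choice(pool, size=n_features, replace=False)]
    return GeneList(picked, n_features)


def _expr_hash(expr: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(expr.values).tobytes())
    h.update("\x00".join(expr.cell_names).encode())
    return h.hexdigest()


def partition_cells(cells: list[str], n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    arr = np.asarray(cells)
    return [arr[ix] for ix in np.array_split(rng.permutation(len(arr)), n_folds)]


def outer_cv_run(
    expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    selector: Selector,
    n_features: int,
    n_folds: int = 10,
    seed: int = 0,
    method: str = "selector",
    quantile_grid: np.ndarray = DEFAULT_QUANTILE_GRID,
) -> tuple[EvaluationReport, StabilityReport, list[GeneList]]:
    """Leakage-safe outer CV around selection + prediction.

    Per fold: the selector sees only the training cells; the trained
    binarization and selected genes then predict the held-out fold, scored
    with the blind metric against reference locations.
    """
    truth = reference_locations(expr, atlas)
    folds = partition_cells(list(expr.cell_names), n_folds, seed)
    seeds = np.random.SeedSequence(seed).generate_state(n_folds) % (2**31)

    per_cell: dict[str, float] = {}
    per_fold: list[float] = []
    gene_lists: list[GeneList] = []
    for f, test_cells in enumerate(folds):
        test_set = set(test_cells)
        train_cells = [c for c in expr.cell_names if c not in test_set]
        train_expr = expr.subset_cells(train_cells)
        test_expr = expr.subset_cells(list(test_cells))

        before = _expr_hash(test_expr)
        genes = selector(train_expr, atlas, n_features, int(seeds[f]))
        after = _expr_hash(test_expr)
        if before != after:
            raise DataError("leakage guard: selector modified held-out expression")
        gene_lists.append(genes)

        preds = predict_top10(train_expr, test_expr, atlas, genes, quantile_grid)
        dists = mean_eucl_dist_per_cell(preds, truth, atlas)
        per_cell.update(dists)
        per_fold.append(float(np.mean(list(dists.values()))))

    report = EvaluationReport(per_cell, per_fold, method=method)
    stability = feature_stability_report(gene_lists)
    return report, stability, gene_lists


def feature_stability_report(
    per_fold_lists: Sequence[GeneList | list[str]],
    second_method_lists: Sequence[GeneList | list[str]] | None = None,
) -> StabilityReport:
    """Per-gene fold counts, their histogram, and (optionally) per-fold
    overlap fractions with a second method's lists."""
    if len(per_fold_lists) < 2:
        raise DataError("stability needs at least two folds")
    counts: dict[str, int] = {}
    for lst in per_fold_lists:
        for g in lst:
            counts[g] = counts.get(g, 0) + 1
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    overlaps: list[float] = []
    if second_method_lists is not None:
        if len(second_method_lists) != len(per_fold_lists):
            raise DataError("fold counts of the two methods differ")
        for a, b in zip(per_fold_lists, second_method_lists):
            sa, sb = set(a), set(b)
            overlaps.append(len(sa & sb) / max(len(sa), len(sb), 1))
    return StabilityReport(counts, len(per_fold_lists), hist, overlaps)


# ---------------------------------------------------------------------------
# Leakage diagnostic
# ---------------------------------------------------------------------------


def _top10_from_map(mcc_map: MccMap, atlas: SpatialBinAtlas) -> LocationPredictions:
    order = np.argsort(-mcc_map.mcc, axis=1, kind="stable")[:, :N_PREDICTED_BINS]
    return LocationPredictions(list(mcc_map.cell_names), order, atlas.coords[order])


def leakage_comparison(
    expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    genes: GeneList | list[str],
    n_folds: int = 10,
    seed: int = 0,
    quantile_grid: np.ndarray = DEFAULT_QUANTILE_GRID,
) -> tuple[EvaluationReport, EvaluationReport]:
    """Paired reports: leakage-safe per-fold refit ("selGenes") versus the
    leaky global binarization ("PB").

    PB reuses thresholds fitted once on all cells and all atlas genes — the
    same information the reference locations come from — so its blind score
    is optimistically inflated; it exists only to measure that inflation.
    """
    gene_list = list(genes)
    truth = reference_locations(expr, atlas)
    insitu = [g for g in atlas.gene_names if g in set(expr.gene_names)]
    global_params = fit_binarization(expr.subset_genes(insitu), atlas, quantile_grid)
    pb_params = BinarizationParams(
        gene_list,
        global_params.quantiles[[insitu.index(g) for g in gene_list]],
        global_params.thresholds[[insitu.index(g) for g in gene_list]],
    )
    folds = partition_cells(list(expr.cell_names), n_folds, seed)

    cells_sel: dict[str, float] = {}
    cells_pb: dict[str, float] = {}
    fold_sel: list[float] = []
    fold_pb: list[float] = []
    for test_cells in folds:
        test_set = set(test_cells)
        train_expr = expr.subset_cells([c for c in expr.cell_names if c not in test_set])
        test_expr = expr.subset_cells(list(test_cells))

        preds_sel = predict_top10(train_expr, test_expr, atlas, gene_list, quantile_grid)
        d_sel = mean_eucl_dist_per_cell(preds_sel, truth, atlas)

        pb_map = compute_mcc_map(
            binarize_cells(test_expr, pb_params), atlas, gene_list,
            cell_names=list(test_expr.cell_names),
        )
        d_pb = mean_eucl_dist_per_cell(_top10_from_map(pb_map, atlas), truth, atlas)

        cells_sel.update(d_sel)
        cells_pb.update(d_pb)
        fold_sel.append(float(np.mean(list(d_sel.values()))))
        fold_pb.append(float(np.mean(list(d_pb.values()))))

    return (
        EvaluationReport(cells_sel, fold_sel, method="two-step", mode="selGenes"),
        EvaluationReport(cells_pb, fold_pb, method="global-binarization (leaky)", mode="PB"),
    )


# ---------------------------------------------------------------------------
# Dataset summary (mapping uniqueness and weak-label counts)
# ---------------------------------------------------------------------------


def make_random_selector() -> Selector:
    def _select(train_expr: ExpressionMatrix, atlas: SpatialBinAtlas,
                n_features: int, seed: int) -> GeneList:
        pool = [g for g in atlas.gene_names if g in set(train_expr.gene_names)]
        return random_feature_baseline(pool, n_features, seed)
    return _select


def make_lasso_selector(**kwargs) -> Selector:
    """Lasso.TopX as an outer-CV selector; kwargs forward to
    :func:`spatialsel.lasso_topx.lasso_topx_select`."""
    from .lasso_topx import lasso_topx_select

    def _select(train_expr: ExpressionMatrix, atlas: SpatialBinAtlas,
                n_features: int, seed: int) -> GeneList:
        ranking, _ = lasso_topx_select(train_expr, atlas, n_features,
                                       seed=seed, **kwargs)
        return ranking.as_gene_list()
    return _select


def make_nn_selector(**kwargs) -> Selector:
    """Weakly-supervised network ensemble as an outer-CV selector; kwargs
    forward to :func:`spatialsel.nn_weak.nn_weak_select`.  The MCC map used
    for weak labels is fitted on the training cells only."""
    from .nn_weak import nn_weak_select

    def _select(train_expr: ExpressionMatrix, atlas: SpatialBinAtlas,
                n_features: int, seed: int) -> GeneList:
        insitu = [g for g in atlas.gene_names if g in set(train_expr.gene_names)]
        params = fit_binarization(train_expr.subset_genes(insitu), atlas)
        mcc_map = compute_mcc_map(
            binarize_cells(train_expr, params), atlas, insitu,
            cell_names=list(train_expr.cell_names),
        )
        opts = dict(kwargs)
        restrict = opts.pop("restrict_to", insitu)
        ranking, _ = nn_weak_select(train_expr, atlas, mcc_map, n_features,
                                    restrict_to=restrict, seed=seed, **opts)
        return ranking.as_gene_list()
    return _select


def mapping_summary(
    expr: ExpressionMatrix, atlas: SpatialBinAtlas, tau: float = 0.95
) -> dict[str, float]:
    """Uniquely-mapped cell count and weak-label statistics for a dataset:
    the quantities reported for the original challenge data (1,010 of 1,297
    cells unique; 11,491 weak observations; mean 7 labels per cell)."""
    insitu = [g for g in atlas.gene_names if g in set(expr.gene_names)]
    params = fit_binarization(expr.subset_genes(insitu), atlas)
    mcc_map = compute_mcc_map(
        binarize_cells(expr, params), atlas, insitu, cell_names=list(expr.cell_names)
    )
    labels = weak_labels(mcc_map, atlas, tau)
    return {
        "n_cells": float(expr.n_cells),
        "n_unique_cells": float(mcc_map.unique_max.sum()),
        "n_weak_observations": float(labels.n_obs),
        "mean_labels_per_cell": float(labels.n_obs / expr.n_cells),
    }
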