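"""Lasso.TopX: select exactly N spatially informative genes.

The selector fits multi-response sparse linear models (one joint model
predicting the x, y, z coordinates of each cell's top mapped location)
over a dense lambda grid inside a repeated k-fold cross-validation.  A
gene's three coordinate coefficients are penalized jointly (group
penalty lambda * sum_g ||w_g||_2) so a gene drops in and out of the
model as a unit, mirroring the mgaussian behaviour of glmnet.  The
lambda whose models carry exactly N features with the lowest mean
validation error is retained; features of those k*reps models are then
scored by stability (how often selected) and mean |coefficient|, the two
ranks are summed (RankSum), and the N genes with the highest RankSum are
returned.

Leakage safety: standardization parameters inside each CV fold come from
that fold's training cells only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import MultiTaskLasso

from .distmap import (
    MccMap,
    TrainingLabels,
    binarize_cells,
    compute_mcc_map,
    fit_binarization,
    top_locations,
)
from .io import DataError, ExpressionMatrix, FeatureRanking, GeneList, SpatialBinAtlas

logger = logging.getLogger("spatialsel")

DEFAULT_K = 5
DEFAULT_REPS = 20
DEFAULT_N_LAMBDAS = 300
DEFAULT_LAMBDA_MIN_RATIO = 1e-4


@dataclass
class LassoCVRecord:
    """One fitted model of the repeated CV: its lambda, fold identity,
    surviving features, coefficients and validation error."""

    lam: float
    rep: int
    fold: int
    selected: list[str]
    coefficients: np.ndarray  # (n_selected, 3), rows aligned with `selected`
    model_error: float        # mean Euclidean distance on the validation cells


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene mean/SD from these rows only; zero-variance genes -> 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.info("%d zero-variance genes in a training fold set to 0", int(dead.sum()))
    sd_safe = np.where(dead, 1.0, sd)
    Xs = (X - mu) / sd_safe
    Xs[:, dead] = 0.0
    return Xs, mu, sd_safe


def make_lambda_grid(
    X: np.ndarray,
    Y: np.ndarray,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Log-spaced grid from lambda_max (smallest lambda with the all-zero
    solution) down to lambda_min_ratio * lambda_max, ascending order.

    lambda_max for the group penalty is max_g ||x_g' Yc|| / n on
    standardized predictors and centred responses.
    """
    Xs, _, _ = _standardize_train(X)
    Yc = Y - Y.mean(axis=0)
    lam_max = np.max(np.linalg.norm(Xs.T @ Yc, axis=1)) / X.shape[0]
    if lam_max == 0:
        raise DataError("degenerate problem: lambda_max is 0")
    return np.geomspace(lam_max * lambda_min_ratio, lam_max, n_lambdas)


def run_repeated_cv(
    X: ExpressionMatrix,
    labels: TrainingLabels,
    lambdas: np.ndarray,
    k: int = DEFAULT_K,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> list[LassoCVRecord]:
    """Fit k * reps * len(lambdas) multi-response lasso models.

    ``X`` holds the predictor genes (rows) by cells (columns); ``labels``
    must carry exactly one (x, y, z) observation per cell of ``X``, in the
    same cell order (cells with tied top locations are excluded upstream).
    """
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    if list(labels.cell_names) != list(X.cell_names):
        raise DataError("labels must be unique per cell and aligned with X")
    n_cells = X.n_cells
    if n_cells < 2 * k:
        raise DataError("too few cells for the requested fold count")
    Xmat = X.values.T  # cells x genes
    Y = labels.coords
    genes = np.asarray(X.gene_names)
    rng = np.random.default_rng(seed)

    records: list[LassoCVRecord] = []
    for rep in range(reps):
        perm = rng.permutation(n_cells)
        folds = np.array_split(perm, k)
        for fold_id, val_idx in enumerate(folds):
            if len(val_idx) < 2:
                raise DataError("a fold has fewer than 2 cells")
            train_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
            Xtr, mu, sd = _standardize_train(Xmat[train_idx])
            Xva = (Xmat[val_idx] - mu) / sd
            Ytr, Yva = Y[train_idx], Y[val_idx]

            model = MultiTaskLasso(alpha=1.0, fit_intercept=True, warm_start=True,
                                   max_iter=2000, tol=1e-6)
            # descend the path (dense -> sparse reversed) with warm starts
            for lam in lambdas[::-1]:
                model.alpha = float(lam)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xtr, Ytr)
                W = model.coef_.T  # (n_genes, 3)
                nz = np.any(W != 0, axis=1)
                pred = Xva @ W + model.intercept_
                err = float(np.mean(np.linalg.norm(pred - Yva, axis=1)))
                records.append(
                    LassoCVRecord(
                        lam=float(lam),
                        rep=rep,
                        fold=fold_id,
                        selected=[str(g) for g in genes[nz]],
                        coefficients=W[nz].copy(),
                        model_error=err,
                    )
                )
    return records


def select_best_lambda(records: list[LassoCVRecord], n_features: int) -> float:
    """Among lambdas with at least one exactly-N-feature model, the one whose
    records have the lowest mean validation error; ties -> larger lambda."""
    if not records:
        raise DataError("no CV records")
    by_lam: dict[float, list[LassoCVRecord]] = {}
    for r in records:
        by_lam.setdefault(r.lam, []).append(r)
    candidates = [
        lam for lam, recs in by_lam.items()
        if any(len(r.selected) == n_features for r in recs)
    ]
    if not candidates:
        raise DataError(
            f"no lambda produced a model with exactly {n_features} features; "
            "extend the lambda grid (n_lambdas / lambda_min_ratio)"
        )
    # minimize mean error; among ties prefer the larger (sparser) lambda
    best = max(candidates, key=lambda lam: (-np.mean([r.model_error for r in by_lam[lam]]), lam))
    return float(best)


def score_features(records: list[LassoCVRecord]) -> FeatureRanking:
    """Stability and mean |coefficient| for the genes of one lambda's models.

    stability(g) = number of retained models selecting g; mean_abs_coef(g) =
    mean |coefficient| over the three coordinates and the selecting models.
    """
    lams = {r.lam for r in records}
    if len(lams) != 1:
        raise DataError("score_features expects records at a single lambda")
    stability: dict[str, float] = {}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in records:
        for g, row in zip(r.selected, r.coefficients):
            stability[g] = stability.get(g, 0) + 1
            sums[g] = sums.get(g, 0.0) + float(np.abs(row).sum())
            counts[g] = counts.get(g, 0) + 3
    mean_abs = {g: sums[g] / counts[g] for g in sums}
    order = sorted(stability, key=lambda g: (-stability[g], -mean_abs[g], g))
    return FeatureRanking(
        genes=order,
        target_size=max(len(order), 1),
        stability=stability,
        score=mean_abs,
    )


def ranksum_select(ranking: FeatureRanking, n_features: int) -> FeatureRanking:
    """Keep the N genes with the highest RankSum (sum of the ascending ranks
    of stability and mean |coefficient|, average ranks on ties)."""
    genes = list(ranking.stability)
    if len(genes) < n_features:
        logger.warning(
            "only %d candidate genes for a target of %d; returning all",
            len(genes), n_features,
        )
    stab = np.array([ranking.stability[g] for g in genes])
    coef = np.array([ranking.score[g] for g in genes])
    ranksum = rankdata(stab) + rankdata(coef)
    rs = {g: float(v) for g, v in zip(genes, ranksum)}
    order = sorted(
        genes,
        key=lambda g: (-rs[g], -ranking.stability[g], -ranking.score[g], g),
    )
    kept = order[: min(n_features, len(order))]
    return FeatureRanking(
        genes=kept,
        target_size=n_features,
        stability={g: ranking.stability[g] for g in kept},
        score={g: ranking.score[g] for g in kept},
        ranksum={g: rs[g] for g in kept},
    )


def unique_top_location_labels(
    expr: ExpressionMatrix, atlas: SpatialBinAtlas
) -> tuple[ExpressionMatrix, TrainingLabels, MccMap]:
    """Map cells with the full atlas gene set and keep only the uniquely
    mapping ones (single max-MCC bin), as the training set for Lasso.TopX."""
    insitu = [g for g in atlas.gene_names if g in set(expr.gene_names)]
    params = fit_binarization(expr.subset_genes(insitu), atlas)
    mcc_map = compute_mcc_map(
        binarize_cells(expr, params), atlas, insitu, cell_names=list(expr.cell_names)
    )
    keep = [c for c, u in zip(expr.cell_names, mcc_map.unique_max) if u]
    sub = expr.subset_cells(keep)
    sub_map = MccMap(
        cell_names=keep,
        mcc=mcc_map.mcc[mcc_map.unique_max],
        genes=insitu,
        unique_max=mcc_map.unique_max[mcc_map.unique_max],
    )
    labels = top_locations(sub_map, atlas)
    return sub, labels, mcc_map


def lasso_topx_select(
    expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    n_features: int,
    k: int = DEFAULT_K,
    reps: int = DEFAULT_REPS,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    predictor_gene_set: str = "insitu_only",
    seed: int = 0,
) -> tuple[FeatureRanking, list[LassoCVRecord]]:
    """End-to-end Lasso.TopX on normalized expression.

    Labels are the top mapped location of each uniquely-mapping cell;
    predictors are either the atlas genes only (``insitu_only``, the
    subchallenge setting) or every gene (``all``).
    """
    if predictor_gene_set not in ("insitu_only", "all"):
        raise DataError("predictor_gene_set must be 'insitu_only' or 'all'")
    sub_expr, labels, _ = unique_top_location_labels(expr, atlas)
    if predictor_gene_set == "insitu_only":
        predictors = [g for g in atlas.gene_names if g in set(expr.gene_names)]
        sub_expr = sub_expr.subset_genes(predictors)
    lambdas = make_lambda_grid(
        sub_expr.values.T, labels.coords, n_lambdas, lambda_min_ratio
    )
    records = run_repeated_cv(sub_expr, labels, lambdas, k=k, reps=reps, seed=seed)
    best = select_best_lambda(records, n_features)
    at_best = [r for r in records if r.lam == best]
    ranking = score_features(at_best)
    return ranksum_select(ranking, n_features), records
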