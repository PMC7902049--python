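"""Weakly supervised neural networks for spatial gene selection.

A feed-forward regression network (genes -> two ReLU hidden layers of 100
units -> x, y, z) is trained on *weak* labels: every bin whose MCC is
within 95% of a cell's maximum becomes one training observation, so a
cell with several plausible positions contributes several rows with
identical expression but different coordinates.  Because of those
repeated rows, cross-validation folds are split on *cell names* — all
observations of a cell stay on one side — otherwise the validation split
would contain near-copies of training rows and the validation loss would
be optimistically biased.

Training uses minibatch Adadelta on a per-observation Euclidean loss
(L2 distance of the predicted to the labelled position, not squared),
10% dropout on the input and hidden layers, and early stopping with a
50-epoch patience on the validation loss, restoring the best weights.

Gene importance per trained model follows Gedeon's weight-path method:
each layer's contribution matrix normalizes absolute weights within each
receiving unit's column, the matrices are chained input-to-output, and a
gene's VIP score is its total contribution over the three outputs.  The
final selection is a consensus vote over an ensemble of models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distmap import MccMap, SpatialBinAtlas, TrainingLabels, weak_labels
from .io import DataError, ExpressionMatrix, FeatureRanking, GeneList

logger = logging.getLogger("spatialsel")

DEFAULT_TAU = 0.95
DEFAULT_R_THRESH = 0.6


@dataclass
class NetworkSpec:
    """Architecture and optimization settings of the regression network."""

    hidden: tuple[int, ...] = (100, 100)
    n_outputs: int = 3
    dropout: float = 0.10          # input and hidden layers
    minibatch: int = 100
    patience: int = 50             # epochs without validation improvement
    epoch_cap: int = 2000          # hard safety bound
    rho: float = 0.9               # Adadelta decay
    eps: float = 1e-6              # Adadelta epsilon

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise DataError("dropout must be in [0, 1)")
        if any(h <= 0 for h in self.hidden) or self.n_outputs <= 0:
            raise DataError("layer sizes must be positive")


@dataclass
class Observations:
    """Aligned (expression, coordinate label, cell name) observations."""

    X: np.ndarray            # (n_obs, n_genes)
    Y: np.ndarray            # (n_obs, 3)
    cells: list[str]         # per observation; repeats mark weak labels
    gene_names: list[str]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def subset_cells(self, keep: set[str]) -> "Observations":
        mask = np.array([c in keep for c in self.cells])
        return Observations(
            self.X[mask], self.Y[mask],
            [c for c, m in zip(self.cells, mask) if m], list(self.gene_names),
        )

    def subset_genes(self, genes: list[str]) -> "Observations":
        pos = {g: i for i, g in enumerate(self.gene_names)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return Observations(self.X[:, idx], self.Y, list(self.cells), list(genes))


@dataclass
class TrainedModel:
    """Weights of one trained network plus its training history."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    gene_names: list[str]          # inputs, in weight row order
    dead_genes: list[str]          # zero-variance in this training split
    train_trace: list[float] = field(default_factory=list)
    val_trace: list[float] = field(default_factory=list)
    best_val_loss: float = np.inf
    rep: int = 0
    fold: int = 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def build_weak_training_set(
    mcc_map: MccMap,
    atlas: SpatialBinAtlas,
    expr: ExpressionMatrix,
    tau: float = DEFAULT_TAU,
) -> Observations:
    """One observation per (cell, qualifying bin); a cell's expression vector
    repeats across its observations with differing coordinate labels."""
    labels: TrainingLabels = weak_labels(mcc_map, atlas, tau)
    cell_pos = {c: i for i, c in enumerate(expr.cell_names)}
    idx = np.array([cell_pos[c] for c in labels.cell_names], dtype=int)
    X = expr.values.T[idx]  # (n_obs, n_genes)
    return Observations(X, labels.coords.copy(), list(labels.cell_names),
                        list(expr.gene_names))


def filter_correlated_genes(
    train_expr: ExpressionMatrix,
    insitu_genes: GeneList | list[str],
    r_thresh: float = DEFAULT_R_THRESH,
) -> list[str]:
    """Drop non-atlas genes whose Pearson |r| with any atlas gene reaches
    ``r_thresh`` on the training cells; atlas genes are always retained."""
    insitu = [g for g in insitu_genes if g in set(train_expr.gene_names)]
    others = [g for g in train_expr.gene_names if g not in set(insitu)]
    if not others:
        return list(train_expr.gene_names)
    A = train_expr.values[train_expr.gene_index(insitu)]
    B = train_expr.values[train_expr.gene_index(others)]

    def _std(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf  # constant genes correlate with nothing
        return (M - mu) / sd

    r = _std(B) @ _std(A).T / train_expr.n_cells  # (others, insitu)
    drop = {g for g, hit in zip(others, (np.abs(r) >= r_thresh).any(axis=1)) if hit}
    return [g for g in train_expr.gene_names if g not in drop]


def grouped_kfold(
    cells: list[str], k: int, reps: int, seed: int
) -> list[list[np.ndarray]]:
    """Per repetition, a partition of *cell names* into k folds of sizes
    differing by at most one; all observations of a cell share its fold."""
    if k < 2:
        raise DataError("k must be >= 2")
    if k > len(cells):
        raise DataError("more folds than cells")
    rng = np.random.default_rng(seed)
    cells_arr = np.asarray(cells)
    out = []
    for _ in range(reps):
        perm = rng.permutation(len(cells_arr))
        out.append([cells_arr[ix] for ix in np.array_split(perm, k)])
    return out


# ---------------------------------------------------------------------------
# Network training (numpy)
# ---------------------------------------------------------------------------


class _Adadelta:
    def __init__(self, params: list[np.ndarray], rho: float, eps: float) -> None:
        self.rho, self.eps = rho, eps
        self.Eg = [np.zeros_like(p) for p in params]
        self.Ed = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, Eg, Ed in zip(params, grads, self.Eg, self.Ed):
            Eg *= self.rho
            Eg += (1 - self.rho) * g * g
            dx = -np.sqrt(Ed + self.eps) / np.sqrt(Eg + self.eps) * g
            Ed *= self.rho
            Ed += (1 - self.rho) * dx * dx
            p += dx


def _forward(X, weights, biases, dropout=0.0, rng=None):
    """Return activations per layer; inverted dropout when rng is given."""
    acts = [X]
    h = X
    if rng is not None and dropout > 0:
        h = h * (rng.random(h.shape) >= dropout) / (1 - dropout)
        acts[0] = h
    n_layers = len(weights)
    for l, (W, b) in enumerate(zip(weights, biases)):
        h = h @ W + b
        if l < n_layers - 1:
            h = np.maximum(h, 0.0)
            if rng is not None and dropout > 0:
                h = h * (rng.random(h.shape) >= dropout) / (1 - dropout)
        acts.append(h)
    return acts


def euclidean_loss(pred: np.ndarray, Y: np.ndarray) -> float:
    """Mean over observations of the L2 distance to the label."""
    return float(np.mean(np.linalg.norm(pred - Y, axis=1)))


def train_network(
    train_obs: Observations,
    val_obs: Observations,
    spec: NetworkSpec = NetworkSpec(),
    seed: int = 0,
    rep: int = 0,
    fold: int = 0,
) -> TrainedModel:
    """Train one network; standardization parameters come from the training
    observations only, and sharing a cell between splits is a fatal error."""
    shared = set(train_obs.cells) & set(val_obs.cells)
    if shared:
        raise DataError(
            f"leakage guard: {len(shared)} cells shared between train and validation"
        )
    if train_obs.gene_names != val_obs.gene_names:
        raise DataError("train/validation gene sets differ")

    rng = np.random.default_rng(seed)
    mu = train_obs.X.mean(axis=0)
    sd = train_obs.X.std(axis=0)
    dead = sd == 0
    sd_safe = np.where(dead, 1.0, sd)
    Xtr = (train_obs.X - mu) / sd_safe
    Xtr[:, dead] = 0.0
    Xva = (val_obs.X - mu) / sd_safe
    Xva[:, dead] = 0.0
    Ytr, Yva = train_obs.Y, val_obs.Y

    sizes = [Xtr.shape[1], *spec.hidden, spec.n_outputs]
    weights = [
        rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(b) for b in sizes[1:]]
    params = weights + biases
    opt = _Adadelta(params, spec.rho, spec.eps)

    best_loss = np.inf
    best_weights = [W.copy() for W in weights]
    best_biases = [b.copy() for b in biases]
    best_epoch = 0
    train_trace: list[float] = []
    val_trace: list[float] = []
    n = Xtr.shape[0]
    bs = min(spec.minibatch, n)

    for epoch in range(spec.epoch_cap):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            ix = order[start : start + bs]
            Xb, Yb = Xtr[ix], Ytr[ix]
            acts = _forward(Xb, weights, biases, spec.dropout, rng)
            pred = acts[-1]
            diff = pred - Yb
            dist = np.linalg.norm(diff, axis=1, keepdims=True)
            epoch_loss += float(dist.sum())
            # d(mean ||pred - y||)/dpred
            delta = diff / np.maximum(dist, 1e-12) / len(ix)
            gw: list[np.ndarray] = [None] * len(weights)  # type: ignore
            gb: list[np.ndarray] = [None] * len(biases)   # type: ignore
            for l in range(len(weights) - 1, -1, -1):
                gw[l] = acts[l].T @ delta
                gb[l] = delta.sum(axis=0)
                if l > 0:
                    delta = (delta @ weights[l].T) * (acts[l] > 0)
            opt.step(params, gw + gb)
        train_trace.append(epoch_loss / n)

        val_pred = _forward(Xva, weights, biases)[-1]
        vloss = euclidean_loss(val_pred, Yva)
        val_trace.append(vloss)
        if vloss < best_loss:
            best_loss = vloss
            best_epoch = epoch
            best_weights = [W.copy() for W in weights]
            best_biases = [b.copy() for b in biases]
        elif epoch - best_epoch >= spec.patience:
            break

    return TrainedModel(
        weights=best_weights,
        biases=best_biases,
        gene_names=list(train_obs.gene_names),
        dead_genes=[g for g, d in zip(train_obs.gene_names, dead) if d],
        train_trace=train_trace,
        val_trace=val_trace,
        best_val_loss=best_loss,
        rep=rep,
        fold=fold,
    )


# ---------------------------------------------------------------------------
# Variable importance and consensus
# ---------------------------------------------------------------------------


def gedeon_vip(model: TrainedModel) -> dict[str, float]:
    """Gedeon weight-path importance per input gene.

    Per layer, contribution C[i, j] = |W[i, j]| / sum_i' |W[i', j]| (all-zero
    columns give zero contributions); the chained product C(1)...C(L) maps
    inputs to outputs and a gene's VIP is its row sum over the outputs.
    Biases and dropout are ignored.
    """
    if len(model.weights) < 2:
        raise DataError("Gedeon VIP needs at least one hidden layer")
    P: np.ndarray | None = None
    for W in model.weights:
        A = np.abs(W)
        col = A.sum(axis=0, keepdims=True)
        C = np.divide(A, col, out=np.zeros_like(A), where=col > 0)
        P = C if P is None else P @ C
    vip = P.sum(axis=1)
    return dict(zip(model.gene_names, vip.astype(float)))


def consensus_select(
    models: list[TrainedModel],
    vips: list[dict[str, float]],
    n_features: int,
    restrict_to: GeneList | list[str] | None = None,
) -> FeatureRanking:
    """Vote-based consensus: a gene's vote is the number of models in which
    it lands in that model's top-N eligible genes by VIP; ties break by mean
    per-model VIP rank, then gene name."""
    if not models:
        raise DataError("need at least one model")
    allowed = set(restrict_to) if restrict_to is not None else None
    votes: dict[str, int] = {}
    rank_sums: dict[str, list[float]] = {}
    vip_sums: dict[str, list[float]] = {}
    for model, vip in zip(models, vips):
        dead = set(model.dead_genes)
        eligible = [
            g for g in model.gene_names
            if g not in dead and (allowed is None or g in allowed)
        ]
        order = sorted(eligible, key=lambda g: (-vip[g], g))
        for rank, g in enumerate(order, start=1):
            rank_sums.setdefault(g, []).append(rank)
            vip_sums.setdefault(g, []).append(vip[g])
        for g in order[:n_features]:
            votes[g] = votes.get(g, 0) + 1
    mean_rank = {g: float(np.mean(r)) for g, r in rank_sums.items()}
    mean_vip = {g: float(np.mean(v)) for g, v in vip_sums.items()}
    ordered = sorted(votes, key=lambda g: (-votes[g], mean_rank[g], g))
    kept = ordered[: min(n_features, len(ordered))]
    return FeatureRanking(
        genes=kept,
        target_size=n_features,
        stability={g: float(votes[g]) for g in kept},
        score={g: mean_vip[g] for g in kept},
    )


def nested_selections(ranking: FeatureRanking, sizes: list[int]) -> dict[int, GeneList]:
    """Prefixes of one consensus ordering, guaranteeing top-20 within top-40
    within top-60 style nesting."""
    return {s: GeneList(ranking.genes[: min(s, len(ranking.genes))], s) for s in sizes}


def nn_weak_select(
    expr: ExpressionMatrix,
    atlas: SpatialBinAtlas,
    mcc_map: MccMap,
    n_features: int,
    tau: float = DEFAULT_TAU,
    r_thresh: float = DEFAULT_R_THRESH,
    k: int = 5,
    reps: int = 4,
    spec: NetworkSpec = NetworkSpec(),
    restrict_to: GeneList | list[str] | None = None,
    seed: int = 0,
    grouped: bool = True,
) -> tuple[FeatureRanking, list[TrainedModel]]:
    """Full ensemble pipeline: weak labels, per-fold correlated-gene filter,
    cell-grouped k-fold splits, k * reps trained networks, Gedeon VIPs and a
    consensus vote.

    ``grouped=False`` (row-wise observation splits) exists only as a
    leakage diagnostic and is refused here; use
    :func:`rowwise_split_validation_loss` to measure its effect.
    """
    if not grouped:
        raise DataError("row-wise splits leak weak-label rows; use grouped=True")
    obs = build_weak_training_set(mcc_map, atlas, expr, tau)
    folds_per_rep = grouped_kfold(list(expr.cell_names), k, reps, seed)
    seed_seq = np.random.SeedSequence(seed)
    model_seeds = seed_seq.generate_state(k * len(folds_per_rep))

    models: list[TrainedModel] = []
    vips: list[dict[str, float]] = []
    i = 0
    for rep, folds in enumerate(folds_per_rep):
        for fold_id, val_cells in enumerate(folds):
            val_set = set(val_cells)
            train_set = set(expr.cell_names) - val_set
            train_expr = expr.subset_cells(sorted(train_set))
            retained = filter_correlated_genes(train_expr, atlas.gene_names, r_thresh)
            tr = obs.subset_cells(train_set).subset_genes(retained)
            va = obs.subset_cells(val_set).subset_genes(retained)
            model = train_network(
                tr, va, spec, seed=int(model_seeds[i] % (2**31)), rep=rep, fold=fold_id
            )
            models.append(model)
            vips.append(gedeon_vip(model))
            i += 1
    ranking = consensus_select(models, vips, n_features, restrict_to)
    return ranking, models


def rowwise_split_validation_loss(
    obs: Observations,
    frac_val: float,
    spec: NetworkSpec,
    seed: int,
    grouped: bool,
) -> float:
    """Validation loss of one network under a grouped (by cell) or naive
    row-wise split of the same observations; the row-wise number is
    optimistically biased and exists to demonstrate that leakage."""
    rng = np.random.default_rng(seed)
    if grouped:
        cells = sorted(set(obs.cells))
        perm = rng.permutation(len(cells))
        n_val = max(1, int(len(cells) * frac_val))
        val_cells = {cells[i] for i in perm[:n_val]}
        tr = obs.subset_cells(set(cells) - val_cells)
        va = obs.subset_cells(val_cells)
    else:
        perm = rng.permutation(obs.n_obs)
        n_val = max(1, int(obs.n_obs * frac_val))
        vix, tix = perm[:n_val], perm[n_val:]
        # deliberately ignores cell identity: weak-label rows of one cell can
        # land on both sides (the leakage under study)
        tr = Observations(obs.X[tix], obs.Y[tix],
                          [obs.cells[i] for i in tix], list(obs.gene_names))
        va = Observations(obs.X[vix], obs.Y[vix],
                          [obs.cells[i] for i in vix], list(obs.gene_names))
        shared = set(tr.cells) & set(va.cells)
        # bypass the guard in train_network by renaming validation cells
        va = Observations(va.X, va.Y, [f"row_{i}" for i in range(va.n_obs)],
                          list(va.gene_names))
        logger.info("row-wise split shares %d cells between partitions", len(shared))
    model = train_network(tr, va, spec, seed=seed)
    return model.best_val_loss
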