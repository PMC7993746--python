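"""Stage 2 of panel construction: feature selection, Gene-Scores, weights.

Candidate genes are binarized into Gene-Scores (score 1 = the prognostically
favorable expression state, chosen by the direction of the gene's median-split
hazard ratio). A random forest classifying 3-year vital status ranks the
binary features by mean decrease in node impurity averaged over stratified
cross-validation folds; selected genes feed a small fixed feed-forward
network (inputs -> 4 ReLU -> 2 ReLU -> 2 softmax) trained with Adam on
cross-entropy. Each gene's weight is a norm of its outgoing first-layer
weights, and the assembled panel is score-direction + weight per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import GenePanel, MpsValidationError, PanelGene
from .screen import ScreenResult

logger = logging.getLogger(__name__)


@dataclass
class RfConfig:
    n_trees: int = 500
    max_depth: int = 10
    n_folds: int = 10
    importance_cutoff: float = 0.5  # raw averaged impurity-decrease scale
    top_k: int | None = None  # if set, select the k most important genes instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise MpsValidationError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise MpsValidationError("n_folds must be >= 2")
        if self.max_depth < 1:
            raise MpsValidationError("max_depth must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise MpsValidationError("top_k must be >= 1 when given")


def _raw_forest_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Mean over trees of the unnormalized weighted impurity decrease."""
    imp = [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_]
    return np.mean(imp, axis=0)


def rf_select_features(
    score_matrix: pd.DataFrame, labels: pd.Series, config: RfConfig | None = None
) -> pd.DataFrame:
    """Rank genes by impurity importance averaged over stratified CV folds.

    score_matrix: genes x samples binary Gene-Scores. labels: binary vital
    status (alive=0, deceased=1) indexed by sample id; samples with unknown
    status must be excluded upstream. Returns a DataFrame indexed by symbol
    with columns importance and selected, deterministic given config.seed.
    """
    config = config or RfConfig()
    labels = labels.loc[[s for s in score_matrix.columns if s in labels.index]]
    X = score_matrix[labels.index].to_numpy(dtype=float).T  # samples x genes
    y = labels.to_numpy(dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise MpsValidationError("labels contain a single class; cannot train a classifier")
    if len(y) < config.n_folds or counts.min() < config.n_folds:
        raise MpsValidationError(
            f"too few samples per class for {config.n_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    fold_imp = []
    for k, (train_idx, _test_idx) in enumerate(skf.split(X, y)):
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=config.seed + k,
            n_jobs=1,
        )
        forest.fit(X[train_idx], y[train_idx])
        fold_imp.append(_raw_forest_importance(forest))
    importance = np.mean(fold_imp, axis=0)
    out = pd.DataFrame(
        {"importance": importance}, index=pd.Index(score_matrix.index, name="symbol")
    )
    if config.top_k is not None:
        k = min(config.top_k, len(out))
        thresh = out["importance"].nlargest(k).min()
        out["selected"] = out["importance"] >= thresh
        # deterministic tie-break: keep first k in importance-then-index order
        ranked = out.sort_values("importance", ascending=False, kind="stable").index[:k]
        out["selected"] = out.index.isin(ranked)
    else:
        out["selected"] = out["importance"] >= config.importance_cutoff
    return out


def assign_gene_scores(
    expr_values: pd.DataFrame,
    screen: ScreenResult | pd.DataFrame,
    genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Binarize expression into Gene-Scores for the given genes.

    Score 1 marks the prognostically favorable state: for a gene whose
    median-split HR < 1 (high expression protective) samples above the median
    score 1 (score_high = 1); for HR > 1 samples at or below the median score
    1 (score_low = 1). Ties at the median fall in the low-expression state.
    HR exactly 1 is tie-broken to score_low = 1 and logged.

    Returns (score matrix genes x samples, directions frame with
    score_high/score_low per gene, median cutoffs).
    """
    table = screen.table if isinstance(screen, ScreenResult) else screen
    missing = [g for g in genes if g not in table.index or g not in expr_values.index]
    if missing:
        raise MpsValidationError(f"genes without screen result or expression: {missing}")
    scores = {}
    directions = {}
    cutoffs = {}
    for g in genes:
        hr = float(table.loc[g, "hr"])
        cutoff = float(table.loc[g, "median_cutoff"])
        high = (expr_values.loc[g] > cutoff).astype(int)
        if hr < 1.0:
            score_high, score_low = 1, 0
            scores[g] = high
        else:
            if hr == 1.0:
                logger.warning("%s: HR exactly 1; tie-broken to favorable = low state", g)
            score_high, score_low = 0, 1
            scores[g] = 1 - high
        directions[g] = {"score_high": score_high, "score_low": score_low}
        cutoffs[g] = cutoff
    score_matrix = pd.DataFrame(scores).T.loc[genes]
    score_matrix.index.name = "symbol"
    dir_frame = pd.DataFrame(directions).T.loc[genes].astype(int)
    return score_matrix, dir_frame, pd.Series(cutoffs).loc[genes]


# ---------------------------------------------------------------------------
# neural network


@dataclass
class NnConfig:
    hidden_sizes: tuple[int, int] = (4, 2)
    learning_rate: float = 0.001
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise MpsValidationError("learning_rate must be positive")
        if self.epochs < 1:
            raise MpsValidationError("epochs must be >= 1")
        if len(self.hidden_sizes) != 2 or any(h < 1 for h in self.hidden_sizes):
            raise MpsValidationError("hidden_sizes must be two positive layer widths")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NnModel:
    """Trained feed-forward net; output node 1 (y2) is P(death)."""

    weights: list[np.ndarray]  # W per layer, shape (in, out)
    biases: list[np.ndarray]
    gene_order: list[str]
    training_loss_trace: np.ndarray = field(repr=False)
    death_probability_output: int = 1

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for samples x genes input."""
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return _softmax(h @ self.weights[-1] + self.biases[-1])

    def death_probability(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[:, self.death_probability_output]


def train_nn(
    score_matrix: pd.DataFrame, labels: pd.Series, config: NnConfig | None = None
) -> NnModel:
    """Train the fixed-architecture net on Gene-Scores vs 3-year status.

    Full-batch Adam on the softmax cross-entropy E for exactly config.epochs
    epochs; the per-epoch loss trace is recorded. Deterministic given
    config.seed.
    """
    config = config or NnConfig()
    labels = labels.loc[[s for s in score_matrix.columns if s in labels.index]]
    if not set(np.unique(labels)) <= {0, 1}:
        raise MpsValidationError("labels must be binary (alive=0, deceased=1)")
    vals = score_matrix[labels.index].to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise MpsValidationError("score matrix must be binary")
    X = vals.T  # samples x genes
    y = labels.to_numpy(dtype=int)
    n, g = X.shape
    sizes = [g, *config.hidden_sizes, 2]
    rng = np.random.default_rng(config.seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        # forward
        acts = [X]
        h = X
        for W, b in zip(weights[:-1], biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = h @ weights[-1] + biases[-1]
        probs = _softmax(logits)
        loss = float(-np.mean(np.sum(onehot * np.log(np.clip(probs, 1e-12, None)), axis=1)))
        if not np.isfinite(loss):
            raise MpsValidationError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = loss
        # backward
        delta = (probs - onehot) / n
        grads_w = []
        grads_b = []
        for li in range(len(weights) - 1, -1, -1):
            grads_w.append(acts[li].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if li > 0:
                delta = (delta @ weights[li].T) * (acts[li] > 0)
        grads_w.reverse()
        grads_b.reverse()
        t = epoch + 1
        for li in range(len(weights)):
            m_w[li] = b1 * m_w[li] + (1 - b1) * grads_w[li]
            v_w[li] = b2 * v_w[li] + (1 - b2) * grads_w[li] ** 2
            weights[li] -= lr * (m_w[li] / (1 - b1**t)) / (np.sqrt(v_w[li] / (1 - b2**t)) + eps)
            m_b[li] = b1 * m_b[li] + (1 - b1) * grads_b[li]
            v_b[li] = b2 * v_b[li] + (1 - b2) * grads_b[li] ** 2
            biases[li] -= lr * (m_b[li] / (1 - b1**t)) / (np.sqrt(v_b[li] / (1 - b2**t)) + eps)

    return NnModel(
        weights=weights,
        biases=biases,
        gene_order=list(score_matrix.index),
        training_loss_trace=trace,
    )


def extract_gene_weights(model: NnModel, reduction: str = "l1") -> pd.Series:
    """Collapse each gene's outgoing first-layer weights to one scalar.

    reduction: "l1" (default, sum of absolute values), "l2", or "sum".
    A gene whose entire outgoing row is zero gets weight 0 and a warning;
    build_panel excludes such genes.
    """
    if not model.weights:
        raise MpsValidationError("model has no trained weights")
    W1 = model.weights[0]
    if reduction == "l1":
        w = np.abs(W1).sum(axis=1)
    elif reduction == "l2":
        w = np.sqrt((W1**2).sum(axis=1))
    elif reduction == "sum":
        w = W1.sum(axis=1)
    else:
        raise MpsValidationError(f"unknown reduction: {reduction!r}")
    out = pd.Series(w, index=pd.Index(model.gene_order, name="symbol"))
    zero = out.index[out == 0].tolist()
    if zero:
        logger.warning("genes with all-zero first-layer rows (weight 0): %s", zero)
    return out


def build_panel(
    genes: list[str],
    directions: pd.DataFrame,
    weights: pd.Series,
    provenance: str = "",
) -> GenePanel:
    """Assemble a GenePanel from aligned directions and weights."""
    if not genes:
        raise MpsValidationError("empty panel")
    missing_d = [g for g in genes if g not in directions.index]
    missing_w = [g for g in genes if g not in weights.index]
    if missing_d or missing_w:
        raise MpsValidationError(
            f"misaligned inputs: no direction for {missing_d}, no weight for {missing_w}"
        )
    entries = []
    for g in genes:
        w = float(weights.loc[g])
        if w <= 0:
            logger.warning("%s: non-positive weight %.4g, excluded from panel", g, w)
            continue
        entries.append(
            PanelGene(
                symbol=g,
                score_high=int(directions.loc[g, "score_high"]),
                score_low=int(directions.loc[g, "score_low"]),
                weight=w,
            )
        )
    if not entries:
        raise MpsValidationError("empty panel: no gene has a positive weight")
    return GenePanel(entries, provenance=provenance)
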