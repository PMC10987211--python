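"""Training loop, repeated k-fold cross-validation, metric panel, and the
reverse-rank comprehensive score used to compare models.

The classification panel is the confusion-matrix family TPR / TNR / PRE /
ACC / F1 / MCC plus the threshold-free AUC (Mann-Whitney rank estimator,
ties get half credit) and AP (area under the precision-recall curve);
regression uses R2 / MAE / RMSE. A metric whose denominator vanishes is
reported as NaN and listed under ``undefined`` rather than silently set
to zero.

Model comparison: within every (dataset, metric) cell the models are ranked
in reverse order — the best value receives the largest rank, ties get the
mean of the tied ranks, and error metrics (MAE, RMSE) rank ascending. A
model's comprehensive score is its mean rank over all cells; higher is
better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import KFold, StratifiedKFold

from .autodiff import Adam, Tensor
from .featurization import MolGraph, batch_graphs, parse_smiles
from .model_builder import GNNModel, ModelSpec, build_model

CLASSIFICATION_METRICS = ["ACC", "AP", "F1", "MCC", "AUC", "TPR", "TNR", "PRE"]
REGRESSION_METRICS = ["R2", "MAE", "RMSE"]

#: Metrics for which smaller values are better (ranked ascending).
LOWER_IS_BETTER = {"MAE", "RMSE"}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_score(labels, scores) -> float:
    """AUC via the Mann-Whitney rank statistic; tied scores get 0.5 credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def classification_metrics(tn: int, fp: int, fn: int, tp: int,
                           scores=None, labels=None) -> dict:
    """Confusion-matrix metric panel, optionally with AUC/AP from scores.

    Returns a dict with the metric values plus an ``undefined`` list naming
    any metric whose denominator was zero (reported as NaN, never as 0).
    """
    for c in (tn, fp, fn, tp):
        if c < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tn + fp + fn + tp
    if total == 0:
        raise ValueError("empty confusion matrix")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out = {
        "ACC": (tp + tn) / total,
        "TPR": _safe_div(tp, tp + fn),
        "TNR": _safe_div(tn, tn + fp),
        "PRE": _safe_div(tp, tp + fp),
        "F1": _safe_div(2 * tp, 2 * tp + fp + fn),
        "MCC": _safe_div(tp * tn - fp * fn, mcc_den),
    }
    if scores is not None:
        if labels is None:
            raise ValueError("labels are required alongside scores")
        out["AUC"] = auc_score(labels, scores)
        labels = np.asarray(labels)
        out["AP"] = (average_precision_score(labels, scores)
                     if 0 < labels.sum() < labels.size else math.nan)
    out["undefined"] = sorted(k for k, v in out.items()
                              if isinstance(v, float) and math.isnan(v))
    return out


def panel_from_predictions(y_true, scores, threshold: float = 0.5) -> dict:
    """Full classification panel from probabilities at a decision threshold."""
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    out = classification_metrics(tn, fp, fn, tp, scores=scores, labels=y_true)
    out.update({"TN": tn, "FP": fp, "FN": fn, "TP": tp})
    return out


def regression_metrics(y, yhat) -> dict:
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    resid = y - yhat
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    out = {
        "R2": 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan,
        "MAE": float(np.abs(resid).mean()),
        "RMSE": float(np.sqrt((resid**2).mean())),
    }
    out["undefined"] = ["R2"] if ss_tot == 0 else []
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(model: GNNModel, graphs: list[MolGraph], y, *,
                epochs: int = 60, lr: float = 5e-3, batch_size: int = 64,
                seed: int = 0, verbose: bool = False) -> list[float]:
    """Fit a model in place with Adam; returns the per-epoch mean loss.

    Binary cross-entropy on the logits for classification (computed through
    a numerically stable softplus form), mean squared error for regression.
    """
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    n = len(graphs)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            yb = Tensor(y[idx])
            logits = model.forward_logits(batch)
            if model.spec.task == "binary_classification":
                # mean(softplus(z) - y*z) == mean BCE-with-logits
                loss = (logits.softplus() - yb * logits).mean()
            else:
                diff = logits - yb
                loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
        if verbose:
            print(f"epoch {len(losses):3d}  loss {losses[-1]:.4f}")
    return losses


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-fold, per-repeat metric panel for one model on one dataset."""

    model_name: str
    dataset_name: str
    rows: pd.DataFrame  # columns: repeat, fold, <metrics>
    seed: int
    fold_assignments: list[np.ndarray] = field(default_factory=list)

    def means(self) -> pd.Series:
        return self.rows.drop(columns=["repeat", "fold"]).mean()

    def stds(self) -> pd.Series:
        return self.rows.drop(columns=["repeat", "fold"]).std()


def _resolve_graphs(dataset) -> tuple[list[MolGraph], np.ndarray]:
    """Accept a list of (smiles, label) pairs or (graphs, labels)."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        graphs, labels = dataset
        return list(graphs), np.asarray(labels, dtype=np.float64)
    records = getattr(dataset, "records", dataset)
    graphs = [parse_smiles(s) for s, _ in records]
    labels = np.asarray([lab for _, lab in records], dtype=np.float64)
    return graphs, labels


def kfold_cross_validate(dataset, spec: ModelSpec, k: int = 5,
                         repeats: int = 5, seed: int = 0, *,
                         epochs: int = 60, lr: float = 5e-3,
                         batch_size: int = 64,
                         dataset_name: str = "dataset",
                         model_factory=None) -> MetricReport:
    """Repeated k-fold cross-validation of one model spec.

    Folds are stratified for classification; every example lands in exactly
    one test fold per repeat, and the whole procedure is a pure function of
    ``seed``. ``model_factory(spec, seed) -> fitted-model-interface`` allows
    external (non-GNN) models through the same protocol; it must return an
    object with ``fit(graphs, y)`` and ``predict(graphs)``.
    """
    graphs, y = _resolve_graphs(dataset)
    n = len(graphs)
    if n < k:
        raise ValueError(f"dataset of {n} examples cannot be split into {k} folds")
    classification = spec.task == "binary_classification"
    if classification and len(np.unique(y)) < 2:
        raise ValueError("classification dataset must contain both classes")

    seeds = np.random.SeedSequence(seed).generate_state(repeats * k * 2)
    rows, assignments = [], []
    for rep in range(repeats):
        rep_seed = int(seeds[rep * k] % (2**31))
        if classification:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            split_iter = splitter.split(np.zeros(n), y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
            split_iter = splitter.split(np.zeros(n))
        fold_of = np.empty(n, dtype=np.intp)
        for fold, (train_idx, test_idx) in enumerate(split_iter):
            fold_of[test_idx] = fold
            if classification and len(np.unique(y[train_idx])) < 2:
                raise ValueError(
                    f"fold {fold} of repeat {rep}: a class is absent from the "
                    "training split")
            fit_seed = int(seeds[rep * k + fold] % (2**31))
            train_graphs = [graphs[i] for i in train_idx]
            test_graphs = [graphs[i] for i in test_idx]
            if model_factory is not None:
                model = model_factory(spec, fit_seed)
                model.fit(train_graphs, y[train_idx])
                scores = np.asarray(model.predict(test_graphs), dtype=np.float64)
            else:
                model = build_model(replace(spec, seed=fit_seed))
                train_model(model, train_graphs, y[train_idx], epochs=epochs,
                            lr=lr, batch_size=batch_size, seed=fit_seed)
                scores = model.predict(test_graphs)
            if classification:
                panel = panel_from_predictions(y[test_idx], scores)
                row = {m: panel[m] for m in CLASSIFICATION_METRICS}
            else:
                resid = y[test_idx] - scores
                ss_tot = float(((y[test_idx] - y[test_idx].mean()) ** 2).sum())
                row = {  # R2 undefined on constant/singleton test folds
                    "R2": 1.0 - float((resid**2).sum()) / ss_tot
                          if ss_tot > 0 else math.nan,
                    "MAE": float(np.abs(resid).mean()),
                    "RMSE": float(np.sqrt((resid**2).mean())),
                }
            rows.append({"repeat": rep, "fold": fold, **row})
        assignments.append(fold_of)
    return MetricReport(
        model_name=spec.config.name, dataset_name=dataset_name,
        rows=pd.DataFrame(rows), seed=seed, fold_assignments=assignments,
    )


# ---------------------------------------------------------------------------
# comprehensive score
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Reverse-rank matrix and per-model comprehensive scores."""

    ranks: pd.DataFrame     # index: model, columns: (dataset, metric)
    scores: pd.Series       # per-model mean rank, descending order

    def best(self) -> str:
        return str(self.scores.idxmax())


def comprehensive_score(reports: list[MetricReport]) -> RankTable:
    """Rank models within every (dataset, metric) cell and average.

    The best value in a cell receives the largest rank number (reverse
    ranking); MAE and RMSE rank ascending since smaller is better; ties get
    the mean of the tied ranks. All models must cover the same cells.
    """
    cells: dict[tuple[str, str], dict[str, float]] = {}
    models: list[str] = []
    for rep in reports:
        if rep.model_name not in models:
            models.append(rep.model_name)
        for metric, value in rep.means().items():
            cells.setdefault((rep.dataset_name, str(metric)), {})[rep.model_name] = value
    missing = [(ds, m, model) for (ds, m), vals in cells.items()
               for model in models if model not in vals]
    if missing:
        raise ValueError(f"missing (dataset, metric, model) cells: {missing}")

    rank_cols = {}
    for (ds, metric), vals in sorted(cells.items()):
        v = np.array([vals[m] for m in models], dtype=np.float64)
        if metric in LOWER_IS_BETTER:
            v = -v
        rank_cols[(ds, metric)] = rankdata(v)  # largest value -> largest rank
    ranks = pd.DataFrame(rank_cols, index=models)
    ranks.columns = pd.MultiIndex.from_tuples(ranks.columns,
                                              names=["dataset", "metric"])
    scores = ranks.mean(axis=1).sort_values(ascending=False)
    return RankTable(ranks=ranks, scores=scores)
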