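"""Dataset splitting, cross-validation, Adam training, hyperparameter grid
search, evaluation metrics and a reference-classifier comparison harness.

Splits and folds are always made at the subject level: the three replicate
measurements of one subject never straddle a train/test boundary, which is
what keeps the reported performance honest on repeated-measures data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import rankdata

from .nn.autodiff import Adam, Tensor
from .nn.losses import combined_loss
from .nn.model import ADENA, ModelConfig
from .signalprep import build_feature_table, fit_pca, project, standardize
from .synthcohort import BreathRecord

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "Confusion",
    "EvalReport",
    "split_dataset",
    "make_folds",
    "cross_validate_predictor",
    "cross_validate",
    "train",
    "grid_search",
    "mse",
    "f1_score",
    "accuracy",
    "confusion_counts",
    "roc_auc",
    "evaluate_predictions",
    "reference_classifiers",
    "DEFAULT_LR_GRID",
    "DEFAULT_EPOCH_GRID",
    "DEFAULT_BATCH_GRID",
]

# Grids explored on the device cohort, plus the 5e-4 value ultimately chosen
# (absent from the published candidate list).
DEFAULT_LR_GRID = (5e-3, 1e-3, 1e-4, 1e-1, 1e-2, 5e-4)
DEFAULT_EPOCH_GRID = (200, 500, 1000)
DEFAULT_BATCH_GRID = (2, 4)


class SplitSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    train_fraction: float = 0.6
    val_fraction: float = 0.3
    test_fraction: float = 0.1
    seed: int = 0
    stratified: bool = True

    @model_validator(mode="after")
    def _sums_to_one(self) -> "SplitSpec":
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train_fraction, self.val_fraction, self.test_fraction) < 0:
            raise ValueError("split fractions must be non-negative")
        return self


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    learning_rate: float = Field(default=5e-4, ge=0)
    epochs: int = Field(default=200, ge=1)
    batch_size: int = Field(default=4, ge=1)
    optimizer: Literal["adam"] = "adam"
    seed: int = 0


@dataclass(frozen=True)
class Confusion:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    accuracy: float
    f1: float
    mse: float
    auc: float
    confusion: Confusion
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mse": self.mse,
            "auc": self.auc,
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "threshold": self.threshold,
        }


# ---------------------------------------------------------------------------
# Metrics


def mse(y_actual: Sequence[float], y_predicted: Sequence[float]) -> float:
    """Mean squared error (1/N) sum (y - p)^2."""
    y = np.asarray(y_actual, dtype=float)
    p = np.asarray(y_predicted, dtype=float)
    if y.shape != p.shape:
        raise ValueError("mse: label and prediction lengths differ")
    if y.size == 0:
        raise ValueError("mse: empty input")
    return float(np.mean((y - p) ** 2))


def f1_score(confusion: Confusion) -> float:
    """Harmonic mean of precision and recall; 0 by convention when TP = 0."""
    tp, fp, fn = confusion.tp, confusion.fp, confusion.fn
    if tp + fp + fn == 0:
        raise ValueError("f1 undefined: no positive labels or predictions")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def accuracy(confusion: Confusion) -> float:
    if confusion.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    return (confusion.tp + confusion.tn) / confusion.total


def confusion_counts(y_actual, scores, threshold: float = 0.5) -> Confusion:
    y = np.asarray(y_actual).astype(int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return Confusion(
        tp=int(np.sum((y == 1) & (pred == 1))),
        tn=int(np.sum((y == 0) & (pred == 0))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == 0))),
    )


def roc_auc(y_actual, scores) -> tuple[float, pd.DataFrame]:
    """AUC via the rank (Mann-Whitney) statistic, ties counted 1/2, plus the
    ROC curve evaluated at every distinct threshold."""
    y = np.asarray(y_actual).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = [(s[y == 1] >= th).mean() for th in thresholds]
    fpr = [(s[y == 0] >= th).mean() for th in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return float(auc), curve


def evaluate_predictions(y_actual, scores, threshold: float = 0.5) -> EvalReport:
    confusion = confusion_counts(y_actual, scores, threshold)
    auc, _curve = roc_auc(y_actual, scores)
    return EvalReport(
        accuracy=accuracy(confusion),
        f1=f1_score(confusion),
        mse=mse(np.asarray(y_actual, dtype=float), scores),
        auc=auc,
        confusion=confusion,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Splitting


def _subject_labels(records: Sequence[BreathRecord]) -> tuple[list[str], np.ndarray]:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.subject_id in seen and seen[rec.subject_id] != rec.label:
            raise ValueError(f"subject {rec.subject_id} has inconsistent labels")
        seen[rec.subject_id] = rec.label
    subjects = sorted(seen)
    return subjects, np.array([seen[s] for s in subjects])


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items across fractions."""
    ideal = np.asarray(fractions, dtype=float) * n
    base = np.floor(ideal).astype(int)
    for _ in range(n - int(base.sum())):
        base[int(np.argmax(ideal - base))] += 1
    return base.tolist()


def split_dataset(
    records: Sequence[BreathRecord] | tuple[Sequence[str], Sequence[int]],
    spec: SplitSpec,
) -> tuple[list[str], list[str], list[str]]:
    """Subject-level random split into train/val/test at the spec fractions.

    Accepts either breath records or a pre-built (subjects, labels) pair.
    Stratification keeps each portion's class ratio within one subject of the
    cohort ratio.  Disjoint and exhaustive by construction.
    """
    if isinstance(records, tuple):
        subjects, labels = list(records[0]), np.asarray(records[1])
    else:
        subjects, labels = _subject_labels(records)
    if len(subjects) < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train_fraction, spec.val_fraction, spec.test_fraction)
    portions: list[list[str]] = [[], [], []]
    groups = (
        [np.flatnonzero(labels == v) for v in (1, 0)]
        if spec.stratified
        else [np.arange(len(subjects))]
    )
    for idx in groups:
        idx = rng.permutation(idx)
        counts = _allocate(len(idx), fractions)
        start = 0
        for portion, count in zip(portions, counts):
            portion.extend(subjects[i] for i in idx[start : start + count])
            start += count
    return tuple(sorted(p) for p in portions)  # type: ignore[return-value]


def make_folds(
    subjects: Sequence[str], labels: Sequence[int], k: int, seed: int = 0
) -> list[list[str]]:
    """k stratified subject-level folds (round-robin within each class)."""
    subjects = list(subjects)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = 0
    for value in (1, 0):
        idx = rng.permutation(np.flatnonzero(labels == value))
        for i in idx:
            folds[cursor % k].append(subjects[i])
            cursor += 1
    return [sorted(f) for f in folds]


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate_predictor(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    k: int,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    seed: int = 0,
    group_level: bool = True,
) -> list[EvalReport]:
    """Generic k-fold CV.  ``fit_predict(X_train, y_train, X_test) -> scores``.

    With ``group_level`` (the default) folds partition unique group ids
    (subjects); otherwise rows are folded naively — exposed only so leakage
    through repeated measures can be demonstrated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups)
    if group_level:
        uniq, first = np.unique(groups, return_index=True)
        fold_ids = make_folds(list(uniq), y[first], k, seed)
    else:
        rows = [str(i) for i in range(len(y))]
        fold_ids = make_folds(rows, y, k, seed)
        groups = np.asarray(rows)
    reports = []
    for held_out in fold_ids:
        test_mask = np.isin(groups, held_out)
        scores = fit_predict(X[~test_mask], y[~test_mask], X[test_mask])
        reports.append(evaluate_predictions(y[test_mask], scores))
    return reports


def _adena_fit_predict(
    model_config: ModelConfig | None,
    train_config: TrainConfig,
    variance_target: float = 0.95,
) -> Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]:
    """Standard classifier pipeline: standardize -> PCA (variance-weighted
    scores) -> ADENA, with all statistics learned on the training portion."""

    def fit_predict(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Z_tr, mean, sd, const = standardize(X_tr, return_stats=True)
        pca = fit_pca(Z_tr, variance_target=variance_target)
        S_tr = project(pca, Z_tr, weight_by_variance=True)
        Z_te = (np.asarray(X_te, dtype=float) - mean) / sd
        Z_te[:, const] = 0.0
        S_te = project(pca, Z_te, weight_by_variance=True)
        model, _history = train(model_config, (S_tr, y_tr), None, train_config)
        return model.predict_proba(S_te)

    return fit_predict


def cross_validate(
    records: Sequence[BreathRecord],
    k: int = 5,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> list[EvalReport]:
    """Subject-level stratified k-fold CV of the full classifier pipeline on
    a cohort of breath records; one EvalReport per held-out fold."""
    train_config = train_config or TrainConfig()
    features = build_feature_table(list(records))
    y = features["label"].to_numpy()
    X = features.drop(columns="label").to_numpy()
    subjects = features.index.to_numpy()
    return cross_validate_predictor(
        X, y, subjects, k, _adena_fit_predict(model_config, train_config), seed=seed
    )


# ---------------------------------------------------------------------------
# Training


def train(
    model_config: ModelConfig | None,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    train_config: TrainConfig | None = None,
) -> tuple[ADENA, pd.DataFrame]:
    """Adam training of the classifier on (X, y); returns the fitted model
    and a per-epoch history of train (and validation) loss.

    A fixed ``train_config.seed`` makes the run reproducible on one thread.
    Divergence (non-finite loss) aborts with a diagnostic.
    """
    cfg = train_config or TrainConfig()
    mcfg = model_config or ModelConfig()
    X, y = train_data
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) == 0:
        raise ValueError("train: empty training set")
    model = ADENA(mcfg, seed=cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs, _logits = model.forward(X[idx], mode="train", rng=rng)
            loss = combined_loss(y[idx], probs, gamma=mcfg.gamma)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_data is not None:
            val_probs = model.predict_proba(np.atleast_2d(val_data[0]))
            val_loss = combined_loss(
                np.asarray(val_data[1], dtype=float), val_probs, gamma=mcfg.gamma
            )
            history["val_loss"].append(float(val_loss))
        else:
            history["val_loss"].append(np.nan)
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Hyperparameter grid search


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    k: int = 5,
    model_config: ModelConfig | None = None,
    lr_grid: Sequence[float] = DEFAULT_LR_GRID,
    epoch_grid: Sequence[int] = DEFAULT_EPOCH_GRID,
    batch_grid: Sequence[int] = DEFAULT_BATCH_GRID,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrainConfig]:
    """Evaluate every (lr, epochs, batch) combination by k-fold mean F1.

    Ties break toward lower mean MSE, then fewer epochs.  Returns the full
    ranking (one row per combination) and the winning TrainConfig.
    Combinations that diverge score F1 = 0 with infinite MSE.
    """
    if not (len(lr_grid) and len(epoch_grid) and len(batch_grid)):
        raise ValueError("grid_search: all grids must be non-empty")
    rows = []
    for lr in lr_grid:
        for epochs in epoch_grid:
            for batch in batch_grid:
                cfg = TrainConfig(
                    learning_rate=lr, epochs=epochs, batch_size=batch, seed=seed
                )
                try:
                    reports = cross_validate_predictor(
                        X, y, groups, k, _adena_fit_predict(model_config, cfg), seed=seed
                    )
                    mean_f1 = float(np.mean([r.f1 for r in reports]))
                    mean_mse = float(np.mean([r.mse for r in reports]))
                    mean_acc = float(np.mean([r.accuracy for r in reports]))
                except RuntimeError:  # divergence
                    mean_f1, mean_mse, mean_acc = 0.0, float("inf"), 0.0
                rows.append(
                    {
                        "learning_rate": lr,
                        "epochs": epochs,
                        "batch_size": batch,
                        "mean_f1": mean_f1,
                        "mean_mse": mean_mse,
                        "mean_accuracy": mean_acc,
                    }
                )
    ranking = pd.DataFrame(rows).sort_values(
        by=["mean_f1", "mean_mse", "epochs"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    best = ranking.iloc[0]
    winner = TrainConfig(
        learning_rate=float(best["learning_rate"]),
        epochs=int(best["epochs"]),
        batch_size=int(best["batch_size"]),
        seed=seed,
    )
    return ranking, winner


# ---------------------------------------------------------------------------
# Reference-classifier comparison


def reference_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence[str],
    k: int = 5,
    seed: int = 0,
    adena_report: dict | None = None,
) -> pd.DataFrame:
    """Standard classifiers under the identical subject-level k-fold protocol.

    Library defaults throughout (recorded in the output for audit); a model
    that fails on degenerate features is recorded as failed and the run
    continues.  Optionally appends a pre-computed row for the neural model.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    models: dict[str, Callable[[], object]] = {
        "svm": lambda: SVC(probability=True, random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "logistic_regression": lambda: LogisticRegression(max_iter=1000, random_state=seed),
        "mlp": lambda: MLPClassifier(max_iter=2000, random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
    }
    rows = []
    for name, factory in models.items():
        def fit_predict(X_tr, y_tr, X_te, _factory=factory):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                Z_tr, mean, sd, const = standardize(X_tr, return_stats=True)
            Z_te = (np.asarray(X_te, dtype=float) - mean) / sd
            Z_te[:, const] = 0.0
            clf = _factory()
            clf.fit(Z_tr, y_tr)
            return clf.predict_proba(Z_te)[:, 1]

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports = cross_validate_predictor(X, y, groups, k, fit_predict, seed=seed)
            rows.append(
                {
                    "model": name,
                    "accuracy": float(np.mean([r.accuracy for r in reports])),
                    "f1": float(np.mean([r.f1 for r in reports])),
                    "mse": float(np.mean([r.mse for r in reports])),
                    "auc": float(np.mean([r.auc for r in reports])),
                    "failed": False,
                }
            )
        except Exception as err:  # degenerate features etc.
            rows.append(
                {
                    "model": name,
                    "accuracy": np.nan,
                    "f1": np.nan,
                    "mse": np.nan,
                    "auc": np.nan,
                    "failed": True,
                    "error": str(err),
                }
            )
    if adena_report is not None:
        rows.append({"model": "adena", "failed": False, **adena_report})
    return pd.DataFrame(rows)
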