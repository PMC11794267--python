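"""ANN classifier and stratified 5-fold cross-validation harness.

A feed-forward network with three hidden layers of 20 ReLU units, trained
with Adam for a fixed number of epochs (early stopping disabled), is the
single classifier used everywhere: per-feature ranking, reduction-method
comparison, and exhaustive subset search.  Cross-validation is stratified;
the column z-scorer (and, when used, the reduction method) is fit on the
training folds only, so no test statistics leak into training.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .features import Scaler, zscore_apply, zscore_fit

__all__ = ["ANNConfig", "CVReport", "train_ann", "evaluate_cv", "stratified_folds",
           "fast_profile"]


class TrainingError(ValueError):
    pass


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class ANNConfig:
    hidden_layers: int = 3
    neurons_per_layer: int = 20
    activation: str = "relu"
    max_iter: int = 1000
    learning_rate: float = 1e-3
    batch_size: int = 128       # capped at n_samples when training
    seed: int = 0

    def __post_init__(self):
        if self.hidden_layers < 1 or self.neurons_per_layer < 1 or self.max_iter < 1:
            raise TrainingError("layers, neurons and max_iter must all be >= 1")


def fast_profile(cfg: ANNConfig | None = None) -> ANNConfig:
    """Reduced-epoch profile for desk-scale runs (the architecture is unchanged)."""
    return replace(cfg or ANNConfig(), max_iter=150)


@dataclass
class CVReport:
    fold_accuracies: list
    mean_accuracy: float
    sd_accuracy: float
    n_samples: int
    n_classes: int
    train_seconds: float
    fold_indices: list = field(default_factory=list)  # test-row indices per fold

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy),
            "n_samples": int(self.n_samples),
            "n_classes": int(self.n_classes),
            "train_seconds": float(self.train_seconds),
        }


def train_ann(X: np.ndarray, y: np.ndarray, cfg: ANNConfig | None = None) -> MLPClassifier:
    """Train the fixed-architecture MLP; deterministic under cfg.seed."""
    cfg = cfg or ANNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("need at least 2 classes to train")
    model = MLPClassifier(
        hidden_layer_sizes=(cfg.neurons_per_layer,) * cfg.hidden_layers,
        activation=cfg.activation,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.max_iter,
        batch_size=min(cfg.batch_size, len(y)),
        random_state=cfg.seed,
        early_stopping=False,
        n_iter_no_change=cfg.max_iter,   # run the full epoch budget
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def stratified_folds(y: np.ndarray, k: int = 5, seed: int = 0) -> list:
    """(train_idx, test_idx) pairs from a seeded stratified k-fold split."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise FoldError(
            f"smallest class has {counts.min()} samples; need >= {k} for {k}-fold CV"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def evaluate_cv(X: np.ndarray, y: np.ndarray, cfg: ANNConfig | None = None,
                k: int = 5, seed: int = 0, folds=None, reducer_factory=None,
                scale: bool = True, return_models: bool = False):
    """Stratified k-fold CV of the ANN, with per-fold scaling and reduction.

    ``reducer_factory`` (optional) is called once per fold and must return an
    object with ``fit(X_train, y_train)`` and ``transform(X)``; it sees only
    the training fold.  Pass precomputed ``folds`` to share one fold
    assignment across many evaluations.
    """
    cfg = cfg or ANNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    accs, models, fold_idx = [], [], []
    t0 = time.perf_counter()
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        if scale:
            sc = zscore_fit(Xtr)
            Xtr, Xte = zscore_apply(Xtr, sc), zscore_apply(Xte, sc)
        if reducer_factory is not None:
            red = reducer_factory()
            red.fit(Xtr, y[tr])
            Xtr, Xte = red.transform(Xtr), red.transform(Xte)
        model = train_ann(Xtr, y[tr], cfg)
        accs.append(float(np.mean(model.predict(Xte) == y[te])))
        fold_idx.append(np.asarray(te))
        if return_models:
            models.append(model)
    seconds = time.perf_counter() - t0
    report = CVReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        n_samples=len(y),
        n_classes=len(np.unique(y)),
        train_seconds=seconds,
        fold_indices=fold_idx,
    )
    return (report, models) if return_models else report
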