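"""Class-weighted stratified k-fold cross-validation for the CNN-LSTM.

Each of the k folds holds out 10% of the windows for testing (k=10); 15% of
the remaining training windows are split off — again stratified — for
validation, giving the 76.5 / 13.5 / 10 train/validation/test proportions.
A fresh model is built per fold, trained with Adam for a fixed number of
epochs (no early stopping) with the data reshuffled before training and at
the end of every epoch, and class-imbalance is handled by inverse-frequency
loss weights.

Feature extraction and per-window normalization are stateless, so nothing
is fitted outside a fold's training data and no test-set leakage can occur
by construction.

Two profiles are conventional: the reference profile (300 epochs, batch 60,
learning rate 1e-4) and a desk-scale profile for synthetic-data checks
(tens of epochs on a few hundred windows) that differs only in epochs and
dataset size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import model as model_mod
from .evaluation import MetricsReport, compute_metrics, confusion_counts
from .features import WaveletConfig, concat_features
from .io import normalize_window
from .records import WindowedDataset

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CVResult",
    "stratified_folds",
    "class_weights",
    "extract_feature_matrix",
    "run_cv",
]


@dataclass(frozen=True)
class TrainConfig:
    """Cross-validation and optimizer settings.

    Defaults are the reference training recipe: 10 folds, validation split
    0.15, Adam at learning rate 1e-4, batch size 60, 300 epochs, per-epoch
    shuffling, inverse-frequency class weighting.
    """

    k_folds: int = 10
    val_split: float = 0.15
    lr: float = 1e-4
    batch_size: int = 60
    epochs: int = 300
    class_weighting: str = "inverse-frequency"  # or "none"
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 < self.val_split < 1.0:
            raise ValueError("val_split must be in (0, 1)")
        if self.class_weighting not in ("inverse-frequency", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size and epochs must be positive")

    def desk_scale(self, epochs: int = 30) -> "TrainConfig":
        return replace(self, epochs=epochs)


@dataclass
class FoldResult:
    fold_index: int
    history: dict[str, list[float]]
    test_indices: np.ndarray
    test_labels: np.ndarray
    test_predictions: np.ndarray
    metrics: MetricsReport
    split_sizes: tuple[int, int, int]  # train, val, test


@dataclass
class CVResult:
    folds: list[FoldResult]
    aggregate_mean: dict[str, float]
    aggregate_sd: dict[str, float]

    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.metrics.values["ACC"] for f in self.folds])


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint, stratified test-index sets partitioning ``range(n)``.

    Per-fold class proportions match the global proportions to within one
    sample.  Raises if any class has fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights: ``w_c = n_total / (n_classes * n_c)``.

    Balanced classes get weight 1; the weighted sample mass is equal across
    classes.  Raises on an empty class.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if np.any(counts == 0):
        raise ValueError("every class in [0, max(label)] must have >= 1 sample")
    n, k = len(labels), len(counts)
    return {c: n / (k * counts[c]) for c in range(k)}


def extract_feature_matrix(
    ds: WindowedDataset, cfg: WaveletConfig | None, fs: float = 256.0
) -> np.ndarray:
    """Per-window normalized DWT concat vectors as ``(n, length, 1)``.

    With ``cfg=None`` the raw normalized window is flattened channel-major
    instead (the without-DWT input geometry).  Both transforms are per
    window and involve no fitted state.
    """
    rows = []
    for w in ds.windows:
        wn = normalize_window(w)
        if cfg is None:
            rows.append(wn.ravel())
        else:
            rows.append(concat_features(wn, cfg, fs=fs).concat)
    x = np.asarray(rows)
    return x[:, :, None]


def run_cv(
    dataset: WindowedDataset,
    feature_cfg: WaveletConfig | None,
    cfg: TrainConfig,
    spec_factory: Callable[[int, int], model_mod.ModelSpec] | None = None,
    fs: float = 256.0,
    verbose: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of the CNN-LSTM on a dataset.

    ``spec_factory(input_length, n_classes)`` defaults to
    :func:`seizurekit.model.default_spec`; pass an ablated factory to train
    a variant on the same folds.  Returns per-fold histories, test
    predictions and metrics plus the mean and SD of every metric over folds.
    """
    if spec_factory is None:
        spec_factory = model_mod.default_spec
    x = extract_feature_matrix(dataset, feature_cfg, fs=fs)
    y = dataset.labels
    n_classes = dataset.n_classes
    weights = class_weights(y) if cfg.class_weighting == "inverse-frequency" else None

    folds: list[FoldResult] = []
    for fold_i, test_idx in enumerate(stratified_folds(y, cfg.k_folds, cfg.seed)):
        train_pool = np.setdiff1d(np.arange(len(y)), test_idx)
        tr_idx, val_idx = train_test_split(
            train_pool,
            test_size=cfg.val_split,
            stratify=y[train_pool],
            random_state=cfg.seed + fold_i,
        )
        spec = spec_factory(x.shape[1], n_classes)
        net = model_mod.build(spec, seed=cfg.seed * 1000 + fold_i)
        rng = np.random.default_rng(cfg.seed * 1000 + fold_i)
        history = net.fit(
            x[tr_idx],
            y[tr_idx],
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.lr,
            validation_data=(x[val_idx], y[val_idx]),
            class_weight=weights,
            shuffle_rng=rng if cfg.shuffle_each_epoch else np.random.default_rng(0),
            verbose=verbose,
        )
        pred = net.predict(x[test_idx])
        cm = confusion_counts(y[test_idx], pred, n_classes)
        folds.append(
            FoldResult(
                fold_index=fold_i,
                history=history,
                test_indices=test_idx,
                test_labels=y[test_idx],
                test_predictions=pred,
                metrics=compute_metrics(cm),
                split_sizes=(len(tr_idx), len(val_idx), len(test_idx)),
            )
        )

    keys = folds[0].metrics.values.keys()
    stacked = {k: np.array([f.metrics.values[k] for f in folds]) for k in keys}
    mean = {k: float(np.nanmean(v)) for k, v in stacked.items()}
    sd = {k: float(np.nanstd(v)) for k, v in stacked.items()}
    return CVResult(folds=folds, aggregate_mean=mean, aggregate_sd=sd)
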