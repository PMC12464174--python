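"""Classical-ML baselines and architecture ablations.

Baselines (SVC, KNN, Gaussian naive Bayes, decision tree, MLP) run on the
same stratified folds as the deep model — same seed, same partition — so
fold-paired statistical comparison is valid.  They consume one of four
feature sources: the DWT concat vector, per-channel time-domain statistics,
Welch-PSD frequency summaries, or the raw flattened window.

Three ablations probe the architecture, each a minimal surgery on the
reference network:

* ``no_dwt``  — the raw normalized window, flattened channel-major, feeds
  the unchanged network (no wavelet stage);
* ``no_lstm`` — the LSTM is removed and the final conv/pool output is
  flattened straight into the dense head;
* ``no_cnn``  — the DWT vector, as a (length, 1) sequence, feeds the
  200-unit LSTM directly, then the dense head.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import MetricsReport, compute_metrics, confusion_counts
from .features import WaveletConfig, concat_features, freq_domain_features, time_domain_features
from .io import normalize_window
from .model import LayerSpec, ModelSpec, default_spec, infer_shapes
from .records import WindowedDataset
from .training import CVResult, TrainConfig, run_cv, stratified_folds

__all__ = [
    "BaselineSpec",
    "BaselineResult",
    "BASELINE_NAMES",
    "FEATURE_SOURCES",
    "ABLATIONS",
    "baseline_features",
    "run_baseline",
    "ablated_spec",
    "run_ablation",
]

BASELINE_NAMES = ("SVC", "KNN", "GNB", "DT", "MLP")
FEATURE_SOURCES = ("dwt", "time_domain", "freq_domain", "raw")
ABLATIONS = ("no_dwt", "no_lstm", "no_cnn")


@dataclass(frozen=True)
class BaselineSpec:
    """A named classical classifier plus its feature source.

    ``hyperparameters`` are passed to the scikit-learn estimator; the
    defaults are the library defaults, frozen here (a fixed random_state
    for the stochastic MLP).
    """

    name: str
    feature_source: str = "dwt"
    hyperparameters: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}")
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(
                f"unknown feature source {self.feature_source!r}; "
                f"choose from {FEATURE_SOURCES}"
            )


def _make_estimator(spec: BaselineSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.name == "SVC":
        return SVC(**hp)
    if spec.name == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.name == "GNB":
        return GaussianNB(**hp)
    if spec.name == "DT":
        hp.setdefault("random_state", seed)
        return DecisionTreeClassifier(**hp)
    hp.setdefault("random_state", seed)
    return MLPClassifier(**hp)


def baseline_features(
    ds: WindowedDataset, source: str, fs: float = 256.0, wavelet: WaveletConfig | None = None
) -> np.ndarray:
    """Per-window feature rows for a baseline classifier (windows are
    z-scored per channel first, as for the deep model)."""
    wavelet = wavelet or WaveletConfig()
    rows = []
    for w in ds.windows:
        wn = normalize_window(w)
        if source == "dwt":
            rows.append(concat_features(wn, wavelet, fs=fs).concat)
        elif source == "time_domain":
            rows.append(time_domain_features(wn))
        elif source == "freq_domain":
            rows.append(freq_domain_features(wn, fs=fs))
        elif source == "raw":
            rows.append(wn.ravel())
        else:
            raise ValueError(f"unknown feature source {source!r}")
    return np.asarray(rows)


@dataclass
class BaselineResult:
    spec: BaselineSpec
    fold_metrics: list[MetricsReport]
    aggregate_mean: dict[str, float]
    aggregate_sd: dict[str, float]

    def fold_accuracies(self) -> np.ndarray:
        return np.array([m.values["ACC"] for m in self.fold_metrics])


def run_baseline(
    spec: BaselineSpec,
    dataset: WindowedDataset,
    cv: TrainConfig,
    fs: float = 256.0,
    wavelet: WaveletConfig | None = None,
) -> BaselineResult:
    """Cross-validate one classical baseline on the deep model's folds.

    The fold partition is :func:`seizurekit.training.stratified_folds` with
    the same ``(k, seed)``, so accuracies pair fold-by-fold with a
    :func:`seizurekit.training.run_cv` result for the same config.
    """
    x = baseline_features(dataset, spec.feature_source, fs=fs, wavelet=wavelet)
    y = dataset.labels
    n_classes = dataset.n_classes
    fold_metrics: list[MetricsReport] = []
    for fold_i, test_idx in enumerate(stratified_folds(y, cv.k_folds, cv.seed)):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        est = _make_estimator(spec, seed=cv.seed * 1000 + fold_i)
        est.fit(x[train_idx], y[train_idx])
        pred = est.predict(x[test_idx])
        fold_metrics.append(compute_metrics(confusion_counts(y[test_idx], pred, n_classes)))

    keys = fold_metrics[0].values.keys()
    stacked = {k: np.array([m.values[k] for m in fold_metrics]) for k in keys}
    return BaselineResult(
        spec=spec,
        fold_metrics=fold_metrics,
        aggregate_mean={k: float(np.nanmean(v)) for k, v in stacked.items()},
        aggregate_sd={k: float(np.nanstd(v)) for k, v in stacked.items()},
    )


def ablated_spec(which: str, input_length: int, n_classes: int = 2) -> ModelSpec:
    """Architecture variant with one component removed.

    ``input_length`` is the length the variant actually sees: the DWT
    concat length for ``no_lstm``/``no_cnn``, the raw flattened window
    length for ``no_dwt``.
    """
    if which == "no_dwt":
        # Same network; the caller feeds the raw normalized window.
        return default_spec(input_length, n_classes)
    if which == "no_lstm":
        base = default_spec(input_length, n_classes)
        layers = tuple(ls for ls in base.layers if ls.kind != "lstm")
        spec = ModelSpec(input_length=input_length, layers=layers, n_classes=n_classes)
        infer_shapes(spec)
        return spec
    if which == "no_cnn":
        head_units = 1 if n_classes == 2 else n_classes
        head_act = "sigmoid" if n_classes == 2 else "softmax"
        layers = (
            LayerSpec("lstm", units=200),
            LayerSpec("flatten"),
            LayerSpec("dense", units=64, l2=0.03, activation="relu"),
            LayerSpec("dropout", rate=0.4),
            LayerSpec("dense", units=head_units),
            LayerSpec("activation", activation=head_act),
        )
        spec = ModelSpec(input_length=input_length, layers=layers, n_classes=n_classes)
        infer_shapes(spec)
        return spec
    raise ValueError(f"unknown ablation {which!r}; choose from {ABLATIONS}")


def run_ablation(
    dataset: WindowedDataset,
    which: str | None,
    cfg: TrainConfig,
    fs: float = 256.0,
    wavelet: WaveletConfig | None = None,
) -> CVResult:
    """Cross-validate the full model (``which=None``) or an ablated variant
    on the same folds (shared ``cfg.seed``)."""
    wavelet = wavelet or WaveletConfig()
    if which is None:
        return run_cv(dataset, wavelet, cfg, fs=fs)
    if which == "no_dwt":
        return run_cv(dataset, None, cfg, fs=fs)
    if which in ("no_lstm", "no_cnn"):
        factory = lambda n, k: ablated_spec(which, n, k)  # noqa: E731
        return run_cv(dataset, wavelet, cfg, spec_factory=factory, fs=fs)
    raise ValueError(f"unknown ablation {which!r}; choose from {ABLATIONS}")
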