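"""Classifier-based assessment of condition effects across correction stages.

Two classifiers discriminate the two conditions from single trials:

* a compact CNN for EEG (temporal convolution band, grouped spatial
  filters, depthwise-separable integration, sigmoid head), built on the
  numpy backend in :mod:`erplat.nn`;
* a regularized logistic regression on flattened, standardized voltages —
  the linear baseline.

Assessment modes: overall 10-fold cross-validated accuracy on the whole
analysis epoch, sliding-window temporal decoding (120-ms windows moved in
4-ms steps, each point labeled by its window endpoint), and temporal
generalization (train on one window, test on all windows, same folds).
Fold splits are trial-level, stratified by condition and pooled over
subjects; an optional subject-grouped split is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from erplat import nn
from erplat.epochs_core import EpochSet

__all__ = [
    "ClassifierConfig",
    "DecodingResult",
    "GeneralizationMatrix",
    "build_eegnet",
    "train_classifier",
    "crossval_accuracy",
    "temporal_decoding",
    "temporal_generalization",
    "sliding_windows",
    "encode_labels",
    "binomial_chance_band",
]

ClassifierName = Literal["eegnet", "logistic"]


def default_temporal_length(input_samples: int) -> int:
    """Default temporal kernel length: half the input, rounded down to odd."""
    l1 = input_samples // 2
    if l1 % 2 == 0:
        l1 -= 1
    return max(l1, 3)


@dataclass
class ClassifierConfig:
    """Hyperparameters of the compact CNN (and shared training settings).

    ``k1`` temporal kernels, ``k2`` spatial kernels per temporal kernel
    (``k1 * k2`` spatial filters in total), temporal kernel length ``l1``
    (derived from the input length when ``None``), separable kernel length
    ``l2 = l1 // 2``.  Training: Adam with the configured learning rate and
    L2 weight decay, batch-normalized blocks, dropout in blocks 2-3.
    """

    k1: int = 4
    k2: int = 2
    l1: int | None = None
    channels: int | None = None
    dropout: float = 0.2
    weight_decay: float = 1e-3
    lr: float = 0.05
    n_epochs: int = 100
    batch_size: int = 64
    pool1: int = 4
    pool2: int = 8
    seed: int = 0

    @property
    def n_spatial_filters(self) -> int:
        return self.k1 * self.k2

    def l2_for(self, l1: int) -> int:
        return max(l1 // 2, 1)


@dataclass
class DecodingResult:
    """Cross-validated accuracy for one dataset/window."""

    fold_accuracies: np.ndarray
    stage: str = ""
    window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def t_statistic(self) -> float:
        return float(stats.ttest_1samp(self.fold_accuracies, 0.5).statistic)

    @property
    def p_value(self) -> float:
        """Two-sided one-sample t-test of fold accuracies against chance 0.5."""
        return float(stats.ttest_1samp(self.fold_accuracies, 0.5).pvalue)

    def p_value_corrected(self, alternative: str = "greater") -> float:
        """Corrected resampled t-test against chance (Nadeau-Bengio).

        The plain fold-wise t-test is liberal because the k training sets
        overlap; the corrected test inflates the variance estimate by the
        test/train ratio ``1/(k-1)``, restoring calibration.  Used for
        permutation-null calibration checks.
        """
        a = self.fold_accuracies
        k = a.shape[0]
        var = a.var(ddof=1)
        if var == 0:
            return 1.0 if a.mean() <= 0.5 else 0.0
        se = np.sqrt((1.0 / k + 1.0 / (k - 1)) * var)
        t = (a.mean() - 0.5) / se
        if alternative == "greater":
            return float(stats.t.sf(t, k - 1))
        if alternative == "two-sided":
            return float(2 * stats.t.sf(abs(t), k - 1))
        return float(stats.t.cdf(t, k - 1))


@dataclass
class GeneralizationMatrix:
    """Accuracy over (training window x generalization window)."""

    accuracy: np.ndarray  # (n_windows, n_windows), fold-averaged
    window_starts_ms: np.ndarray
    window_ends_ms: np.ndarray
    k: int

    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.accuracy,
            index=pd.Index(self.window_ends_ms, name="train_end_ms"),
            columns=pd.Index(self.window_ends_ms, name="gen_end_ms"),
        )


def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """0/1 encoding; class order is sorted label names (index 1 = positive)."""
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"binary classification needs 2 label values, got {classes}")
    return (labels == classes[1]).astype(int), classes


def binomial_chance_band(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided binomial confidence band around chance 0.5 for n trials."""
    lo = stats.binom.ppf(alpha / 2, n, 0.5) / n
    hi = stats.binom.ppf(1 - alpha / 2, n, 0.5) / n
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# model construction and training
# ---------------------------------------------------------------------------

def build_eegnet(cfg: ClassifierConfig, input_samples: int, n_channels: int | None = None) -> nn.Sequential:
    """Build the compact CNN for ``n_channels x input_samples`` trials.

    Block 1: ``k1`` temporal convolutions of size ``(1, l1)`` (same-padded
    along time), batch-normalized — learned temporal band-pass filters.
    Block 2: per temporal map, ``k2`` spatial convolutions of size ``(C, 1)``
    spanning all electrodes, batch norm, ELU, average pooling, dropout.
    Block 3: a depthwise ``(1, l2)`` convolution per feature map, a 1x1
    pointwise merge across all ``k1*k2`` maps, batch norm, ELU, pooling,
    dropout, flatten, and a single-logit sigmoid head.

    Pooling sizes are clipped so short inputs (sliding windows) keep at
    least one output sample.
    """
    n_channels = n_channels or cfg.channels
    if n_channels is None:
        raise ValueError("channel count required (cfg.channels or n_channels)")
    l1 = cfg.l1 or default_temporal_length(input_samples)
    if input_samples < l1:
        raise ValueError(f"input of {input_samples} samples is shorter than l1={l1}")
    l2 = cfg.l2_for(l1)
    f2 = cfg.k1 * cfg.k2
    rng = np.random.default_rng([int(cfg.seed), 0xC0FFEE])

    pool1 = max(1, min(cfg.pool1, input_samples))
    t_after1 = input_samples // pool1
    pool2 = max(1, min(cfg.pool2, t_after1))
    t_after2 = t_after1 // pool2

    layers = [
        nn.Conv2d(1, cfg.k1, (1, l1), pad_same_time=True, rng=rng),
        nn.BatchNorm2d(cfg.k1),
        nn.Conv2d(cfg.k1, f2, (n_channels, 1), groups=cfg.k1, bias=False, rng=rng),
        nn.BatchNorm2d(f2),
        nn.ELU(),
        nn.AvgPool2d(pool1),
        nn.Dropout(cfg.dropout, rng=np.random.default_rng([int(cfg.seed), 1])),
        nn.Conv2d(f2, f2, (1, min(l2, t_after1)), groups=f2, pad_same_time=True, bias=False, rng=rng),
        nn.Conv2d(f2, f2, (1, 1), rng=rng),
        nn.BatchNorm2d(f2),
        nn.ELU(),
        nn.AvgPool2d(pool2),
        nn.Dropout(cfg.dropout, rng=np.random.default_rng([int(cfg.seed), 2])),
        nn.Flatten(),
        nn.Dense(f2 * t_after2, 1, rng=rng),
    ]
    return nn.Sequential(layers)


def train_classifier(
    model: nn.Sequential,
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
) -> nn.Sequential:
    """Train the CNN with Adam on binary cross-entropy; deterministic per seed.

    ``X`` is ``(trials, channels, samples)`` (a leading map axis is added),
    ``y`` binary 0/1.  Aborts with diagnostics if the loss goes non-finite.
    """
    if X.ndim == 3:
        X = X[:, None, :, :]
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    opt = nn.Adam(model, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([int(cfg.seed), 3])
    n = X.shape[0]
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, dz = nn.bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"lr={cfg.lr}, |logits| max={np.max(np.abs(logits)):.3g}"
                )
            model.backward(dz)
            opt.step()
    return model


def _make_logistic(seed: int):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=500, C=1.0, random_state=seed),
    )


def _model_seed(seed: int, fold: int, win_start: int) -> int:
    return (int(seed) * 1000003 + fold * 9176 + win_start * 31 + 7) % (2**31)


def _fold_splits(labels, subjects, k, seed, grouped):
    y, _ = encode_labels(labels)
    if grouped:
        cv = GroupKFold(n_splits=k)
        return list(cv.split(np.zeros_like(y), y, groups=subjects))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    return list(cv.split(np.zeros_like(y), y))


def _fit_eval(
    classifier: ClassifierName,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: ClassifierConfig,
    seed: int,
):
    """Fit one classifier; returns a ``predict(X) -> 0/1`` callable."""
    if classifier == "logistic":
        clf = _make_logistic(seed)
        clf.fit(X_train.reshape(X_train.shape[0], -1), y_train)
        return lambda X: clf.predict(X.reshape(X.shape[0], -1))
    if classifier == "eegnet":
        cfg_fold = ClassifierConfig(**{**cfg.__dict__, "seed": seed})
        model = build_eegnet(cfg_fold, X_train.shape[-1], X_train.shape[-2])
        train_classifier(model, X_train, y_train, cfg_fold)
        return lambda X: (model.predict_proba(X[:, None, :, :]) > 0.5).astype(int)
    raise ValueError(f"unknown classifier {classifier!r}")


def crossval_accuracy(
    epochs: EpochSet,
    cfg: ClassifierConfig | None = None,
    k: int = 10,
    classifier: ClassifierName = "logistic",
    seed: int = 0,
    stage: str = "",
    grouped_by_subject: bool = False,
) -> DecodingResult:
    """Stratified k-fold cross-validated accuracy, pooled over subjects.

    Trials from all participants and conditions are pooled and split
    trial-level, stratified by condition (so both classes appear in every
    fold).  Returns per-fold test accuracies with a one-sample t-test
    against chance 0.5.
    """
    cfg = cfg or ClassifierConfig(seed=seed)
    y, _ = encode_labels(epochs.labels)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} trials per class, got {counts.tolist()}")
    splits = _fold_splits(epochs.labels, epochs.subjects, k, seed, grouped_by_subject)
    accs = []
    for fold, (tr, te) in enumerate(splits):
        predict = _fit_eval(
            classifier, epochs.data[tr], y[tr], cfg, _model_seed(seed, fold, 0)
        )
        accs.append(float(np.mean(predict(epochs.data[te]) == y[te])))
    window = (float(epochs.times[0]), float(epochs.times[-1] + 1000.0 / epochs.srate))
    return DecodingResult(np.array(accs), stage=stage, window_ms=window)


def sliding_windows(
    n_samples: int,
    srate: float,
    window_ms: float = 120.0,
    stride_ms: float = 4.0,
) -> tuple[np.ndarray, int]:
    """Start indices and sample length of the sliding windows.

    The stride is snapped to a whole number of samples (with a warning if it
    was not one already).  A ``[100, 1100)`` ms epoch at 250 Hz with 120/4 ms
    windows gives 221 windows of 30 samples.
    """
    w = int(round(window_ms * srate / 1000.0))
    stride_exact = stride_ms * srate / 1000.0
    stride = max(1, int(round(stride_exact)))
    if abs(stride_exact - stride) > 1e-9:
        warnings.warn(
            f"stride {stride_ms} ms is not a whole number of samples at {srate} Hz; "
            f"snapped to {stride} sample(s)",
            RuntimeWarning,
        )
    if w > n_samples:
        raise ValueError("window longer than the epoch")
    starts = np.arange(0, n_samples - w + 1, stride)
    return starts, w


def temporal_decoding(
    epochs: EpochSet,
    cfg: ClassifierConfig | None = None,
    window_ms: float = 120.0,
    stride_ms: float = 4.0,
    k: int = 10,
    classifier: ClassifierName = "logistic",
    seed: int = 0,
    stage: str = "",
) -> list[DecodingResult]:
    """Sliding-window decoding: cross-validated accuracy per time segment.

    Each segment's result is labeled by its window endpoint.  The fold
    splits and per-fold model seeds match :func:`temporal_generalization`,
    so the generalization diagonal reproduces this curve.
    """
    cfg = cfg or ClassifierConfig(seed=seed)
    starts, w = sliding_windows(epochs.n_samples, epochs.srate, window_ms, stride_ms)
    y, _ = encode_labels(epochs.labels)
    splits = _fold_splits(epochs.labels, epochs.subjects, k, seed, False)
    dt = 1000.0 / epochs.srate
    results = []
    for s in starts:
        sl = slice(s, s + w)
        accs = []
        for fold, (tr, te) in enumerate(splits):
            predict = _fit_eval(
                classifier, epochs.data[tr][:, :, sl], y[tr], cfg,
                _model_seed(seed, fold, int(s)),
            )
            accs.append(float(np.mean(predict(epochs.data[te][:, :, sl]) == y[te])))
        win = (float(epochs.times[s]), float(epochs.times[s + w - 1] + dt))
        results.append(DecodingResult(np.array(accs), stage=stage, window_ms=win))
    return results


def temporal_generalization(
    epochs: EpochSet,
    cfg: ClassifierConfig | None = None,
    window_ms: float = 120.0,
    stride_ms: float = 4.0,
    k: int = 10,
    classifier: ClassifierName = "logistic",
    seed: int = 0,
) -> GeneralizationMatrix:
    """Train on each window, test on every window; fold-averaged accuracy.

    Cell ``[i, j]`` is the accuracy of the model trained on window ``i``
    evaluated on window ``j`` of the held-out trials, averaged over the same
    stratified folds used for temporal decoding.  Below-chance off-diagonal
    cells flag time-shifted, pattern-reversed structure between conditions.
    """
    cfg = cfg or ClassifierConfig(seed=seed)
    starts, w = sliding_windows(epochs.n_samples, epochs.srate, window_ms, stride_ms)
    y, _ = encode_labels(epochs.labels)
    splits = _fold_splits(epochs.labels, epochs.subjects, k, seed, False)
    n_win = starts.shape[0]
    acc = np.zeros((n_win, n_win, len(splits)))
    for fold, (tr, te) in enumerate(splits):
        for i, s in enumerate(starts):
            sl = slice(s, s + w)
            predict = _fit_eval(
                classifier, epochs.data[tr][:, :, sl], y[tr], cfg,
                _model_seed(seed, fold, int(s)),
            )
            for j, s2 in enumerate(starts):
                pred = predict(epochs.data[te][:, :, s2 : s2 + w])
                acc[i, j, fold] = float(np.mean(pred == y[te]))
    dt = 1000.0 / epochs.srate
    return GeneralizationMatrix(
        accuracy=acc.mean(axis=2),
        window_starts_ms=epochs.times[starts],
        window_ends_ms=epochs.times[starts + w - 1] + dt,
        k=len(splits),
    )
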