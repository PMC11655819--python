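"""Saliency maps: which channels and time points drive the classifier.

For a fitted CNN the per-trial attribution of the output logit is computed
with the DeepLIFT rescale rule (default; gradient x input as fallback)
against an all-zero baseline — the average-referenced resting state.
Condition-level maps average the signed attributions of trials the model
classifies correctly with high confidence (predicted class probability
above 0.9), separately per condition, and combine them into one signed
``channels x samples`` map: positive values mark features supporting the
positive-class condition, negative values the other condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from erplat import nn
from erplat.decode import encode_labels
from erplat.epochs_core import EpochSet

__all__ = ["SaliencyMap", "attribute_trial", "condition_saliency_map"]


@dataclass
class SaliencyMap:
    """Signed channels x samples importance map for one dataset/stage.

    Positive scores support the positive-class condition (sorted-second
    label); negative scores the other.  ``n_trials_used`` records how many
    confidently-correct trials entered each condition's average.
    """

    importance: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials_used: dict[str, int]
    stage: str = ""
    p_threshold: float = 0.9
    method: str = "deeplift_rescale"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.importance)):
            raise ValueError("saliency map contains non-finite values")


def attribute_trial(
    model: nn.Sequential,
    trial: np.ndarray,
    method: str = "deeplift_rescale",
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Signed per-feature contribution of one trial to the output logit.

    ``trial`` is ``channels x samples``; the default baseline is an all-zero
    input.  ``deeplift_rescale`` distributes the logit difference to the
    input via the rescale rule (complete: contributions sum to
    ``logit(trial) - logit(baseline)``); ``gradient_x_input`` multiplies the
    local gradient by the input.
    """
    x = np.asarray(trial, dtype=np.float64)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    if method == "deeplift_rescale":
        ref = None if baseline is None else np.broadcast_to(baseline, x.shape).astype(float)
        attr = nn.deeplift_rescale(model, x, ref)
    elif method == "gradient_x_input":
        attr = nn.gradient_input(model, x)
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    return attr[0, 0]


def condition_saliency_map(
    model: nn.Sequential,
    epochs: EpochSet,
    p_threshold: float = 0.9,
    method: str = "deeplift_rescale",
    stage: str = "",
) -> SaliencyMap:
    """Average attributions over confidently, correctly classified trials.

    A trial enters its condition's average when the model assigns the true
    class a probability strictly greater than ``p_threshold``.  The two
    condition means (signed, not absolute) are averaged into one map; if one
    condition has no qualifying trial a warning is issued and the map uses
    the other side only.
    """
    y, classes = encode_labels(epochs.labels)
    probs_pos = model.predict_proba(epochs.data[:, None, :, :])
    p_true = np.where(y == 1, probs_pos, 1.0 - probs_pos)
    correct = (probs_pos > 0.5).astype(int) == y
    selected = correct & (p_true > p_threshold)

    cond_means: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for ci, cond in enumerate(classes):
        idx = np.flatnonzero(selected & (y == ci))
        n_used[cond] = int(idx.size)
        if idx.size == 0:
            warnings.warn(
                f"no trial of condition {cond!r} passed the p>{p_threshold} "
                "selection; that side of the map is empty",
                RuntimeWarning,
            )
            continue
        attrs = np.stack(
            [attribute_trial(model, epochs.data[i], method=method) for i in idx]
        )
        cond_means[cond] = attrs.mean(axis=0)

    if cond_means:
        importance = np.mean(np.stack(list(cond_means.values())), axis=0)
    else:
        importance = np.zeros((epochs.n_channels, epochs.n_samples))
    return SaliencyMap(
        importance=importance,
        times=epochs.times.copy(),
        channel_names=list(epochs.channel_names),
        n_trials_used=n_used,
        stage=stage,
        p_threshold=p_threshold,
        method=method,
    )
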