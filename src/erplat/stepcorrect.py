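"""Latency synchronization stages and the stepwise correction pipeline.

After the S/C/R decomposition (Step 1) three sources of latency variability
remain in the C-component trials, each removed by one stage:

* **Step 2** — within-condition jitter: every trial is shifted by the
  negative of its estimated latency lag, aligning trials to their template
  while preserving between-condition and between-subject latency
  differences.
* **Step 3** — between-condition shifts: per subject, both conditions'
  template peak latencies at a reference electrode (default ``Pz``) are
  synchronized to their median (= midpoint for two conditions) by a uniform
  per-condition shift.
* **Step 4** — between-subject shifts + amplitude normalization: all
  subjects are synchronized to the common median peak latency, then each
  trial is divided, time point by time point, by its global field power so
  that only the topography (the shape of the channel vector) remains.

``run_stepwise_pipeline`` materializes the five datasets handed to the
classifiers — Original, Step1..Step4 — all cropped to the analysis window
(default 100..1100 ms) only after shifting, so zero padding stays outside
the window the classifiers see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from erplat.epochs_core import (
    EpochSet,
    Template,
    assert_average_reference,
    average_erp,
    crop_epoch,
    gfp,
    shift_trial,
)
from erplat.ride import RideDecomposition, RideWindows, decompose_by_cell

__all__ = [
    "CorrectionResult",
    "PipelineConfig",
    "correct_within_condition",
    "template_peak_latency",
    "correct_between_conditions",
    "correct_between_subjects",
    "gfp_normalize",
    "run_stepwise_pipeline",
    "ms_to_samples",
]

STAGES = ("Original", "Step1", "Step2", "Step3", "Step4")


def ms_to_samples(ms: float, srate: float) -> int:
    """Convert a latency in ms to samples, rounding half away from zero."""
    x = ms * srate / 1000.0
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class CorrectionResult:
    """One pipeline stage: its dataset plus the bookkeeping of how it was made."""

    stage: str
    epochs: EpochSet
    applied_shifts: np.ndarray  # per-trial cumulative shift in samples
    reference_electrode: str | None = None
    peak_latencies: dict | None = None  # per subject (x condition) template peak ms
    normalization: Literal["none", "gfp"] = "none"


@dataclass
class PipelineConfig:
    """Knobs of the stepwise pipeline."""

    windows: RideWindows = field(default_factory=RideWindows)
    reference_electrode: str = "Pz"
    analysis_window: tuple[float, float] = (100.0, 1100.0)
    estimator: str = "median"
    max_lag_ms: float = 200.0
    latency_smooth_ms: float = 40.0
    max_iter: int = 10
    tol: float = 1e-3
    gfp_eps: float = 1e-12
    stages: tuple[str, ...] = STAGES
    per_trial_step3: bool = False  # per-trial peak picking instead of uniform shifts


def _shift_all(epochs: EpochSet, shifts: np.ndarray) -> EpochSet:
    n = epochs.n_samples
    if np.any(np.abs(shifts) >= n):
        raise ValueError("a latency shift exceeds the epoch length")
    data = np.stack(
        [shift_trial(tr, int(s)) if s else tr.copy() for tr, s in zip(epochs.data, shifts)]
    )
    return replace(epochs, data=data)


def correct_within_condition(step1: EpochSet, c_lags: np.ndarray) -> EpochSet:
    """Step 2: undo within-condition jitter by shifting each trial by ``-lag``.

    ``c_lags`` are the per-trial latency lags (samples) from the same
    decomposition, in the order of ``step1``'s trials.  A trial whose
    pattern occurs 50 ms late (lag +50 ms) is shifted 50 ms forward.
    Between-condition and between-subject latency differences are preserved
    (no recentering).
    """
    c_lags = np.asarray(c_lags, dtype=int)
    if c_lags.shape != (step1.n_trials,):
        raise ValueError("c_lags length must equal the trial count")
    return _shift_all(step1, -c_lags)


def template_peak_latency(
    template: Template | np.ndarray,
    electrode: str | int,
    window: tuple[float, float],
    times: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    polarity: Literal["abs", "pos", "neg"] = "abs",
    interpolate: bool = False,
) -> float:
    """Peak latency (ms) of one electrode of a template within ``window``.

    By default the maximum of ``|value|``; ``polarity`` restricts the search
    to positive or negative deflections.  Ties break toward the earlier
    sample.  With ``interpolate=True`` the peak is refined to sub-sample
    precision by parabolic interpolation through the three samples around
    the maximum (used by the synchronization stages to minimize residual
    misalignment under integer-sample shifting).
    """
    if isinstance(template, Template):
        values, times = template.values, template.times
    else:
        values = np.asarray(template)
        if times is None:
            raise ValueError("times required when passing a bare array")
    if isinstance(electrode, str):
        if channel_names is None:
            raise ValueError("channel_names required to resolve an electrode label")
        try:
            electrode = channel_names.index(electrode)
        except ValueError:
            raise KeyError(f"electrode {electrode!r} not found") from None
    mask = (times >= window[0]) & (times < window[1])
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    trace = values[electrode, mask]
    if polarity == "abs":
        score = np.abs(trace)
    elif polarity == "pos":
        score = trace
    else:
        score = -trace
    if np.ptp(trace) == 0:
        raise ValueError("flat template trace: peak latency undefined")
    i = int(np.argmax(score))
    t_win = times[mask]
    if interpolate and 0 < i < score.shape[0] - 1:
        y0, y1, y2 = score[i - 1], score[i], score[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # proper maximum
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            dt = float(t_win[1] - t_win[0]) if t_win.shape[0] > 1 else 0.0
            return float(t_win[i] + delta * dt)
    return float(t_win[i])


def _condition_peaks(
    epochs: EpochSet,
    electrode: str,
    window: tuple[float, float],
) -> dict[tuple[str, str], float]:
    """Per (subject, condition) peak latency of the condition-average trace."""
    peaks: dict[tuple[str, str], float] = {}
    ch = epochs.channel_index(electrode)
    for subj in epochs.subject_ids:
        sel = epochs.subjects == subj
        sub = epochs.select_trials(np.flatnonzero(sel))
        for cond, avg in average_erp(sub).items():
            peaks[(subj, cond)] = template_peak_latency(
                avg, ch, window, times=epochs.times, interpolate=True
            )
    return peaks


def correct_between_conditions(
    step2: EpochSet,
    peak_latencies: Mapping[tuple[str, str], float] | None = None,
    reference_electrode: str = "Pz",
    window: tuple[float, float] | None = None,
) -> tuple[EpochSet, np.ndarray, dict]:
    """Step 3: synchronize the two conditions' peak latencies per subject.

    For each subject the target is the median (= midpoint) of the two
    conditions' C-template peak latencies at the reference electrode; every
    trial of a condition is shifted uniformly by ``target - peak`` (rounded
    half away from zero to samples).  ``peak_latencies`` maps
    ``(subject, condition) -> ms``; if omitted it is computed from the
    post-Step2 condition averages within ``window``.

    Returns ``(epochs, per-trial shifts in samples, peak_latencies)``.
    """
    conds = step2.conditions
    if len(conds) != 2:
        raise ValueError("between-condition correction requires exactly two conditions")
    if peak_latencies is None:
        if window is None:
            raise ValueError("window required to compute peak latencies")
        peak_latencies = _condition_peaks(step2, reference_electrode, window)
    shifts = np.zeros(step2.n_trials, dtype=int)
    dt = 1000.0 / step2.srate
    for subj in step2.subject_ids:
        try:
            peaks = {c: peak_latencies[(subj, c)] for c in conds}
        except KeyError as e:
            raise ValueError(f"missing peak latency for {e.args[0]}") from None
        # coupled rounding: shift both conditions toward the midpoint with
        # integer shifts whose difference equals the rounded peak gap, so the
        # residual misalignment never exceeds half a sample
        gap = (peaks[conds[1]] - peaks[conds[0]]) / dt  # samples, continuous
        s0 = ms_to_samples(gap / 2 * dt, step2.srate)
        s1 = s0 - ms_to_samples(gap * dt, step2.srate)
        for cond, s in zip(conds, (s0, s1)):
            shifts[(step2.subjects == subj) & (step2.labels == cond)] = s
    return _shift_all(step2, shifts), shifts, dict(peak_latencies)


def correct_between_subjects(
    step3: EpochSet,
    subject_peaks: Mapping[str, float] | None = None,
    reference_electrode: str = "Pz",
    window: tuple[float, float] | None = None,
) -> tuple[EpochSet, np.ndarray, dict]:
    """Step 4 (synchronization half): align all subjects to the common median peak.

    Each subject's condition-common peak latency (reference electrode, post
    Step 3) is shifted uniformly to the median across subjects.  Returns
    ``(epochs, per-trial shifts, subject_peaks)``.
    """
    if subject_peaks is None:
        if window is None:
            raise ValueError("window required to compute subject peaks")
        ch = step3.channel_index(reference_electrode)
        subject_peaks = {}
        for subj in step3.subject_ids:
            sub = step3.select_trials(np.flatnonzero(step3.subjects == subj))
            avg = sub.data.mean(axis=0)
            subject_peaks[subj] = template_peak_latency(
                avg, ch, window, times=step3.times, interpolate=True
            )
    target = float(np.median(list(subject_peaks.values())))
    shifts = np.zeros(step3.n_trials, dtype=int)
    for subj, peak in subject_peaks.items():
        shifts[step3.subjects == subj] = ms_to_samples(target - peak, step3.srate)
    return _shift_all(step3, shifts), shifts, dict(subject_peaks)


def gfp_normalize(epochs: EpochSet, eps: float = 1e-12) -> EpochSet:
    """Divide every trial's channel vector by its GFP, time point by time point.

    Scales each moment's activation to unit global field power while
    preserving the topography (the relative pattern across electrodes).
    Time points with GFP below ``eps`` become zeros.  Requires
    average-referenced data; idempotent.
    """
    assert_average_reference(epochs.data)
    g = gfp(epochs.data, channel_axis=1)  # (trials, samples)
    safe = g >= eps
    scale = np.where(safe, g, 1.0)
    data = np.where(safe[:, None, :], epochs.data / scale[:, None, :], 0.0)
    return replace(epochs, data=data)


def run_stepwise_pipeline(
    epochs: EpochSet,
    config: PipelineConfig = PipelineConfig(),
    decomps: dict[tuple[str, str], RideDecomposition] | None = None,
) -> dict[str, CorrectionResult]:
    """Materialize the five per-stage datasets of the stepwise correction.

    ``Original`` is the raw input; ``Step1`` the extracted C components;
    ``Step2``..``Step4`` the successively synchronized (and finally
    GFP-normalized) datasets.  All stages are cropped to
    ``config.analysis_window`` (default 100..1100 ms) after shifting.  A
    pre-computed decomposition may be passed to avoid re-running RIDE.

    Returns ``{stage: CorrectionResult}`` restricted to ``config.stages``;
    each result carries the cumulative per-trial shifts applied since Step1.
    """
    if len(epochs.conditions) != 2:
        raise ValueError("the pipeline requires exactly two conditions")
    lo, hi = config.analysis_window
    results: dict[str, CorrectionResult] = {}
    zero_shifts = np.zeros(epochs.n_trials, dtype=int)

    if "Original" in config.stages:
        results["Original"] = CorrectionResult(
            stage="Original",
            epochs=crop_epoch(epochs, lo, hi),
            applied_shifts=zero_shifts.copy(),
        )
    need_decomp = any(s in config.stages for s in STAGES[1:])
    if not need_decomp:
        return results

    if decomps is None:
        decomps = decompose_by_cell(
            epochs,
            config.windows,
            max_iter=config.max_iter,
            tol=config.tol,
            estimator=config.estimator,
            max_lag_ms=config.max_lag_ms,
            latency_smooth_ms=config.latency_smooth_ms,
        )

    # stitch per-cell C trials and lags back into the parent trial order
    c_data = np.zeros_like(epochs.data)
    c_lags = np.zeros(epochs.n_trials, dtype=int)
    for (subj, cond), dec in decomps.items():
        if dec.trial_index is None:
            raise ValueError("decompositions must carry trial_index for stitching")
        c_data[dec.trial_index] = dec.c_trials
        c_lags[dec.trial_index] = dec.c_lags
    step1_full = epochs.copy()
    step1_full.data = c_data

    if "Step1" in config.stages:
        results["Step1"] = CorrectionResult(
            stage="Step1",
            epochs=crop_epoch(step1_full, lo, hi),
            applied_shifts=zero_shifts.copy(),
        )

    step2_full = correct_within_condition(step1_full, c_lags)
    shifts2 = -c_lags
    if "Step2" in config.stages:
        results["Step2"] = CorrectionResult(
            stage="Step2",
            epochs=crop_epoch(step2_full, lo, hi),
            applied_shifts=shifts2.copy(),
        )

    step3_full, shifts3, cond_peaks = correct_between_conditions(
        step2_full,
        reference_electrode=config.reference_electrode,
        window=config.windows.c_window,
    )
    if "Step3" in config.stages:
        results["Step3"] = CorrectionResult(
            stage="Step3",
            epochs=crop_epoch(step3_full, lo, hi),
            applied_shifts=shifts2 + shifts3,
            reference_electrode=config.reference_electrode,
            peak_latencies=cond_peaks,
        )

    step4_sync, shifts4, subj_peaks = correct_between_subjects(
        step3_full,
        reference_electrode=config.reference_electrode,
        window=config.windows.c_window,
    )
    step4_full = gfp_normalize(step4_sync, eps=config.gfp_eps)
    if "Step4" in config.stages:
        results["Step4"] = CorrectionResult(
            stage="Step4",
            epochs=crop_epoch(step4_full, lo, hi),
            applied_shifts=shifts2 + shifts3 + shifts4,
            reference_electrode=config.reference_electrode,
            peak_latencies=subj_peaks,
            normalization="gfp",
        )
    return results
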