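"""Core data model for epoched EEG and elementary signal operations.

The central container is :class:`EpochSet`: single trials as a
``trials x channels x samples`` voltage array (microvolts) on a uniform
millisecond time grid, with per-trial condition labels, subject identifiers
and reaction times.  Everything downstream — the simulator, the S/C/R
decomposition, the latency-correction stages and the classifiers — consumes
and produces ``EpochSet`` objects only.

Conventions
-----------
* Time is in milliseconds relative to target onset; the sample grid is
  uniform at ``1000 / srate`` ms.
* All time windows are half-open ``[start, end)`` so that a 1-s analysis
  window at 250 Hz is exactly 250 samples.
* Latency shifts are integer-sample, zero-padded; no sub-sample
  interpolation is performed.
* Data are assumed average-referenced upstream (mean over channels ~ 0);
  operations that rely on this assert it but never re-reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np

__all__ = [
    "EpochSet",
    "Template",
    "gfp",
    "shift_trial",
    "crop_epoch",
    "average_erp",
    "difference_wave",
    "tukey_rt_filter",
    "amplitude_variability",
    "assert_average_reference",
    "read_eeglab_epochs",
    "read_fif_epochs",
    "save_epochs_h5",
    "load_epochs_h5",
]


def _as_string_array(values: Iterable, n: int, name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr.astype(str)


@dataclass
class EpochSet:
    """Epoched multi-channel EEG single trials with per-trial metadata.

    Parameters
    ----------
    data
        Voltages, shape ``(n_trials, n_channels, n_samples)``, microvolts.
    times
        Per-sample latency in ms relative to target onset; strictly
        increasing and uniformly spaced at ``1000 / srate``.
    srate
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, length ``n_channels``.
    labels
        Per-trial condition tag (two-level for classification).
    subjects
        Per-trial subject identifier.
    rts
        Per-trial reaction time in ms; ``NaN`` marks a missing response.
        ``None`` for data without responses.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_names: list[str]
    labels: np.ndarray
    subjects: np.ndarray
    rts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 + 1:
            raise ValueError("data must be 3-D (trials, channels, samples)")
        n_trials, n_channels, n_samples = self.data.shape
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.shape != (n_samples,):
            raise ValueError("times length must equal the sample count")
        step = 1000.0 / self.srate
        diffs = np.diff(self.times)
        if n_samples > 1 and not np.allclose(diffs, step, rtol=0, atol=1e-6 * step):
            raise ValueError("times must be uniformly spaced at 1000/srate ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length must equal the channel count")
        self.labels = _as_string_array(self.labels, n_trials, "labels")
        self.subjects = _as_string_array(self.subjects, n_trials, "subjects")
        if self.rts is not None:
            self.rts = np.asarray(self.rts, dtype=np.float64)
            if self.rts.shape != (n_trials,):
                raise ValueError("rts length must equal the trial count")

    # -- basic introspection ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    @property
    def subject_ids(self) -> list[str]:
        return sorted(np.unique(self.subjects).tolist())

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not found") from None

    def sample_index(self, t_ms: float) -> int:
        """Index of the grid sample nearest ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean sample mask for the half-open window ``[start_ms, end_ms)``."""
        return (self.times >= start_ms) & (self.times < end_ms)

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the trials in ``idx`` (order kept)."""
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            rts=None if self.rts is None else self.rts[idx],
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            labels=self.labels.copy(),
            subjects=self.subjects.copy(),
            rts=None if self.rts is None else self.rts.copy(),
        )


@dataclass
class Template:
    """Spatiotemporal component template: the latency-locked trial average.

    ``values`` is a ``channels x samples`` array on the same grid as the
    parent :class:`EpochSet`; it is exactly zero outside the half-open
    ``window`` (with tapered edges inside the window).
    """

    values: np.ndarray
    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.times.shape[0]:
            raise ValueError("values must be (channels, samples) matching times")
        outside = ~((self.times >= self.window[0]) & (self.times < self.window[1]))
        if np.any(np.abs(self.values[:, outside]) > 0):
            raise ValueError("template values must be zero outside the window")

    @property
    def window_mask(self) -> np.ndarray:
        return (self.times >= self.window[0]) & (self.times < self.window[1])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def gfp(values: np.ndarray, channel_axis: int = -1) -> np.ndarray:
    """Global field power: population std of voltage across channels.

    For a single time-point snapshot (1-D array of per-channel voltages)
    returns a scalar; for stacked arrays the reduction runs over
    ``channel_axis`` and one value per remaining index is returned, e.g.
    ``gfp(epochs.data, channel_axis=1)`` gives per-trial, per-time GFP.

    Uses the population standard deviation (``ddof=0``), the classical GFP
    definition.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape[channel_axis] < 2:
        raise ValueError("GFP requires at least 2 channels")
    if not np.all(np.isfinite(values)):
        raise ValueError("GFP input must be finite")
    return np.std(values, axis=channel_axis, ddof=0)


def shift_trial(trial: np.ndarray, lag: int) -> np.ndarray:
    """Shift a ``channels x samples`` trial by ``lag`` samples, zero-padding.

    Positive ``lag`` moves the waveform later in time.  Output shape equals
    input shape; the vacated edge samples are zero.
    """
    trial = np.asarray(trial)
    lag = int(lag)
    n = trial.shape[-1]
    if abs(lag) >= n:
        raise ValueError(f"|lag|={abs(lag)} >= sample count {n}: trial would be all padding")
    out = np.zeros_like(trial)
    if lag == 0:
        out[...] = trial
    elif lag > 0:
        out[..., lag:] = trial[..., :-lag]
    else:
        out[..., :lag] = trial[..., -lag:]
    return out


def crop_epoch(epochs: EpochSet, start_ms: float, end_ms: float) -> EpochSet:
    """Restrict an EpochSet to the half-open time window ``[start_ms, end_ms)``."""
    mask = epochs.window_mask(start_ms, end_ms)
    if not np.any(mask):
        raise ValueError(f"crop [{start_ms}, {end_ms}) contains no samples")
    return replace(epochs, data=epochs.data[:, :, mask], times=epochs.times[mask])


def average_erp(epochs: EpochSet, by: str = "label") -> dict[str, np.ndarray]:
    """Condition-wise trial averages.

    Returns a mapping ``condition -> channels x samples`` arithmetic mean.
    ``by`` may be ``"label"`` (default) or ``"subject"``.
    """
    keys = epochs.labels if by == "label" else epochs.subjects
    out: dict[str, np.ndarray] = {}
    for key in np.unique(keys):
        sel = keys == key
        out[str(key)] = epochs.data[sel].mean(axis=0)
    return out


def difference_wave(epochs: EpochSet, cond_a: str, cond_b: str) -> np.ndarray:
    """``mean(cond_a) - mean(cond_b)`` as channels x samples."""
    means = average_erp(epochs)
    for cond in (cond_a, cond_b):
        if cond not in means:
            raise ValueError(f"condition {cond!r} absent from epochs")
    return means[cond_a] - means[cond_b]


def tukey_rt_filter(epochs: EpochSet, min_rt_ms: float = 200.0) -> EpochSet:
    """Drop trials with implausible reaction times.

    Removes trials whose RT is missing (NaN), shorter than ``min_rt_ms``, or
    outside the Tukey fences ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` computed per
    subject x condition cell (fences from the trials surviving the minimum-RT
    cut).  Idempotent on its own output.
    """
    if epochs.rts is None:
        raise ValueError("tukey_rt_filter requires reaction times")
    keep = np.zeros(epochs.n_trials, dtype=bool)
    valid = np.isfinite(epochs.rts) & (epochs.rts >= min_rt_ms)
    for subj in np.unique(epochs.subjects):
        for cond in np.unique(epochs.labels):
            cell = (epochs.subjects == subj) & (epochs.labels == cond)
            if not np.any(cell):
                continue
            cell_valid = cell & valid
            if not np.any(cell_valid):
                warnings.warn(
                    f"all trials of cell ({subj}, {cond}) removed by the RT filter",
                    RuntimeWarning,
                )
                continue
            rts = epochs.rts[cell_valid]
            q1, q3 = np.percentile(rts, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            keep |= cell_valid & (epochs.rts >= lo) & (epochs.rts <= hi)
    return epochs.select_trials(np.flatnonzero(keep))


def amplitude_variability(trial: np.ndarray, template: Template) -> np.ndarray:
    """Per-channel population covariance between a trial and its template.

    The covariance is computed over the samples inside the template window
    (one value per channel); a constant voltage offset on the trial leaves it
    unchanged.  This is the single-trial amplitude measure used to sort
    trials by how strongly they express the template.
    """
    trial = np.asarray(trial, dtype=np.float64)
    mask = template.window_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("template window contains no samples")
    x = trial[:, mask]
    y = template.values[:, mask]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    return (xc * yc).sum(axis=1) / n


def assert_average_reference(data: np.ndarray, rtol: float = 1e-6) -> None:
    """Assert that voltages are average-referenced (channel mean ~ 0).

    ``data`` is ``(..., channels, samples)``; the tolerance is
    ``rtol * max |v|``.  Raises ``ValueError`` otherwise — the package never
    re-references silently.
    """
    data = np.asarray(data)
    scale = np.max(np.abs(data))
    if scale == 0:
        return
    worst = np.max(np.abs(data.mean(axis=-2)))
    if worst > rtol * scale:
        raise ValueError(
            f"data is not average-referenced (max channel-mean {worst:.3g} "
            f"exceeds {rtol:.1g} x max |v| = {rtol * scale:.3g})"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _epochs_from_mne(
    mne_epochs,
    subject: str | None,
    rt_column: str | None,
    subject_column: str | None,
) -> EpochSet:
    data = mne_epochs.get_data(copy=True) * 1e6  # Volts -> microvolts
    times = mne_epochs.times * 1000.0
    srate = float(mne_epochs.info["sfreq"])
    inv_event_id = {v: k for k, v in mne_epochs.event_id.items()}
    labels = np.array([inv_event_id[e] for e in mne_epochs.events[:, 2]])
    n = data.shape[0]
    meta = getattr(mne_epochs, "metadata", None)
    if subject_column is not None and meta is not None and subject_column in meta:
        subjects = meta[subject_column].astype(str).to_numpy()
    else:
        subjects = np.array([subject or "S01"] * n)
    rts = None
    if rt_column is not None and meta is not None and rt_column in meta:
        rts = meta[rt_column].to_numpy(dtype=float)
    return EpochSet(
        data=data,
        times=times,
        srate=srate,
        channel_names=list(mne_epochs.ch_names),
        labels=labels,
        subjects=subjects,
        rts=rts,
    )


def read_eeglab_epochs(
    path: str | Path,
    subject: str | None = None,
    rt_column: str | None = "rt",
    subject_column: str | None = "subject",
) -> EpochSet:
    """Read an EEGLAB epoched ``.set`` file (with companion ``.fdt`` if split).

    Condition labels are taken from the epoch event types; reaction times and
    subject ids from the metadata columns if present, else ``subject`` is
    used for all trials.
    """
    import mne

    epochs = mne.io.read_epochs_eeglab(str(path), verbose="error")
    return _epochs_from_mne(epochs, subject, rt_column, subject_column)


def read_fif_epochs(
    path: str | Path,
    subject: str | None = None,
    rt_column: str | None = "rt",
    subject_column: str | None = "subject",
) -> EpochSet:
    """Read epochs from an MNE FIF file (``*-epo.fif``)."""
    import mne

    epochs = mne.read_epochs(str(path), preload=True, verbose="error")
    return _epochs_from_mne(epochs, subject, rt_column, subject_column)


def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to the package's HDF5 container.

    Layout: named datasets ``data`` (trials x channels x samples, µV),
    ``times`` (ms), ``labels``, ``subjects``, ``rts`` and ``channel_names``
    plus an ``srate`` attribute — reloadable with :func:`load_epochs_h5`.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["srate"] = epochs.srate
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("channel_names", data=np.array(epochs.channel_names, dtype=object), dtype=str_dt)
        f.create_dataset("labels", data=epochs.labels.astype(object), dtype=str_dt)
        f.create_dataset("subjects", data=epochs.subjects.astype(object), dtype=str_dt)
        if epochs.rts is not None:
            f.create_dataset("rts", data=epochs.rts)


def load_epochs_h5(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs_h5`."""
    with h5py.File(path, "r") as f:
        rts = f["rts"][()] if "rts" in f else None
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            srate=float(f.attrs["srate"]),
            channel_names=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_names"][()]],
            labels=np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]]),
            subjects=np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][()]]),
            rts=rts,
        )
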