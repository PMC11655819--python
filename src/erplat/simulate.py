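"""Synthetic single-trial ERP generator with known ground truth.

Each simulated trial is a sum of three component clusters on a fixed channel
montage, mirroring the generative picture behind S/C/R decomposition:

* **S** — a stimulus-locked bump at a fixed early latency (sensory),
* **C** — a latency-variable central bump whose per-trial latency is drawn
  from a condition-specific distribution (mean latency per condition +
  within-condition jitter + a per-subject offset), optionally with a
  condition-specific amplitude,
* **R** — a response-locked bump tied to the trial's reaction time, with
  RT = C latency + motor delay (log-normal), so that response timing
  co-varies with the central process, as it does behaviorally.

Every component has a zero-mean channel topography (consistent with an
average reference) and additive noise is spatially correlated (optionally
white) and projected to the average reference, so generated data satisfy the
assumptions the correction pipeline asserts.  A ground-truth table (true C
latency, RT, per-component amplitudes) is returned for parameter-recovery
tests.

The default scenario mirrors a two-condition face repetition priming
session: 72 trials per condition per subject, 41 channels at 250 Hz, epochs
-100..1500 ms around target onset, C latencies 360 ms (primed) vs 440 ms
(unprimed) with 50 ms within-condition jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from erplat.epochs_core import EpochSet

__all__ = [
    "ComponentSpec",
    "SimConfig",
    "component_waveform",
    "generate_epochs",
    "default_channel_names",
    "priming_config",
]

# 41-channel analysis montage (10-10 subset); 'Pz' is the synchronization
# reference electrode downstream.
_MONTAGE_41 = [
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6",
    "F8", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "T7", "C3", "C1",
    "Cz", "C2", "C4", "T8", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]


def default_channel_names(n_channels: int) -> list[str]:
    """Montage labels for ``n_channels`` (the 41-channel set, cycled/truncated)."""
    if n_channels <= len(_MONTAGE_41):
        names = _MONTAGE_41[:n_channels]
        if "Pz" not in names:  # keep the reference electrode in small montages
            names[-1] = "Pz"
        return names
    extra = [f"EX{i}" for i in range(n_channels - len(_MONTAGE_41))]
    return _MONTAGE_41 + extra


def _per_condition(value, condition: str) -> float:
    if isinstance(value, Mapping):
        return float(value[condition])
    return float(value)


@dataclass
class ComponentSpec:
    """One component cluster of the generative model.

    ``kind`` is ``'S'`` (fixed latency), ``'C'`` (condition-dependent latency
    distribution) or ``'R'`` (locked to the reaction time).  ``amplitude``
    and, for C, ``latency_ms`` / ``jitter_sd_ms`` may be a single number or a
    per-condition mapping.  The topography is a per-channel weight vector
    with zero mean across channels; if ``None`` a smooth random topography is
    drawn at generation time (with the peak pinned to the reference electrode
    for C, where downstream synchronization reads its peak latency).
    """

    kind: str
    morphology: str = "gaussian"  # or "halfcos"
    width_ms: float = 100.0
    amplitude: float | Mapping[str, float] = 1.0
    topography: np.ndarray | None = None
    latency_ms: float | Mapping[str, float] = 0.0  # S/C: post-stimulus; R: offset from RT
    jitter_sd_ms: float | Mapping[str, float] = 0.0  # C only
    subject_sd_ms: float = 0.0  # C only: per-subject latency offset SD

    def __post_init__(self) -> None:
        if self.kind not in ("S", "C", "R"):
            raise ValueError("kind must be 'S', 'C' or 'R'")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        jit = self.jitter_sd_ms
        vals = jit.values() if isinstance(jit, Mapping) else [jit]
        if any(v < 0 for v in vals):
            raise ValueError("jitter SD must be nonnegative")
        if self.topography is not None:
            topo = np.asarray(self.topography, dtype=np.float64)
            if abs(topo.mean()) > 1e-9 * max(np.abs(topo).max(), 1e-30):
                raise ValueError("topography must have ~zero mean across channels")
            self.topography = topo


@dataclass
class SimConfig:
    """Full description of one simulated dataset; the seed determines everything."""

    n_subjects: int = 20
    trials_per_condition: int = 72
    conditions: tuple[str, str] = ("primed", "unprimed")
    n_channels: int = 41
    srate: float = 250.0
    tmin_ms: float = -100.0
    tmax_ms: float = 1500.0
    components: Sequence[ComponentSpec] = field(default_factory=list)
    rt_median_ms: Mapping[str, float] | float = field(
        default_factory=lambda: {"primed": 640.0, "unprimed": 760.0}
    )
    rt_sigma: float = 0.2  # log-normal shape of the motor delay
    noise_sd_uv: float = 0.0  # per-channel noise SD in microvolts
    noise_spatial: bool = True  # channel-correlated noise (False: white)
    noise_pink: bool = False  # 1/f temporal coloring
    simulate_rt: bool = True  # draw reaction times (required for an R component)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.srate
        n = int(round((self.tmax_ms - self.tmin_ms) / step))
        return self.tmin_ms + step * np.arange(n)


def _morphology(kind: str, times: np.ndarray, latency: float, width: float) -> np.ndarray:
    if kind == "gaussian":
        sigma = width / 2.3548200450309493  # width == FWHM
        return np.exp(-0.5 * ((times - latency) / sigma) ** 2)
    if kind == "halfcos":
        half = width / 2.0
        u = (times - latency) / half
        w = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        return w
    raise ValueError(f"unknown morphology {kind!r}")


def component_waveform(
    spec: ComponentSpec,
    latency_ms: float,
    times: np.ndarray,
    amplitude: float = 1.0,
    topography: np.ndarray | None = None,
) -> np.ndarray:
    """Render one component instance as a ``channels x samples`` array.

    The morphology is centered at ``latency_ms`` and multiplied outer-product
    style by the topography; ``amplitude`` is the signed peak voltage (µV) at
    the topography's unit-weight channel.
    """
    times = np.asarray(times, dtype=np.float64)
    if not (times[0] <= latency_ms <= times[-1]):
        raise ValueError(
            f"latency {latency_ms} ms outside epoch span [{times[0]}, {times[-1]}] ms"
        )
    topo = topography if topography is not None else spec.topography
    if topo is None:
        raise ValueError("no topography supplied")
    wave = _morphology(spec.morphology, times, latency_ms, spec.width_ms)
    return amplitude * np.outer(np.asarray(topo, dtype=np.float64), wave)


def _smooth_topography(rng: np.random.Generator, n_channels: int, peak_channel: int | None) -> np.ndarray:
    """Zero-mean smooth random channel weights with max |w| = 1."""
    raw = rng.normal(size=n_channels)
    # smooth along the (arbitrary but fixed) montage ordering
    kernel = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
    raw = np.convolve(raw, kernel / kernel.sum(), mode="same")
    if peak_channel is not None:
        raw[peak_channel] = np.sign(raw[peak_channel] or 1.0) * (np.abs(raw).max() * 1.5 + 0.1)
    raw = raw - raw.mean()
    return raw / np.abs(raw).max()


def _noise_mixing(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    """Mixing matrix giving smooth cross-channel noise correlation, unit variance."""
    a = rng.normal(size=(n_channels, n_channels))
    kernel = np.ones(5) / 5.0
    a = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 0, a)
    a /= np.sqrt((a**2).sum(axis=1, keepdims=True))
    return a


def _pink_filter(n_samples: int) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    amp = np.ones_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:] / freqs[1])
    return amp


def default_components(
    c_latency_ms: Mapping[str, float] | float = None,  # type: ignore[assignment]
    c_amplitude: Mapping[str, float] | float = 5.0,
    c_jitter_sd_ms: Mapping[str, float] | float = 50.0,
    c_subject_sd_ms: float = 30.0,
    s_amplitude: float = 4.0,
    r_amplitude: float = 3.0,
) -> list[ComponentSpec]:
    """The three-component priming scenario (S at 150 ms, C per condition, R at RT)."""
    if c_latency_ms is None:
        c_latency_ms = {"primed": 360.0, "unprimed": 440.0}
    return [
        ComponentSpec(kind="S", width_ms=80.0, amplitude=s_amplitude, latency_ms=150.0),
        ComponentSpec(
            kind="C",
            width_ms=120.0,
            amplitude=c_amplitude,
            latency_ms=c_latency_ms,
            jitter_sd_ms=c_jitter_sd_ms,
            subject_sd_ms=c_subject_sd_ms,
        ),
        ComponentSpec(kind="R", width_ms=100.0, amplitude=r_amplitude, latency_ms=0.0),
    ]


def priming_config(
    n_subjects: int = 20,
    trials_per_condition: int = 72,
    n_channels: int = 41,
    jitter_sd_ms: float = 50.0,
    latency_shift: bool = True,
    subject_sd_ms: float = 30.0,
    amplitude_effect: float = 0.0,
    noise_sd_uv: float = 5.0,
    with_s: bool = True,
    with_r: bool = True,
    seed: int = 0,
) -> SimConfig:
    """Ready-made scenarios of the priming study.

    ``latency_shift`` toggles the 360 vs 440 ms condition latency difference;
    ``amplitude_effect`` adds that many µV to the unprimed C amplitude;
    ``jitter_sd_ms``/``subject_sd_ms`` control within-condition and
    between-subject latency variability.  ``noise_sd_uv=5`` puts the
    single-trial C-peak SNR at ~1 for the default 5 µV C amplitude.
    """
    lat = {"primed": 360.0, "unprimed": 440.0} if latency_shift else {"primed": 400.0, "unprimed": 400.0}
    amp = {"primed": 5.0, "unprimed": 5.0 + amplitude_effect}
    comps = default_components(
        c_latency_ms=lat,
        c_amplitude=amp,
        c_jitter_sd_ms=jitter_sd_ms,
        c_subject_sd_ms=subject_sd_ms,
        s_amplitude=4.0 if with_s else 0.0,
        r_amplitude=3.0,
    )
    if not with_r:  # no response stream at all: pure stimulus-locked design
        comps = [c for c in comps if c.kind != "R"]
    rt_median = {cond: lat[cond] + 300.0 for cond in ("primed", "unprimed")}
    return SimConfig(
        n_subjects=n_subjects,
        trials_per_condition=trials_per_condition,
        n_channels=n_channels,
        components=comps,
        rt_median_ms=rt_median,
        noise_sd_uv=noise_sd_uv,
        simulate_rt=with_r,
        seed=seed,
    )


def generate_epochs(config: SimConfig) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate an EpochSet plus its ground-truth table.

    Returns ``(epochs, truth)`` where ``truth`` has one row per trial:
    subject, condition, true C latency (ms), RT (ms), and per-component
    amplitudes.  The same seed yields byte-identical output; each subject
    draws from its own sub-stream so subject subsets are reproducible.
    """
    times = config.times
    n_samples = times.shape[0]
    n_channels = config.n_channels
    channel_names = default_channel_names(n_channels)
    pz = channel_names.index("Pz") if "Pz" in channel_names else n_channels - 1

    top_rng = np.random.default_rng([int(config.seed), 0xA11CE])
    topos: dict[int, np.ndarray] = {}
    for i, spec in enumerate(config.components):
        if spec.topography is not None:
            topos[i] = spec.topography
        else:
            peak = pz if spec.kind == "C" else None
            topos[i] = _smooth_topography(top_rng, n_channels, peak)
    mixing = _noise_mixing(np.random.default_rng([int(config.seed), 0x5EED]), n_channels)
    pink = _pink_filter(n_samples) if config.noise_pink else None

    n_cell = config.trials_per_condition
    n_total = config.n_subjects * 2 * n_cell
    data = np.zeros((n_total, n_channels, n_samples))
    labels = np.empty(n_total, dtype=object)
    subjects = np.empty(n_total, dtype=object)
    rts = np.full(n_total, np.nan)
    rows = []

    c_specs = [(i, s) for i, s in enumerate(config.components) if s.kind == "C"]
    epoch_end = times[-1]

    t = 0
    for si in range(config.n_subjects):
        subj = f"S{si + 1:02d}"
        rng = np.random.default_rng([int(config.seed), 1, si])
        # per-subject C latency offset, shared across conditions
        subj_offsets = {
            i: rng.normal(0.0, spec.subject_sd_ms) if spec.subject_sd_ms > 0 else 0.0
            for i, spec in c_specs
        }
        for cond in config.conditions:
            rt_median = _per_condition(config.rt_median_ms, cond)
            for _ in range(n_cell):
                trial = np.zeros((n_channels, n_samples))
                c_latency = np.nan
                rt = np.nan
                amps: dict[str, float] = {}
                # draw C latencies first; RT hangs off the (first) C latency
                c_lat_by_idx: dict[int, float] = {}
                for i, spec in c_specs:
                    mean_lat = _per_condition(spec.latency_ms, cond) + subj_offsets[i]
                    jit = _per_condition(spec.jitter_sd_ms, cond)
                    for _retry in range(100):
                        lat = rng.normal(mean_lat, jit) if jit > 0 else mean_lat
                        if times[0] <= lat <= epoch_end:
                            break
                    else:
                        raise RuntimeError("could not draw a C latency inside the epoch")
                    c_lat_by_idx[i] = lat
                if c_lat_by_idx:
                    c_latency = c_lat_by_idx[c_specs[0][0]]
                has_r = any(s.kind == "R" for s in config.components)
                if has_r and not config.simulate_rt:
                    raise ValueError("an R component requires simulate_rt=True")
                if config.simulate_rt:
                    base = c_latency if np.isfinite(c_latency) else 0.0
                    delay_median = max(rt_median - (_per_condition(
                        config.components[c_specs[0][0]].latency_ms, cond) if c_specs else 0.0), 50.0)
                    for _retry in range(100):
                        delay = delay_median * np.exp(rng.normal(0.0, config.rt_sigma))
                        rt_try = base + delay
                        if rt_try < epoch_end:
                            rt = rt_try
                            break
                    else:
                        raise RuntimeError("could not draw an RT inside the epoch")
                for i, spec in enumerate(config.components):
                    amp = _per_condition(spec.amplitude, cond)
                    amps[f"amp_{spec.kind}{i}"] = amp
                    if amp == 0.0:
                        continue
                    if spec.kind == "S":
                        lat = _per_condition(spec.latency_ms, cond)
                    elif spec.kind == "C":
                        lat = c_lat_by_idx[i]
                    else:  # R locked to RT (+ optional offset)
                        lat = rt + _per_condition(spec.latency_ms, cond)
                    trial += component_waveform(spec, lat, times, amp, topos[i])
                if config.noise_sd_uv > 0:
                    white = rng.normal(size=(n_channels, n_samples))
                    if pink is not None:
                        spec_w = np.fft.rfft(white, axis=1) * pink
                        white = np.fft.irfft(spec_w, n=n_samples, axis=1)
                        white /= white.std(axis=1, keepdims=True)
                    noise = (mixing @ white) if config.noise_spatial else white
                    trial += config.noise_sd_uv * noise
                # enforce the average reference exactly
                trial -= trial.mean(axis=0, keepdims=True)
                data[t] = trial
                labels[t] = cond
                subjects[t] = subj
                rts[t] = rt
                rows.append(
                    {"trial": t, "subject": subj, "condition": cond,
                     "c_latency_ms": c_latency, "rt_ms": rt, **amps}
                )
                t += 1

    epochs = EpochSet(
        data=data,
        times=times,
        srate=config.srate,
        channel_names=channel_names,
        labels=np.array(labels, dtype=str),
        subjects=np.array(subjects, dtype=str),
        rts=rts if np.any(np.isfinite(rts)) else None,
    )
    truth = pd.DataFrame(rows)
    return epochs, truth
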