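"""Shared fixtures: small synthetic EpochSets built programmatically."""

import numpy as np
import pytest

from erplat.epochs_core import EpochSet


def make_epochs(
    n_trials=8,
    n_channels=5,
    n_samples=100,
    srate=250.0,
    tmin=-100.0,
    seed=0,
    rts=True,
    two_subjects=False,
):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_trials, n_channels, n_samples))
    data -= data.mean(axis=1, keepdims=True)  # average reference
    times = tmin + np.arange(n_samples) * (1000.0 / srate)
    labels = np.array(["primed", "unprimed"] * (n_trials // 2) + ["primed"] * (n_trials % 2))
    if two_subjects:
        subjects = np.array(["S01"] * (n_trials // 2) + ["S02"] * (n_trials - n_trials // 2))
    else:
        subjects = np.array(["S01"] * n_trials)
    names = [f"ch{i}" for i in range(n_channels - 1)] + ["Pz"]
    return EpochSet(
        data=data,
        times=times,
        srate=srate,
        channel_names=names,
        labels=labels,
        subjects=subjects,
        rts=rng.uniform(300, 900, n_trials) if rts else None,
    )


@pytest.fixture
def small_epochs():
    return make_epochs()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
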