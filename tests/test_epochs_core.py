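"""Unit tests for the epoch container and elementary signal operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erplat.epochs_core import (
    EpochSet,
    Template,
    amplitude_variability,
    assert_average_reference,
    average_erp,
    crop_epoch,
    difference_wave,
    gfp,
    load_epochs_h5,
    save_epochs_h5,
    shift_trial,
    tukey_rt_filter,
)
from tests.conftest import make_epochs


class TestGfp:
    def test_two_channel_snapshot(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_constant_snapshot_is_zero(self):
        assert gfp(np.array([5.0, 5.0, 5.0, 5.0])) == 0.0

    def test_matches_two_pass_oracle(self, rng):
        snapshot = rng.normal(size=41)
        mean = sum(snapshot) / 41
        var = sum((v - mean) ** 2 for v in snapshot) / 41
        assert gfp(snapshot) == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_vectorized_per_trial_per_time(self, small_epochs):
        out = gfp(small_epochs.data, channel_axis=1)
        assert out.shape == (small_epochs.n_trials, small_epochs.n_samples)
        assert np.all(out >= 0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.array([1.0]))

    @given(scale=st.floats(-10, 10), offset=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance_and_offset_invariance(self, scale, offset):
        v = np.array([0.3, -1.2, 2.0, 0.1, -0.7])
        assert gfp(scale * v) == pytest.approx(abs(scale) * gfp(v), abs=1e-9)
        assert gfp(v + offset) == pytest.approx(gfp(v), abs=1e-9)


class TestShiftTrial:
    def test_zero_lag_identity(self, rng):
        trial = rng.normal(size=(3, 20))
        assert np.array_equal(shift_trial(trial, 0), trial)

    def test_inverse_up_to_padding(self, rng):
        # +7 then -7 loses exactly the 7 samples pushed off the far edge
        trial = rng.normal(size=(2, 50))
        back = shift_trial(shift_trial(trial, 7), -7)
        assert np.allclose(back[:, :-7], trial[:, :-7])
        assert np.all(back[:, -7:] == 0)

    def test_negative_lag_index_oracle(self, rng):
        trial = rng.normal(size=(2, 30))
        out = shift_trial(trial, -3)
        for t in range(27):
            assert np.allclose(out[:, t], trial[:, t + 3])
        assert np.all(out[:, 27:] == 0)

    def test_energy_preserved_minus_padding(self, rng):
        trial = rng.normal(size=(4, 40))
        lag = 6
        out = shift_trial(trial, lag)
        lost = (trial[:, -lag:] ** 2).sum()
        assert out[..., :].__pow__(2).sum() == pytest.approx((trial**2).sum() - lost)

    def test_full_length_lag_rejected(self, rng):
        with pytest.raises(ValueError):
            shift_trial(rng.normal(size=(2, 10)), 10)


class TestCropEpoch:
    def test_one_second_is_250_samples(self):
        ep = make_epochs(n_samples=400, tmin=-100.0)
        cropped = crop_epoch(ep, 100.0, 1100.0)
        assert cropped.n_samples == 250
        assert cropped.times[0] == 100.0
        assert cropped.times[-1] < 1100.0

    def test_full_span_identity(self, small_epochs):
        out = crop_epoch(small_epochs, small_epochs.times[0], small_epochs.times[-1] + 4.0)
        assert np.array_equal(out.data, small_epochs.data)

    def test_composition_equals_single_crop(self):
        ep = make_epochs(n_samples=400, tmin=-100.0)
        twice = crop_epoch(crop_epoch(ep, 100.0, 1100.0), 200.0, 300.0)
        once = crop_epoch(ep, 200.0, 300.0)
        assert np.array_equal(twice.data, once.data)
        assert np.array_equal(twice.times, once.times)

    def test_empty_crop_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            crop_epoch(small_epochs, 5000.0, 6000.0)

    def test_commutes_with_average(self):
        ep = make_epochs(n_samples=200)
        a = average_erp(crop_epoch(ep, 0.0, 400.0))
        mask = ep.window_mask(0.0, 400.0)
        b = {k: v[:, mask] for k, v in average_erp(ep).items()}
        for cond in a:
            assert np.allclose(a[cond], b[cond])


class TestAverageErp:
    def test_identical_trials(self):
        ep = make_epochs(n_trials=4, seed=1)
        ep.data[:] = ep.data[0]
        avg = average_erp(ep)
        for cond in avg:
            assert np.allclose(avg[cond], ep.data[0])

    def test_opposite_trials_cancel(self):
        ep = make_epochs(n_trials=2)
        ep.data[1] = -ep.data[0]
        ep.labels[:] = "primed"
        assert np.allclose(average_erp(ep)["primed"], 0.0)

    def test_missing_condition_named_in_error(self, small_epochs):
        with pytest.raises(ValueError, match="nosuch"):
            difference_wave(small_epochs, "primed", "nosuch")


class TestTukeyRtFilter:
    def test_gross_outlier_removed(self):
        ep = make_epochs(n_trials=11)
        ep.labels[:] = "primed"
        ep.rts = np.array([400.0, 410, 420, 430, 440, 450, 460, 470, 480, 490, 5000.0])
        out = tukey_rt_filter(ep)
        assert out.n_trials == 10
        assert 5000.0 not in out.rts

    def test_fast_rt_removed(self):
        ep = make_epochs(n_trials=6)
        ep.labels[:] = "primed"
        ep.rts = np.array([150.0, 400, 420, 440, 460, 480])
        out = tukey_rt_filter(ep)
        assert 150.0 not in out.rts

    def test_matches_fence_oracle(self, rng):
        ep = make_epochs(n_trials=40, seed=3)
        ep.labels[:] = "primed"
        ep.rts = rng.lognormal(6.3, 0.4, 40)
        out = tukey_rt_filter(ep)
        rts = ep.rts[ep.rts >= 200]
        q1, q3 = np.percentile(rts, [25, 75])
        fence_lo, fence_hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expected = np.flatnonzero(
            (ep.rts >= 200) & (ep.rts >= fence_lo) & (ep.rts <= fence_hi)
        )
        assert np.array_equal(np.sort(out.rts), np.sort(ep.rts[expected]))

    def test_idempotent(self, rng):
        ep = make_epochs(n_trials=50, seed=4)
        ep.rts = rng.lognormal(6.3, 0.5, 50)
        once = tukey_rt_filter(ep)
        twice = tukey_rt_filter(once)
        assert np.array_equal(once.data, twice.data)

    def test_requires_rts(self):
        ep = make_epochs(rts=False)
        with pytest.raises(ValueError):
            tukey_rt_filter(ep)


class TestAmplitudeVariability:
    def _template(self, values, times):
        return Template(values=values, times=times, window=(times[0], times[-1] + 4.0))

    def test_self_covariance_is_variance(self, rng):
        times = np.arange(50) * 4.0
        vals = rng.normal(size=(3, 50))
        tmpl = self._template(vals, times)
        cov = amplitude_variability(vals, tmpl)
        assert np.allclose(cov, vals.var(axis=1))

    def test_offset_invariance(self, rng):
        times = np.arange(30) * 4.0
        vals = rng.normal(size=(2, 30))
        tmpl = self._template(vals, times)
        assert np.allclose(
            amplitude_variability(vals + 7.5, tmpl), amplitude_variability(vals, tmpl)
        )

    def test_matches_explicit_oracle(self, rng):
        times = np.arange(40) * 4.0
        trial = rng.normal(size=(4, 40))
        tmpl = self._template(rng.normal(size=(4, 40)), times)
        cov = amplitude_variability(trial, tmpl)
        for ch in range(4):
            x, y = trial[ch], tmpl.values[ch]
            expected = np.sum((x - x.mean()) * (y - y.mean())) / 40
            assert cov[ch] == pytest.approx(expected, rel=1e-12)


class TestEpochSetValidation:
    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            EpochSet(
                data=np.zeros((1, 2, 3)),
                times=np.array([0.0, 4.0, 9.0]),
                srate=250.0,
                channel_names=["a", "b"],
                labels=["x"],
                subjects=["s"],
            )

    def test_nonfinite_data_rejected(self):
        data = np.zeros((1, 2, 3))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            EpochSet(
                data=data,
                times=np.arange(3) * 4.0,
                srate=250.0,
                channel_names=["a", "b"],
                labels=["x"],
                subjects=["s"],
            )

    def test_average_reference_assertion(self, small_epochs):
        assert_average_reference(small_epochs.data)
        with pytest.raises(ValueError, match="average-referenced"):
            assert_average_reference(small_epochs.data + 1.0)


class TestIO:
    def test_h5_roundtrip(self, small_epochs, tmp_path):
        path = tmp_path / "epochs.h5"
        save_epochs_h5(small_epochs, path)
        back = load_epochs_h5(path)
        assert np.array_equal(back.data, small_epochs.data)
        assert np.array_equal(back.labels, small_epochs.labels)
        assert np.array_equal(back.subjects, small_epochs.subjects)
        assert np.allclose(back.rts, small_epochs.rts)
        assert back.channel_names == small_epochs.channel_names
        assert back.srate == small_epochs.srate

    def test_eeglab_set_reader(self, tmp_path):
        pytest.importorskip("mne")
        from scipy.io import savemat
        from erplat.epochs_core import read_eeglab_epochs

        n_ch, n_t, n_ep = 4, 50, 6
        rng = np.random.default_rng(0)
        data = rng.normal(size=(n_ch, n_t, n_ep)).astype(np.float32)  # µV
        types = ["primed", "unprimed"] * 3
        events = np.array(
            [{"type": ty, "latency": float(i * n_t + 26), "epoch": float(i + 1),
              "duration": 0.0} for i, ty in enumerate(types)], dtype=object)
        epoch = np.array(
            [{"event": float(i + 1), "eventtype": types[i], "eventlatency": 0.0,
              "eventposition": 1.0, "eventduration": 0.0} for i in range(n_ep)],
            dtype=object)
        eeg = {
            "data": data, "srate": 250.0, "nbchan": float(n_ch), "pnts": float(n_t),
            "trials": float(n_ep), "xmin": -0.1, "xmax": -0.1 + (n_t - 1) / 250.0,
            "chanlocs": np.array([{"labels": f"ch{i}"} for i in range(n_ch)],
                                 dtype=object),
            "event": events, "epoch": epoch,
            "icawinv": np.array([]), "icasphere": np.array([]),
            "icaweights": np.array([]), "icaact": np.array([]),
            "ref": "averef", "setname": "synthetic test set",
        }
        path = tmp_path / "synthetic.set"
        savemat(path, {"EEG": eeg}, appendmat=False)
        ep = read_eeglab_epochs(path, subject="S05")
        assert ep.data.shape == (n_ep, n_ch, n_t)
        assert np.array_equal(ep.labels, np.array(types))
        assert ep.srate == 250.0
        assert set(ep.subjects) == {"S05"}
        assert np.allclose(ep.data, np.moveaxis(data, 2, 0), atol=1e-4)

    def test_fif_roundtrip(self, tmp_path):
        mne = pytest.importorskip("mne")
        from erplat.epochs_core import read_fif_epochs

        ep = make_epochs(n_trials=4, n_channels=4, n_samples=50)
        info = mne.create_info(ep.channel_names, ep.srate, ch_types="eeg")
        events = np.column_stack(
            [np.arange(4) * 100, np.zeros(4, int), (ep.labels == "unprimed").astype(int) + 1]
        )
        mne_ep = mne.EpochsArray(
            ep.data * 1e-6, info, events=events,
            event_id={"primed": 1, "unprimed": 2}, tmin=ep.times[0] / 1000.0,
            verbose="error",
        )
        path = tmp_path / "test-epo.fif"
        mne_ep.save(path, overwrite=True, verbose="error")
        back = read_fif_epochs(path)
        assert np.allclose(back.data, ep.data, atol=1e-6)
        assert np.array_equal(back.labels, ep.labels)
        assert back.srate == ep.srate
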