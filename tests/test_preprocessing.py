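"""Preprocessing: filtering, epoching, baselining, resampling, segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from opmbci.containers import ContinuousRecording, EpochSet, SensorLayout
from opmbci.preprocessing import (
    bandpass_filter,
    baseline_correct,
    downsample,
    extract_epochs,
    make_gradiometers,
    rereference_mastoids,
    segment_starts,
    segment_two_periods,
    two_period_samples,
)


def _recording(data, fs=1000.0, kinds=None, events=None):
    n_ch = data.shape[0]
    kinds = kinds or tuple("mag" for _ in range(n_ch))
    layout = SensorLayout(
        tuple(f"C{i}" for i in range(n_ch)), kinds,
        np.column_stack([np.arange(n_ch), np.zeros(n_ch)]),
    )
    events = events if events is not None else pd.DataFrame({"sample": [0]})
    return ContinuousRecording(data=data, fs_hz=fs, layout=layout, events=events)


def _epochs(data, fs=1000.0, t0_ms=0.0):
    n_ep, n_ch, _ = data.shape
    layout = SensorLayout(
        tuple(f"C{i}" for i in range(n_ch)), tuple("mag" for _ in range(n_ch)),
        np.column_stack([np.arange(n_ch), np.zeros(n_ch)]),
    )
    return EpochSet(data=data, fs_hz=fs, t0_ms=t0_ms,
                    labels=pd.DataFrame({"sample": np.zeros(n_ep, int)}),
                    layout=layout)


class TestBandpass:
    def test_zero_phase_impulse_symmetry(self):
        mid = 10_000
        x = np.zeros((1, 2 * mid + 1))
        x[0, mid] = 1.0
        y = bandpass_filter(_recording(x), 4.0, 40.0).data[0]
        asym = np.abs(y[mid + 1 :] - y[mid - 1 :: -1][: mid]).max()
        assert asym < 1e-9 * np.abs(y).max()

    @pytest.mark.parametrize("f_test,rtol", [(10.0, 0.01), (2.0, 0.05)])
    def test_magnitude_matches_analog_prototype_squared(self, f_test, rtol):
        # independent oracle: squared magnitude of the 4th-order analog
        # Butterworth band-pass prototype (two passes of the filter)
        b, a = sps.butter(4, [2 * np.pi * 4.0, 2 * np.pi * 40.0],
                          btype="bandpass", analog=True)
        _, h = sps.freqs(b, a, worN=[2 * np.pi * f_test])
        expected = np.abs(h[0]) ** 2
        fs, dur = 1000.0, 30.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * f_test * t)[None, :]
        y = bandpass_filter(_recording(x), 4.0, 40.0).data[0]
        mid = slice(int(5 * fs), int(25 * fs))
        ratio = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[0, mid] ** 2))
        assert ratio == pytest.approx(expected, rel=rtol)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_recording(np.zeros((1, 1000))), 4.0, 600.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(_recording(np.zeros((1, 10))), 4.0, 40.0)


class TestRereference:
    def test_mastoid_arithmetic_on_toy(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([3.0, 0.0, 1.0])
        c = np.array([5.0, 5.0, 5.0])
        rec = _recording(np.vstack([a, b, c]), kinds=("eeg", "eeg", "eeg"))
        out = rereference_mastoids(rec, "C0", "C1")
        np.testing.assert_allclose(out.data[2], c - (a + b) / 2)

    def test_common_mode_removed_and_zero_mastoids_noop(self):
        s = np.sin(np.arange(100.0))[None, :]
        rec = _recording(np.repeat(s, 3, axis=0), kinds=("eeg",) * 3)
        assert np.abs(rereference_mastoids(rec, "C0", "C1").data).max() < 1e-12
        rec2 = _recording(np.vstack([np.zeros((2, 100)), s]), kinds=("eeg",) * 3)
        np.testing.assert_array_equal(rereference_mastoids(rec2, "C0", "C1").data[2], s[0])

    def test_meg_channels_pass_through(self):
        data = np.arange(8.0).reshape(2, 4)
        rec = _recording(np.vstack([data, np.ones((2, 4))]),
                         kinds=("mag", "mag", "eeg", "eeg"))
        out = rereference_mastoids(rec, "C2", "C3")
        np.testing.assert_array_equal(out.data[:2], data)

    def test_missing_mastoid_raises(self):
        rec = _recording(np.zeros((2, 50)), kinds=("eeg", "eeg"))
        with pytest.raises(KeyError):
            rereference_mastoids(rec, "C0", "NOPE")


class TestEpoching:
    def test_window_sample_count_half_open(self):
        ev = pd.DataFrame({"sample": [1000]})
        rec = _recording(np.random.default_rng(0).normal(size=(2, 3000)), events=ev)
        ep = extract_epochs(rec, -200.0, 600.0)
        assert ep.n_samples == 800
        assert ep.t0_ms == -200.0

    def test_out_of_bounds_event_skipped(self):
        ev = pd.DataFrame({"sample": [50, 1000]})
        rec = _recording(np.zeros((1, 3000)), events=ev)
        ep = extract_epochs(rec, -200.0, 600.0)
        assert ep.n_epochs == 1
        assert ep.labels["sample"].iloc[0] == 1000

    def test_no_usable_events_raises(self):
        ev = pd.DataFrame({"sample": [10]})
        rec = _recording(np.zeros((1, 300)), events=ev)
        with pytest.raises(ValueError, match="no usable events"):
            extract_epochs(rec, -200.0, 600.0)

    def test_epoch_samples_match_source(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 2000))
        ev = pd.DataFrame({"sample": [500, 900]})
        ep = extract_epochs(_recording(data, events=ev), -100.0, 100.0)
        np.testing.assert_array_equal(ep.data[1], data[:, 800:1000])


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = _epochs(np.full((3, 2, 100), 7.0), t0_ms=-200.0, fs=500.0)
        out = baseline_correct(ep, -200.0, 0.0)
        assert np.abs(out.data).max() == 0.0

    def test_ramp_toy_and_zero_mean_property(self):
        ramp = np.arange(5.0)[None, None, :]
        ep = _epochs(ramp, t0_ms=-200.0, fs=10.0)  # baseline = first 2 samples
        out = baseline_correct(ep, -200.0, 0.0)
        np.testing.assert_allclose(out.data[0, 0], np.arange(5.0) - 0.5)
        assert abs(out.data[0, 0, :2].mean()) < 1e-12

    def test_window_outside_epoch_raises(self):
        ep = _epochs(np.zeros((1, 1, 100)), t0_ms=0.0)
        with pytest.raises(ValueError):
            baseline_correct(ep, -200.0, 0.0)


class TestDownsample:
    def test_sample_count_4s_to_150hz(self):
        ep = _epochs(np.zeros((1, 1, 4000)), fs=1000.0)
        assert downsample(ep, 150.0).n_samples == 600

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(4000) / 1000.0
        ep = _epochs(np.sin(2 * np.pi * 12.0 * t)[None, None, :], fs=1000.0)
        out = downsample(ep, 150.0)
        amp = 2 * np.abs(np.fft.rfft(out.data[0, 0])) / out.n_samples
        assert amp.max() == pytest.approx(1.0, rel=0.01)

    def test_dc_unchanged_and_upsampling_rejected(self):
        ep = _epochs(np.full((1, 1, 1000), 3.0), fs=1000.0)
        np.testing.assert_allclose(downsample(ep, 250.0).data, 3.0, rtol=1e-6)
        with pytest.raises(ValueError):
            downsample(ep, 2000.0)


class TestGradiometers:
    def test_identical_pair_is_zero(self):
        data = np.random.default_rng(0).normal(size=(1, 3, 100))
        ep = _epochs(data)
        out = make_gradiometers(ep, [("C1", "C1")])
        assert np.abs(out.data).max() == 0.0

    def test_all_pairs_of_10_magnetometers_gives_45(self):
        layout = SensorLayout.grid(2, 5)
        rec = ContinuousRecording(
            data=np.zeros((10, 50)), fs_hz=100.0, layout=layout,
            events=pd.DataFrame({"sample": [0]}),
        )
        out = make_gradiometers(rec, "all-pairs")
        assert out.n_channels == 45
        assert all(k == "grad" for k in out.layout.kinds)

    def test_antiphase_pair_snr_gain_sqrt2(self):
        rng = np.random.default_rng(2)
        n = 200_000
        s = np.sin(2 * np.pi * 10 * np.arange(n) / 1000.0)
        x = np.vstack([s + rng.normal(size=n), -s + rng.normal(size=n)])
        grad = make_gradiometers(_recording(x), [("C0", "C1")]).data[0]
        noise_var = np.var(grad - 2 * s)
        # signal doubles, independent unit noise adds: amplitude SNR x sqrt(2)
        snr_gain = (2.0 / np.sqrt(noise_var)) / 1.0
        assert snr_gain == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_unknown_channel_raises(self):
        ep = _epochs(np.zeros((1, 2, 50)))
        with pytest.raises(KeyError):
            make_gradiometers(ep, [("C0", "C9")])


class TestSegmentation:
    def test_enumeration_4s_150hz_10hz(self):
        ep = _epochs(np.zeros((1, 1, 600)), fs=150.0)
        segs = segment_two_periods(ep, 10.0)
        assert segs.segment_length == 30
        assert segs.n_segments == (600 - 30) // 15 + 1 == 39

    def test_two_period_length_12hz(self):
        assert two_period_samples(150.0, 12.0) == 25

    def test_spelling_discard_rule(self):
        n, starts = segment_starts(300, 150.0, 10.0, 0.5, discard_before_ms=150.0)
        assert n == 30
        assert starts[0] >= 23
        assert starts[0] == 30  # 0 and 15 fall before the 22.5-sample cutoff

    def test_epoch_shorter_than_two_periods_raises(self):
        ep = _epochs(np.zeros((1, 1, 20)), fs=150.0)
        with pytest.raises(ValueError, match="shorter than two periods"):
            segment_two_periods(ep, 10.0)

    def test_segments_lie_within_parent(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, 2, 601))
        ep = _epochs(data, fs=150.0)
        segs = segment_two_periods(ep, 7.5)
        for k in range(segs.n_segments):
            e, s = segs.parent_epochs[k], segs.starts[k]
            assert s + segs.segment_length <= ep.n_samples
            np.testing.assert_array_equal(
                segs.data[k], data[e, :, s : s + segs.segment_length]
            )


class TestLinearity:
    @pytest.mark.parametrize("op", [
        lambda ep: bandpass_filter(ep, 4.0, 40.0),
        lambda ep: baseline_correct(ep, -200.0, 0.0),
        lambda ep: make_gradiometers(ep, [("C0", "C1")]),
        lambda ep: downsample(ep, 250.0),
    ])
    def test_operations_are_linear(self, op):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 2, 1000))
        y = rng.normal(size=(2, 2, 1000))
        mk = lambda d: _epochs(d, fs=1000.0, t0_ms=-200.0)
        lhs = op(mk(2.0 * x - 3.0 * y)).data
        rhs = 2.0 * op(mk(x)).data - 3.0 * op(mk(y)).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9 * np.abs(rhs).max())
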