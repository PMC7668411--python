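"""Conditioning chain: filters, resampling, rejection, balancing, windows."""

import numpy as np
import pytest

from megsense import (
    EpochSet,
    SimulationConfig,
    balance_trials,
    extract_window,
    inject_artifacts,
    lowpass,
    make_layout,
    notch,
    reject_channels,
    reject_trials,
    resample,
    simulate_epochs,
)


def sine_epochs(freq: float, fs: float = 4000.0, dur: float = 2.0, amp: float = 1.0):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return EpochSet(x[None, None, :], fs, np.array([0]), ["MEG0012"], t0=0.0)


def signal_rms(e: EpochSet) -> float:
    return float(np.sqrt(np.mean(e.data.astype(float) ** 2)))


class TestLowpass:
    def test_dc_signal_passes_unchanged(self):
        e = EpochSet(np.full((1, 1, 4000), 3.0), 4000.0, np.array([0]), ["MEG0012"])
        out = lowpass(e, cutoff=250.0)
        assert np.allclose(out.data, 3.0, rtol=1e-6)

    def test_stopband_tone_strongly_attenuated(self):
        out = lowpass(sine_epochs(400.0), cutoff=250.0)
        assert signal_rms(out) < 0.05 * signal_rms(sine_epochs(400.0))

    def test_passband_tone_preserved(self):
        e = sine_epochs(40.0)
        assert signal_rms(lowpass(e, cutoff=250.0)) == pytest.approx(
            signal_rms(e), rel=0.02
        )

    def test_fs_and_shape_preserved(self):
        e = sine_epochs(40.0)
        out = lowpass(e)
        assert out.fs == e.fs and out.data.shape == e.data.shape

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(sine_epochs(40.0), cutoff=2000.0)


class TestNotch:
    def test_line_frequency_removed(self):
        out = notch(sine_epochs(60.0), base=60.0)
        assert signal_rms(out) < 0.05 * signal_rms(sine_epochs(60.0))

    def test_harmonic_also_removed(self):
        out = notch(sine_epochs(120.0), base=60.0, n_harmonics=4)
        assert signal_rms(out) < 0.05 * signal_rms(sine_epochs(120.0))

    def test_neighbouring_frequency_barely_touched(self):
        e = sine_epochs(10.0)
        assert signal_rms(notch(e, base=60.0)) > 0.98 * signal_rms(e)

    def test_zero_signal_stays_zero(self):
        e = EpochSet(np.zeros((1, 1, 4000)), 4000.0, np.array([0]), ["MEG0012"])
        assert np.allclose(notch(e).data, 0.0)


class TestResample:
    def test_4k_to_1k_length_arithmetic(self):
        e = EpochSet(
            np.random.default_rng(0).standard_normal((2, 3, 22000)),
            4000.0, np.array([0, 1]), ["MEG0012", "MEG0022", "MEG0032"], t0=-0.5,
        )
        out = resample(e, 1000.0)
        assert out.n_samples == 5500 and out.fs == 1000.0

    def test_spectral_peak_preserved(self):
        e = sine_epochs(40.0)
        out = resample(lowpass(e, 250.0), 1000.0)
        spec = np.abs(np.fft.rfft(out.data[0, 0]))
        f = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        assert abs(f[np.argmax(spec)] - 40.0) < 1.0

    def test_identity_when_target_equals_fs(self):
        e = sine_epochs(40.0)
        out = resample(e, e.fs)
        assert np.array_equal(out.data, e.data)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(sine_epochs(40.0), 8000.0)


@pytest.fixture(scope="module")
def clean_synth():
    config = SimulationConfig(
        n_sensors=6, n_classes=2, n_trials_per_class=10, fs_raw=1000.0, seed=11,
    )
    layout = make_layout(6, seed=11)
    epochs, _ = simulate_epochs(config, layout)
    return epochs, layout


class TestRejectChannels:
    def test_flat_channel_dropped_with_reason(self, clean_synth):
        epochs, layout = clean_synth
        bad, _ = inject_artifacts(epochs, rate=0.0, seed=0, flat_channel=3)
        out, report = reject_channels(bad)
        assert out.n_channels == epochs.n_channels - 1
        assert (epochs.channel_ids[3], "flat") in report.dropped_channels

    def test_clean_data_keeps_every_channel(self, clean_synth):
        epochs, _ = clean_synth
        out, report = reject_channels(epochs)
        assert out.n_channels == epochs.n_channels
        assert report.dropped_channels == []

    def test_outrageously_noisy_channel_dropped(self, clean_synth):
        epochs, _ = clean_synth
        bad = epochs.copy()
        bad.data[:, 1, :] *= 1e6
        out, report = reject_channels(bad, noisy_z=2.0)
        assert (epochs.channel_ids[1], "noisy") in report.dropped_channels

    def test_all_rejected_is_failure(self):
        e = EpochSet(np.zeros((2, 3, 200)), 1000.0, np.array([0, 1]),
                     ["MEG0012", "MEG0022", "MEG0032"])
        with pytest.raises(RuntimeError):
            reject_channels(e)


class TestRejectTrials:
    def test_exactly_the_injected_artifact_trials_removed(self, clean_synth):
        epochs, layout = clean_synth
        bad, truth = inject_artifacts(epochs, rate=0.1, seed=2, layout=layout)
        out, report = reject_trials(bad)
        dropped = {i for i, _ in report.dropped_trials}
        assert dropped == truth.artifact_trials
        assert out.n_trials == epochs.n_trials - len(truth.artifact_trials)

    def test_infinite_threshold_removes_nothing(self, clean_synth):
        epochs, _ = clean_synth
        out, report = reject_trials(epochs, peak_thresh=np.inf)
        assert out.n_trials == epochs.n_trials and report.dropped_trials == []

    def test_retained_counts_sum_to_retained_trials(self, clean_synth):
        epochs, layout = clean_synth
        bad, _ = inject_artifacts(epochs, rate=0.2, seed=5, layout=layout)
        out, report = reject_trials(bad)
        assert sum(report.retained_counts.values()) == out.n_trials

    def test_emptied_class_is_failure(self):
        data = np.ones((4, 2, 100))
        data[:2] *= 100.0  # class 0 trials all exceed the threshold
        e = EpochSet(data, 1000.0, np.array([0, 0, 1, 1]), ["MEG0012", "MEG0022"])
        with pytest.raises(RuntimeError):
            reject_trials(e, peak_thresh=10.0)


class TestBalanceAndWindow:
    def test_first_n_per_class_kept_in_acquisition_order(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 0])
        data = np.arange(7, dtype=float)[:, None, None] * np.ones((7, 1, 100))
        e = EpochSet(data, 1000.0, labels, ["MEG0012"])
        out = balance_trials(e, n_per_class=2)
        assert out.n_trials == 4
        assert list(out.data[:, 0, 0]) == [0.0, 1.0, 2.0, 3.0]

    def test_balance_is_idempotent(self, clean_synth):
        epochs, _ = clean_synth
        once = balance_trials(epochs, n_per_class=10)
        twice = balance_trials(once, n_per_class=10)
        assert np.array_equal(once.data, twice.data)

    def test_insufficient_trials_names_the_class(self, clean_synth):
        epochs, _ = clean_synth
        with pytest.raises(RuntimeError, match="class 0"):
            balance_trials(epochs, n_per_class=999)

    @pytest.mark.parametrize("stage,start", [("imagination", 1.0), ("production", 2.0)])
    def test_windows_are_one_second_at_the_stated_offset(self, clean_synth, stage, start):
        epochs, _ = clean_synth
        win = extract_window(epochs, stage)
        assert win.n_samples == 1000  # 1 s at 1 kHz
        assert win.t0 == start

    def test_windows_are_disjoint(self, clean_synth):
        epochs, _ = clean_synth
        a = extract_window(epochs, "imagination")
        b = extract_window(epochs, "production")
        assert a.t0 + a.n_samples / a.fs <= b.t0

    def test_window_outside_epoch_rejected(self):
        e = EpochSet(np.zeros((1, 1, 500)), 1000.0, np.array([0]), ["MEG0012"], t0=0.0)
        with pytest.raises(ValueError):
            extract_window(e, "production")

    def test_labels_follow_trials_through_the_chain(self, clean_synth):
        epochs, layout = clean_synth
        bad, truth = inject_artifacts(epochs, rate=0.1, seed=8, layout=layout)
        out, _ = reject_trials(bad)
        keep = [i for i in range(epochs.n_trials) if i not in truth.artifact_trials]
        assert np.array_equal(out.labels, epochs.labels[keep])
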