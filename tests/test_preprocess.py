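"""Bad-channel rules, burst cleaning, ICA heuristics, chain properties, epoching."""

import dataclasses

import numpy as np
import pytest

from mi_erd import (
    SimulationConfig,
    generate_recording,
    PreprocessParams,
    detect_bad_channels,
    burst_clean,
    remove_artifact_components,
    preprocess_continuous,
    epoch_and_reject,
)
from mi_erd.io_brainvision import Recording
from mi_erd.synthgen import CHANNELS_32, _pink_noise


def _noise_recording(seed=0, n_channels=8, duration_s=90.0, fs=125.0, corr=0.6):
    rng = np.random.default_rng(seed)
    names = CHANNELS_32[:n_channels]
    indep = _pink_noise(rng, n_channels, int(duration_s * fs), fs, 1.0, 5.0)
    shared = _pink_noise(rng, 1, int(duration_s * fs), fs, 1.0, 5.0)
    data = np.sqrt(1 - corr) * indep + np.sqrt(corr) * shared
    return Recording(data=data, sampling_rate=fs, channel_names=names)


class TestDetectBadChannels:
    def test_flat_channel_flagged(self):
        rec = _noise_recording()
        rec.data[2, 1000:1000 + int(6 * rec.sampling_rate)] = 0.0
        flags = detect_bad_channels(rec, PreprocessParams())
        assert "flat" in flags[rec.channel_names[2]]

    def test_line_noise_channel_flagged(self):
        rec = _noise_recording(fs=250.0)
        t = np.arange(rec.n_samples) / rec.sampling_rate
        rec.data[3] = 5.0 * np.sin(2 * np.pi * 50.0 * t)
        flags = detect_bad_channels(rec, PreprocessParams())
        assert "line_noise" in flags[rec.channel_names[3]]

    def test_uncorrelated_channel_flagged(self):
        rec = _noise_recording(seed=4)
        rng = np.random.default_rng(99)
        rec.data[5] = rng.normal(scale=5.0, size=rec.n_samples)
        flags = detect_bad_channels(rec, PreprocessParams())
        assert "low_correlation" in flags.get(rec.channel_names[5], [])

    def test_clean_recording_empty(self):
        assert detect_bad_channels(_noise_recording(seed=1), PreprocessParams()) == {}

    def test_single_channel_error(self):
        rec = _noise_recording(n_channels=1)
        with pytest.raises(ValueError, match="single-channel"):
            detect_bad_channels(rec, PreprocessParams())


class TestBurstClean:
    def test_pass_through_without_bursts(self):
        rec = _noise_recording(seed=2)
        out = burst_clean(rec, PreprocessParams())
        np.testing.assert_allclose(out.data, rec.data, atol=1e-8)

    def test_injected_burst_attenuated(self):
        rec = _noise_recording(seed=3)
        fs = rec.sampling_rate
        i0, i1 = int(70 * fs), int(70.2 * fs)
        background_rms = rec.data.std()
        rec.data[1, i0:i1] += 500.0
        out = burst_clean(rec, PreprocessParams())
        assert out.data[:, i0:i1].std() < 3.0 * background_rms
        # untouched stretches barely altered
        quiet = slice(0, int(30 * fs))
        delta = out.data[:, quiet] - rec.data[:, quiet]
        assert delta.std() < 0.05 * background_rms

    def test_threshold_monotonicity(self):
        rec = _noise_recording(seed=5)
        fs = rec.sampling_rate
        rec.data[0, int(65 * fs):int(65.3 * fs)] += 300.0
        rec.data[4, int(80 * fs):int(80.1 * fs)] += 120.0

        def altered(sd):
            params = dataclasses.replace(PreprocessParams(), burst_criterion_sd=sd)
            out = burst_clean(rec, params)
            return int((np.abs(out.data - rec.data) > 1e-6).sum())

        counts = [altered(sd) for sd in (5.0, 10.0, 20.0, 40.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_too_short_recording_errors(self):
        rec = _noise_recording(duration_s=30.0)
        with pytest.raises(ValueError, match="calibration"):
            burst_clean(rec, PreprocessParams())


@pytest.fixture(scope="module")
def blink_recording():
    import mne

    cfg = SimulationConfig(seed=5, blinks=True)
    rec, truth = generate_recording(cfg)
    rec.data = mne.filter.filter_data(rec.data, rec.sampling_rate, 1.0, 40.0,
                                      phase="zero", verbose="error")
    return rec, truth


class TestICARemoval:
    def _blink_peak(self, rec, truth):
        fp1 = rec.channel_names.index("Fp1")
        fs = rec.sampling_rate
        peaks = []
        for bt in truth["blink_times_s"]:
            i0, i1 = int((bt - 0.3) * fs), int((bt + 0.3) * fs)
            peaks.append(np.abs(rec.data[fp1, i0:i1]).max())
        return np.mean(peaks)

    def test_blink_component_flagged_and_removed(self, blink_recording):
        rec, truth = blink_recording
        cleaned, report = remove_artifact_components(rec, PreprocessParams())
        assert any(d["label"] == "blink" for d in report["removed"])
        before = self._blink_peak(rec, truth)
        after = self._blink_peak(cleaned, truth)
        assert after < 0.5 * before

    def test_removal_cap_respected(self, blink_recording):
        """Removals are flagged components truncated at the configured cap."""
        rec, _ = blink_recording
        params = dataclasses.replace(PreprocessParams(), max_ica_components_removed=0)
        cleaned, report = remove_artifact_components(rec, params)
        assert len(report["flagged"]) >= 1
        assert report["removed"] == []
        np.testing.assert_allclose(cleaned.data, rec.data, atol=1e-8)

    def test_clean_recording_untouched(self):
        import mne

        rec, _ = generate_recording(SimulationConfig(seed=6))
        rec.data = mne.filter.filter_data(rec.data, rec.sampling_rate, 1.0, 40.0,
                                          phase="zero", verbose="error")
        cleaned, report = remove_artifact_components(rec, PreprocessParams())
        assert report["removed"] == []
        delta_rms = (cleaned.data - rec.data).std()
        assert delta_rms < 0.05 * rec.data.std()


class TestContinuousChain:
    def test_car_property(self, clean_epochs):
        report = clean_epochs.meta["preprocess_report"]
        assert "ica" in report  # chain completed

    def test_car_zero_mean(self, default_subject):
        rec, _ = default_subject
        params = dataclasses.replace(PreprocessParams(), max_ica_components_removed=0)
        clean, _ = preprocess_continuous(rec, params)
        channel_mean = clean.data.mean(axis=0)
        assert np.abs(channel_mean).max() < 1e-6
        assert clean.reference == "CAR"

    def test_event_reindexing_on_resample(self, default_subject):
        rec, _ = default_subject
        clean, _ = preprocess_continuous(rec, PreprocessParams())
        assert len(clean.events) == len(rec.events)
        for (s_new, d_new), (s_old, d_old) in zip(clean.events, rec.events):
            assert d_new == d_old
            assert s_new == round(s_old * 125.0 / 250.0)

    def test_45hz_attenuated_20db(self):
        rng = np.random.default_rng(7)
        fs = 250.0
        n = int(120 * fs)
        t = np.arange(n) / fs
        names = CHANNELS_32[:6]
        shared = _pink_noise(rng, 1, n, fs, 1.0, 3.0)
        data = shared + 0.5 * _pink_noise(rng, 6, n, fs, 1.0, 3.0)
        data += 5.0 * np.sin(2 * np.pi * 45.0 * t)[None, :]
        rec = Recording(data=data, sampling_rate=fs, channel_names=names)
        params = dataclasses.replace(PreprocessParams(), max_ica_components_removed=0)
        clean, _ = preprocess_continuous(rec, params)

        def power_45(x, fs_):
            freqs = np.fft.rfftfreq(x.shape[1], 1 / fs_)
            psd = (np.abs(np.fft.rfft(x, axis=1)) ** 2).mean(axis=0)
            return psd[(freqs > 44.5) & (freqs < 45.5)].sum() / x.shape[1]

        # compare per-sample 45 Hz power density before (250 Hz) / after (125 Hz)
        before = power_45(rec.data, 250.0)
        after = power_45(clean.data, 125.0)
        assert 10 * np.log10(before / after) >= 20.0

    def test_majority_bad_aborts(self):
        rec = _noise_recording(n_channels=6)
        rec.data[:4] = 0.0
        with pytest.raises(RuntimeError, match="quality"):
            preprocess_continuous(rec, PreprocessParams())

    def test_order_stability_second_pass(self, default_subject):
        """A second pass over already-cleaned data leaves signal RMS stable
        (and flags nothing new)."""
        rec, _ = default_subject
        params = dataclasses.replace(PreprocessParams(), max_ica_components_removed=0)
        once, _ = preprocess_continuous(rec, params)
        params2 = dataclasses.replace(params, target_rate=once.sampling_rate)
        twice, report2 = preprocess_continuous(once, params2)
        assert report2["bad_channels"] == {}
        rel = abs(twice.data.std() - once.data.std()) / once.data.std()
        assert rel < 0.01


class TestEpoching:
    def test_count_conservation(self, clean_epochs):
        assert clean_epochs.n_trials == 30
        _, counts = np.unique(clean_epochs.labels, return_counts=True)
        assert counts.tolist() == [15, 15]

    def test_spike_rejection(self, default_subject):
        rec, _ = default_subject
        rec = rec.copy()
        cue, _ = rec.events[4]
        rec.data[0, cue + 100] += 400.0
        params = dataclasses.replace(PreprocessParams(), epoch_reject_uv=200.0)
        epochs = epoch_and_reject(rec, params)
        assert epochs.n_trials == 29
        assert any("p2p" in reason for _, reason in epochs.dropped)

    def test_time_axis_half_open(self, clean_epochs):
        fs = clean_epochs.sampling_rate
        assert clean_epochs.time_axis[0] == pytest.approx(-5.0)
        assert clean_epochs.time_axis[-1] == pytest.approx(5.0 - 1.0 / fs)

    def test_edge_trial_skipped_with_warning(self, default_subject):
        rec, _ = default_subject
        rec = rec.copy()
        rec.events = [(100, "S  1")] + rec.events  # cue 0.4 s from start
        with pytest.warns(UserWarning, match="edge"):
            epochs = epoch_and_reject(rec)
        assert epochs.n_trials == 30
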