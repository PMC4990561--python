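"""Filtering, artifact guides, and the two-pass ICA procedure."""

import numpy as np
import pytest

from affectsync import (bandpass, blinks_from_gaze, motion_flags, notch,
                        two_pass_ica)
from affectsync.core import (EEG_CHANNELS, GazeSample, StimulusEvent,
                             TimeSeries, resample_indicator)
from affectsync.preprocess import ArtifactMask, flag_bad_epochs
from affectsync.sync import extract_epochs

from conftest import make_eeg

RATE = 128.0


def _sine(freq, seconds=20.0, amp=1.0):
    t = np.arange(0, seconds, 1 / RATE)
    return amp * np.sin(2 * np.pi * freq * t)


def _rms(x):
    trim = int(2 * RATE)  # drop filter edge transients
    return np.sqrt(np.mean(x[trim:-trim] ** 2))


class TestBandpass:
    def test_in_band_amplitude_preserved(self):
        out = bandpass(make_eeg(_sine(10))).series.values[:, 0]
        assert _rms(out) == pytest.approx(_rms(_sine(10)), rel=0.05)

    def test_60hz_attenuated_20db(self):
        out = bandpass(make_eeg(_sine(60))).series.values[:, 0]
        att_db = 20 * np.log10(_rms(out) / _rms(_sine(60)))
        assert att_db <= -20

    def test_dc_offset_removed(self):
        out = bandpass(make_eeg(np.full(int(20 * RATE), 100.0)))
        assert abs(out.series.values[:, 0].mean()) < 1.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="invalid band"):
            bandpass(make_eeg(_sine(10)), low=50, high=0.1)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((int(10 * RATE), 14))
        y = rng.standard_normal((int(10 * RATE), 14))
        a, b = 2.5, -1.3
        fx = bandpass(make_eeg(x)).series.values
        fy = bandpass(make_eeg(y)).series.values
        fxy = bandpass(make_eeg(a * x + b * y)).series.values
        np.testing.assert_allclose(fxy, a * fx + b * fy, atol=1e-8)


class TestNotch:
    def test_50hz_attenuated_20db(self):
        out = notch(make_eeg(_sine(50))).series.values[:, 0]
        assert 20 * np.log10(_rms(out) / _rms(_sine(50))) <= -20

    @pytest.mark.parametrize("freq", [10.0, 45.0, 55.0])
    def test_neighbours_pass(self, freq):
        out = notch(make_eeg(_sine(freq))).series.values[:, 0]
        change_db = abs(20 * np.log10(_rms(out) / _rms(_sine(freq))))
        assert change_db < 3

    def test_zero_in_zero_out(self):
        out = notch(make_eeg(np.zeros(int(5 * RATE))))
        np.testing.assert_allclose(out.series.values, 0.0, atol=1e-12)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch(make_eeg(_sine(10)), freq=64.0)


class TestBlinksFromGaze:
    @staticmethod
    def _gaze(invalid_spans, rate=60.0, seconds=10.0):
        out = []
        for i in range(int(seconds * rate)):
            t = i / rate
            bad = any(a <= t < b for a, b in invalid_spans)
            out.append(GazeSample(t=t, x=1.0, y=1.0, valid_left=not bad,
                                  valid_right=not bad))
        return out

    def test_200ms_run_is_blink(self):
        blinks = blinks_from_gaze(self._gaze([(2.0, 2.2)]))
        assert len(blinks) == 1
        a, b = blinks[0]
        assert a == pytest.approx(2.0, abs=0.02)
        assert b - a == pytest.approx(0.2, abs=0.04)

    def test_2s_run_is_dropout_not_blink(self):
        assert blinks_from_gaze(self._gaze([(2.0, 4.0)])) == []

    def test_planted_schedule_recovered(self, default_session):
        bundle, gt = default_session
        found = blinks_from_gaze(bundle.gaze)
        # blinks at the recording edges or shorter than min_gap may drop out
        assert len(found) >= 0.9 * len(gt.blink_intervals)
        tol = 2 / 60  # one gaze sample each side
        for a, b in found:
            assert any(abs(a - ga) <= tol for ga, _ in gt.blink_intervals)


class TestMotionFlags:
    def test_constant_gravity_no_flags(self):
        acc = TimeSeries(np.tile([0.0, 0.0, 1.0], (320, 1)), rate=32,
                         channel_labels=["x", "y", "z"])
        assert motion_flags(acc, threshold_g=0.2) == []

    def test_planted_shake_flagged(self):
        rng = np.random.default_rng(3)
        v = np.tile([0.0, 0.0, 1.0], (320, 1)) + 0.01 * rng.standard_normal((320, 1))
        v[160:176, 0] += 1.5  # 0.5 s shake at t = 5
        acc = TimeSeries(v, rate=32, channel_labels=["x", "y", "z"])
        flags = motion_flags(acc, threshold_g=0.5)
        assert len(flags) == 1
        a, b = flags[0]
        assert a <= 5.0 <= b

    def test_infinite_threshold_no_flags(self):
        rng = np.random.default_rng(0)
        acc = TimeSeries(rng.standard_normal((320, 3)), rate=32,
                         channel_labels=["x", "y", "z"])
        assert motion_flags(acc, threshold_g=np.inf) == []

    def test_non_3channel_rejected(self):
        acc = TimeSeries(np.zeros((320, 2)), rate=32,
                         channel_labels=["x", "y"])
        with pytest.raises(ValueError, match="3 channels"):
            motion_flags(acc, threshold_g=0.1)


def _epochs_for(eeg, n=6, dur=5.0):
    stimuli = [StimulusEvent(id=f"s{i}", category="neutral", kind="image",
                             onset=dur * i, duration=dur) for i in range(n)]
    return extract_epochs(eeg.series, stimuli)


class TestTwoPassICA:
    @staticmethod
    def _blinky_eeg(seed, seconds=40.0, blink_amp=80.0):
        """Mixed independent sources + one blink source with a known
        frontal topography and known blink times."""
        rng = np.random.default_rng(seed)
        n = int(seconds * RATE)
        t = np.arange(n) / RATE
        sources = rng.standard_normal((n, 14))
        blink_times = np.arange(2.0, seconds - 2.0, 3.1)
        intervals = [(tb, tb + 0.25) for tb in blink_times]
        ind = resample_indicator(intervals, t)
        sources[:, 0] = 8.0 * ind + 0.1 * rng.standard_normal(n)
        topo = np.array([1.0, 0.6, 0.5, 0.3] + [0.05] * 6 + [0.3, 0.5, 0.6, 1.0])
        mixing = rng.standard_normal((14, 14)) * 0.5
        mixing[:, 0] = topo * blink_amp / 8.0
        return make_eeg(sources @ mixing.T), intervals

    def test_blink_component_found_in_90pct_of_runs(self):
        hits = 0
        for seed in range(50):
            eeg, intervals = self._blinky_eeg(seed)
            mask = ArtifactMask(blink_intervals=intervals)
            _, model, _ = two_pass_ica(eeg, _epochs_for(eeg), mask, seed=seed)
            if model.removed and (model.component_scores[model.removed[0]]
                                  == model.component_scores.max()):
                hits += 1
        assert hits >= 45

    def test_identity_when_no_blinks(self, ):
        rng = np.random.default_rng(7)
        eeg = make_eeg(rng.standard_normal((int(40 * RATE), 14)))
        cleaned, model, _ = two_pass_ica(eeg, _epochs_for(eeg),
                                         ArtifactMask())
        assert model.removed == []
        np.testing.assert_allclose(cleaned.series.values, eeg.series.values,
                                   atol=1e-6)
        assert model.check(tol=1e-6)

    def test_planted_500uv_epoch_marked_bad(self):
        rng = np.random.default_rng(11)
        x = 10 * rng.standard_normal((int(40 * RATE), 14))
        x[int(7 * RATE):int(8 * RATE), :] = 500.0
        eeg = make_eeg(x)
        epochs = _epochs_for(eeg, n=8)
        bad = flag_bad_epochs(eeg, epochs)
        assert 1 in bad and "amplitude" in bad[1]

    def test_insufficient_data_after_pruning(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((int(2 * RATE), 14))
        eeg = make_eeg(x)
        stimuli = [StimulusEvent(id="s", category="neutral", kind="image",
                                 onset=0.0, duration=2.0)]
        epochs = extract_epochs(eeg.series, stimuli)
        x[10, 0] = 1e4  # force the whole (only) epoch bad
        with pytest.raises(RuntimeError, match="insufficient data"):
            two_pass_ica(eeg, epochs, ArtifactMask())

    def test_bad_epoch_set_invariant_to_channel_order(self):
        rng = np.random.default_rng(13)
        x = 10 * rng.standard_normal((int(30 * RATE), 14))
        x[int(12 * RATE), 3] = 400.0
        eeg = make_eeg(x)
        perm = rng.permutation(14)
        shuffled = TimeSeries(x[:, perm], rate=RATE,
                              channel_labels=[EEG_CHANNELS[i] for i in perm])
        eeg2 = eeg.with_series(shuffled)
        assert (set(flag_bad_epochs(eeg, _epochs_for(eeg)))
                == set(flag_bad_epochs(eeg2, _epochs_for(eeg2))))
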