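"""Cross-device synchronization and stimulus-locked epoch extraction.

The EEG stream carries no timestamps; the eye tracker (and its audio
track) does.  A loud sound played at the start of the session appears in
the audio track and, through the participant's evoked response, in the
EEG.  Matching the two landmarks shifts the EEG onto the session clock.
Peripheral wristband streams and gaze are natively timestamped and pass
through alignment untouched.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (Epoch, EEGRecording, SessionBundle, StimulusEvent,
                   TimeSeries, reject)


class SpikeNotFoundError(RuntimeError):
    pass


def detect_audio_spike(audio: TimeSeries, threshold_sd: float = 6.0) -> float:
    """Time (session clock) of the first sample exceeding ``threshold_sd``
    robust noise scales, i.e. the onset of the synchronization sound.

    The noise scale is 1.4826 x the median absolute deviation, so the
    spike itself cannot inflate the threshold.  Ties/late crossings are
    resolved by taking the earliest crossing.
    """
    if audio.n_channels != 1:
        raise ValueError("audio must be single channel")
    if audio.duration < 1.0:
        raise ValueError("audio shorter than 1 s")
    x = audio.values[:, 0]
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(x) or np.finfo(float).tiny
    z = np.abs(x - med) / scale
    hits = np.nonzero(z > threshold_sd)[0]
    if hits.size == 0:
        raise SpikeNotFoundError(
            f"no spike found: max |z| = {z.max():.2f} <= {threshold_sd}")
    return audio.offset + hits[0] / audio.rate


def detect_eeg_spike_response(eeg: EEGRecording,
                              search_window: tuple[float, float] | None = None
                              ) -> float:
    """Time (EEG stream clock) of the maximal cross-channel RMS deviation
    from the window baseline -- the EEG-side sync landmark.

    Earliest maximum wins on ties.
    """
    ts = eeg.series
    if search_window is None:
        search_window = (ts.offset, ts.end)
    lo, hi = search_window
    win = ts.slice_seconds(lo, hi)
    if win.n_samples == 0:
        raise ValueError(f"search window {search_window} contains no samples")
    dev = win.values - win.values.mean(axis=0, keepdims=True)
    rms = np.sqrt((dev ** 2).mean(axis=1))
    idx = int(np.argmax(rms))  # argmax returns the first maximum
    return win.offset + idx / win.rate


def align_session(bundle: SessionBundle, threshold_sd: float = 6.0,
                  max_lag: float = 12.0) -> SessionBundle:
    """Shift the EEG onto the session clock via the audio spike.

    The EEG-side landmark is searched from the start of the EEG stream up
    to ``audio spike time + max_lag`` on the stream's own clock (the
    headset is started no more than ``max_lag`` seconds before the
    session clock's zero).  Idempotent: realigning an aligned bundle is a
    no-op up to numerical identity.
    """
    t_audio = detect_audio_spike(bundle.audio, threshold_sd=threshold_sd)
    ts = bundle.eeg.series
    hi = min(ts.end, ts.offset + (t_audio - bundle.audio.offset) + max_lag)
    t_eeg = detect_eeg_spike_response(bundle.eeg, (ts.offset, hi))
    new_offset = ts.offset + (t_audio - t_eeg)
    eeg = bundle.eeg.with_series(ts.shifted(new_offset))
    return SessionBundle(eeg=eeg, peripherals=bundle.peripherals,
                         gaze=bundle.gaze, audio=bundle.audio,
                         stimuli=bundle.stimuli,
                         participant_meta=bundle.participant_meta)


def extract_epochs(stream: TimeSeries,
                   stimuli: list[StimulusEvent]) -> list[Epoch]:
    """One epoch per stimulus over the half-open [onset, onset+duration).

    The epoch length is always ``round(duration * rate)`` samples, so
    disjoint stimuli on a sufficient recording conserve samples exactly.
    Stimuli reaching outside the recorded span yield epochs marked
    rejected with reason ``"truncated"`` (never a failure).
    """
    epochs = []
    for stim in stimuli:
        n_want = round(stim.duration * stream.rate)
        i0 = math.ceil((stim.onset - stream.offset) * stream.rate - 1e-9)
        i1 = i0 + n_want
        lo = max(i0, 0)
        hi = min(i1, stream.n_samples)
        hi = max(hi, lo)
        data = TimeSeries(stream.values[lo:hi].copy(), rate=stream.rate,
                          offset=stream.offset + lo / stream.rate,
                          channel_labels=list(stream.channel_labels))
        ep = Epoch(stimulus=stim, data=data)
        if lo != i0 or hi != i1:
            ep = reject(ep, "truncated")
        epochs.append(ep)
    return epochs
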