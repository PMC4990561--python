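"""Synthetic synchronized sessions with planted ground truth.

Every stream of a real session is emulated with known structure so each
pipeline stage can be scored without any recorded data: EEG is pink
noise plus stimulus-locked 9 Hz alpha with a planted hemispheric power
boost (right hemisphere for unpleasant stimuli, left for pleasant) and
blink artifacts; electrodermal activity is a tonic drift plus an SCR
event train, or a flat near-zero "U" for the self-regulated profile;
gaze samples land in the eyes/mouth AOIs with planted probabilities and
go invalid during blinks; the audio track carries the synchronization
spike at a planted device lag.  Generation is a pure function of the
spec (same seed, same bytes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .core import (EEG_CHANNELS, LEFT_CHANNELS, RIGHT_CHANNELS, EEGRecording,
                   GazeSample, SessionBundle, StimulusEvent, TimeSeries)

SCREEN_W, SCREEN_H = 1280, 1024
#: AOI rectangles used for every video stimulus (coordinates, not pixels
#: of any actual face image).
VIDEO_AOIS = [
    {"label": "eyes", "x0": 440, "y0": 200, "x1": 840, "y1": 320},
    {"label": "mouth", "x0": 520, "y0": 480, "x1": 760, "y1": 580},
]

#: Blink artifact projection strength per channel (frontal-dominant).
_BLINK_WEIGHTS = {"AF3": 1.0, "AF4": 1.0, "F7": 0.6, "F8": 0.6,
                  "F3": 0.5, "F4": 0.5, "FC5": 0.3, "FC6": 0.3}


@dataclass
class SessionSpec:
    """Study conditions of one synthetic session.

    Defaults mirror the emulated protocol: 31 affective images
    (11 pleasant / 13 unpleasant / 7 neutral) shown 5 s each, then 4
    videos of 15 s, with image order counterbalanced by a cyclic Latin
    square.
    """

    seed: int = 0
    n_pleasant: int = 11
    n_unpleasant: int = 13
    n_neutral: int = 7
    n_videos: int = 4
    image_duration: float = 5.0
    video_duration: float = 15.0
    asymmetry_boost: float = 2.0   # alpha power multiplier, boosted side
    eda_profile: str = "reactive"  # "reactive" | "flat"
    scr_rate: float = 3.0          # SCR events/min (reactive profile)
    gaze_eyes_frac: float = 0.6
    gaze_mouth_frac: float = 0.25
    blink_rate: float = 8.0        # blinks/min
    sync_lag: float = 2.0          # s the headset starts before session 0
    snr: float = 5.0               # alpha power over in-band noise power
    eeg_rate: float = 128.0
    audio_rate: float = 1000.0
    gaze_rate: float = 60.0
    baseline: float = 20.0         # s before the first stimulus
    tail: float = 10.0
    spike_time: float = 5.0        # sync sound, session clock
    participant_index: int = 0
    antidepressant: bool = False

    def __post_init__(self) -> None:
        if self.gaze_eyes_frac + self.gaze_mouth_frac > 1:
            raise ValueError("gaze fractions must sum to at most 1")
        if self.eda_profile not in ("reactive", "flat"):
            raise ValueError("eda_profile must be 'reactive' or 'flat'")
        if self.sync_lag < 0:
            raise ValueError("sync_lag must be nonnegative")

    @property
    def n_images(self) -> int:
        return self.n_pleasant + self.n_unpleasant + self.n_neutral

    @property
    def total_duration(self) -> float:
        return (self.baseline + self.n_images * self.image_duration
                + self.n_videos * self.video_duration + self.tail)


@dataclass
class GroundTruth:
    """Everything planted, for scoring the downstream detectors."""

    categories: dict[str, str]
    asymmetry_sign: dict[str, int]   # +1 left-dominant alpha, -1 right, 0 none
    scr_events: list[tuple[float, float]]  # (onset s, amplitude uS)
    blink_intervals: list[tuple[float, float]]
    sync_lag: float
    gaze_eyes_frac: float
    gaze_mouth_frac: float
    group: str                       # G1 non-self-regulated | G2 self-regulated
    eda_profile: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["scr_events"] = [tuple(e) for e in d["scr_events"]]
        d["blink_intervals"] = [tuple(e) for e in d["blink_intervals"]]
        return cls(**d)


def latin_square_order(n_stimuli: int, participant_index: int) -> list[int]:
    """Row ``participant_index mod n`` of the cyclic Latin square of
    order ``n``: position j shows stimulus (i + j) mod n."""
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    i = participant_index % n_stimuli
    return [(i + j) % n_stimuli for j in range(n_stimuli)]


# ------------------------------------------------------------- pieces

def _pink_noise(rng: np.random.Generator, n: int, n_ch: int,
                sigma: float) -> np.ndarray:
    """1/f-amplitude noise, independent phase per channel, std sigma."""
    white = rng.standard_normal((n, n_ch))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)[:, None]
    x = np.fft.irfft(spec, n=n, axis=0)
    x *= sigma / x.std(axis=0, keepdims=True)
    return x


def _scr_shape(t: np.ndarray, rise: float = 0.7, decay: float = 3.0
               ) -> np.ndarray:
    """Canonical SCR waveform: difference of exponentials, unit peak."""
    w = np.exp(-t / decay) - np.exp(-t / rise)
    peak = w.max()
    return w / peak if peak > 0 else w


def _build_stimuli(spec: SessionSpec, rng: np.random.Generator
                   ) -> list[StimulusEvent]:
    cats = (["pleasant"] * spec.n_pleasant
            + ["unpleasant"] * spec.n_unpleasant
            + ["neutral"] * spec.n_neutral)
    norms = {"pleasant": (7.2, 5.5), "unpleasant": (2.2, 6.0),
             "neutral": (5.0, 3.0)}
    images = []
    for i, cat in enumerate(cats):
        v, a = norms[cat]
        images.append(dict(id=f"img{i:02d}", category=cat, kind="image",
                           iaps_valence=float(np.clip(v + 0.4 * rng.standard_normal(), 1, 9)),
                           iaps_arousal=float(np.clip(a + 0.6 * rng.standard_normal(), 1, 9))))
    order = latin_square_order(spec.n_images, spec.participant_index)
    events = []
    t = spec.baseline
    for pos, idx in enumerate(order):
        img = images[idx]
        events.append(StimulusEvent(onset=t, duration=spec.image_duration,
                                    **img))
        t += spec.image_duration
    vid_cats = (["pleasant", "unpleasant"] * ((spec.n_videos + 1) // 2))
    for j in range(spec.n_videos):
        events.append(StimulusEvent(id=f"vid{j}", category=vid_cats[j],
                                    kind="video", onset=t,
                                    duration=spec.video_duration))
        t += spec.video_duration
    return events


def _gen_eeg(spec: SessionSpec, stimuli: list[StimulusEvent],
             blink_times: np.ndarray, rng: np.random.Generator
             ) -> EEGRecording:
    rate = spec.eeg_rate
    lag = spec.sync_lag
    n = round((spec.total_duration + lag) * rate)
    noise_sigma = 10.0  # uV
    x = _pink_noise(rng, n, len(EEG_CHANNELS), noise_sigma)

    # in-band noise power per channel -> alpha amplitude at the target SNR
    f, psd = signal.welch(x, fs=rate, axis=0, nperseg=int(2 * rate))
    band = (f >= 7) & (f <= 10)
    p_band = np.trapezoid(psd[band], f[band], axis=0)
    base_amp = np.sqrt(2 * spec.snr * p_band)  # sinusoid amplitude per channel

    left = [EEG_CHANNELS.index(c) for c in LEFT_CHANNELS]
    right = [EEG_CHANNELS.index(c) for c in RIGHT_CHANNELS]
    t_int = np.arange(n) / rate  # headset-internal clock
    for stim in stimuli:
        a, b = stim.onset + lag, stim.end + lag
        sel = (t_int >= a) & (t_int < b)
        m = int(sel.sum())
        if m == 0:
            continue
        gain = np.ones(len(EEG_CHANNELS))
        if stim.category == "unpleasant":
            gain[right] = np.sqrt(spec.asymmetry_boost)
        elif stim.category == "pleasant":
            gain[left] = np.sqrt(spec.asymmetry_boost)
        env = signal.windows.tukey(m, alpha=0.1)
        phase = rng.uniform(0, 2 * np.pi, len(EEG_CHANNELS))
        tt = t_int[sel]
        burst = np.sin(2 * np.pi * 9.0 * tt[:, None] + phase[None, :])
        x[sel] += env[:, None] * burst * (base_amp * gain)[None, :]

    # blink artifacts: 400 ms half-cosine, frontal-dominant
    w = np.array([_BLINK_WEIGHTS.get(c, 0.05) for c in EEG_CHANNELS])
    for tb in blink_times:
        i0 = int(round((tb + lag - 0.1) * rate))
        m = int(round(0.4 * rate))
        if i0 < 0 or i0 + m > n:
            continue
        tpl = 120.0 * np.sin(np.linspace(0, np.pi, m))
        x[i0:i0 + m] += tpl[:, None] * w[None, :]

    # evoked response to the sync sound: sharp decaying broadband pulse
    i_sp = int(round((spec.spike_time + lag) * rate))
    m = int(round(0.05 * rate))
    tpl = 150.0 * np.exp(-np.arange(m) / (0.01 * rate))
    x[i_sp:i_sp + m] += tpl[:, None]

    series = TimeSeries(x, rate=rate, offset=0.0,
                        channel_labels=list(EEG_CHANNELS))
    return EEGRecording(series=series)


def _gen_eda(spec: SessionSpec, rng: np.random.Generator
             ) -> tuple[TimeSeries, list[tuple[float, float]]]:
    rate, T = 4.0, spec.total_duration
    t = np.arange(round(T * rate)) / rate
    events: list[tuple[float, float]] = []
    if spec.eda_profile == "flat":
        # very flat "U", nearly zero, no phasic activity
        x = 0.04 + 0.03 * ((t - T / 2) / (T / 2)) ** 2
        x = x + 0.002 * rng.standard_normal(len(t))
    else:
        x = (2.0 + 0.2 * np.sin(2 * np.pi * t / 240.0 + rng.uniform(0, 2 * np.pi))
             + 0.01 * rng.standard_normal(len(t)))
        span0, span1 = spec.baseline, T - spec.tail
        n_ev = rng.poisson(spec.scr_rate * (span1 - span0) / 60.0)
        onsets = np.sort(rng.uniform(span0, span1, n_ev))
        for on in onsets:
            amp = rng.uniform(0.2, 1.0)
            tau = t[t >= on] - on
            x[t >= on] += amp * _scr_shape(tau)
            events.append((float(on), float(amp)))
    x = np.maximum(x, 0.0)
    return (TimeSeries(x.reshape(-1, 1), rate=rate, offset=0.0,
                       channel_labels=["EDA"]), events)


def _gen_peripherals(spec: SessionSpec, rng: np.random.Generator
                     ) -> tuple[dict[str, TimeSeries], list[tuple[float, float]]]:
    T = spec.total_duration
    eda, scr_events = _gen_eda(spec, rng)

    t_bvp = np.arange(round(T * 64)) / 64
    bvp = (np.sin(2 * np.pi * 1.17 * t_bvp)
           + 0.1 * rng.standard_normal(len(t_bvp)))
    t_hr = np.arange(round(T * 1)) / 1
    hr = 70.0 + 2.0 * rng.standard_normal(len(t_hr))
    t_temp = np.arange(round(T * 4)) / 4
    temp = 33.5 + 0.1 * t_temp / T + 0.02 * rng.standard_normal(len(t_temp))
    n_acc = round(T * 32)
    acc = np.column_stack([
        0.02 * rng.standard_normal(n_acc),
        0.02 * rng.standard_normal(n_acc),
        1.0 + 0.02 * rng.standard_normal(n_acc),
    ])
    mk = lambda v, r, labels: TimeSeries(v if v.ndim == 2 else v.reshape(-1, 1),
                                         rate=r, offset=0.0,
                                         channel_labels=labels)
    return ({"EDA": eda,
             "BVP": mk(bvp, 64, ["BVP"]),
             "HR": mk(hr, 1, ["HR"]),
             "TEMP": mk(temp, 4, ["TEMP"]),
             "ACC": mk(acc, 32, ["ACC_x", "ACC_y", "ACC_z"])},
            scr_events)


def _sample_point(rng: np.random.Generator, region: str) -> tuple[float, float]:
    eyes, mouth = VIDEO_AOIS
    if region == "eyes":
        r = eyes
    elif region == "mouth":
        r = mouth
    else:
        while True:
            x = rng.uniform(0, SCREEN_W)
            y = rng.uniform(0, SCREEN_H)
            if not any(rr["x0"] <= x <= rr["x1"] and rr["y0"] <= y <= rr["y1"]
                       for rr in VIDEO_AOIS):
                return x, y
    return rng.uniform(r["x0"], r["x1"]), rng.uniform(r["y0"], r["y1"])


def _gen_gaze(spec: SessionSpec, stimuli: list[StimulusEvent],
              blink_intervals: list[tuple[float, float]],
              rng: np.random.Generator) -> list[GazeSample]:
    T = spec.total_duration
    times = np.arange(round(T * spec.gaze_rate)) / spec.gaze_rate
    videos = [s for s in stimuli if s.kind == "video"]
    samples = []
    p_eyes, p_mouth = spec.gaze_eyes_frac, spec.gaze_mouth_frac
    for t in times:
        blinked = any(a <= t < b for a, b in blink_intervals)
        if blinked:
            samples.append(GazeSample(t=float(t), x=0.0, y=0.0,
                                      valid_left=False, valid_right=False))
            continue
        in_video = any(v.onset <= t < v.end for v in videos)
        if in_video:
            u = rng.uniform()
            region = ("eyes" if u < p_eyes
                      else "mouth" if u < p_eyes + p_mouth else "other")
        else:
            region = "other"
        x, y = _sample_point(rng, region)
        pupil = 3.0 + 0.1 * rng.standard_normal()
        samples.append(GazeSample(t=float(t), x=float(x), y=float(y),
                                  pupil_left=float(pupil),
                                  pupil_right=float(pupil)))
    return samples


def _gen_audio(spec: SessionSpec, rng: np.random.Generator) -> TimeSeries:
    n = round(spec.total_duration * spec.audio_rate)
    x = rng.standard_normal(n)
    i = int(round(spec.spike_time * spec.audio_rate))
    m = int(round(0.01 * spec.audio_rate))
    x[i:i + m] += 20.0
    return TimeSeries(x.reshape(-1, 1), rate=spec.audio_rate, offset=0.0,
                      channel_labels=["audio"])


# ------------------------------------------------------------ session

def gen_session(spec: SessionSpec) -> tuple[SessionBundle, GroundTruth]:
    """Generate one full synchronized session with its ground truth.

    The EEG stream is delivered *unaligned*: its offset is 0 on its own
    device clock while every event actually sits ``sync_lag`` seconds
    later in the stream, exactly the situation the audio-spike alignment
    resolves.
    """
    rng = np.random.default_rng(spec.seed)
    stimuli = _build_stimuli(spec, rng)

    n_blinks = rng.poisson(spec.blink_rate * spec.total_duration / 60.0)
    blink_times = np.sort(rng.uniform(1.0, spec.total_duration - 1.0, n_blinks))
    blink_intervals = [(float(tb), float(tb) + 0.2) for tb in blink_times]

    eeg = _gen_eeg(spec, stimuli, blink_times, rng)
    peripherals, scr_events = _gen_peripherals(spec, rng)
    gaze = _gen_gaze(spec, stimuli, blink_intervals, rng)
    audio = _gen_audio(spec, rng)

    meta = {"age": int(rng.integers(20, 31)),
            "sex": "F" if rng.uniform() < 38 / 44 else "M",
            "antidepressant": spec.antidepressant,
            "deaf": False}
    bundle = SessionBundle(eeg=eeg, peripherals=peripherals, gaze=gaze,
                           audio=audio, stimuli=stimuli,
                           participant_meta=meta)
    sign = {"pleasant": 1, "unpleasant": -1, "neutral": 0}
    gt = GroundTruth(
        categories={s.id: s.category for s in stimuli},
        asymmetry_sign={s.id: sign[s.category] for s in stimuli},
        scr_events=scr_events,
        blink_intervals=blink_intervals,
        sync_lag=spec.sync_lag,
        gaze_eyes_frac=spec.gaze_eyes_frac,
        gaze_mouth_frac=spec.gaze_mouth_frac,
        group="G2" if spec.eda_profile == "flat" else "G1",
        eda_profile=spec.eda_profile,
    )
    return bundle, gt


def gen_cohort(n_participants: int = 43, fraction_flat: float = 21 / 43,
               seed: int = 0, **spec_overrides
               ) -> list[tuple[SessionBundle, GroundTruth]]:
    """A cohort of sessions with a planted self-regulated (flat EDA)
    subgroup; ``fraction_flat`` of the participants are generated flat
    and labelled G2, the rest reactive and labelled G1."""
    if not 0 <= fraction_flat <= 1:
        raise ValueError("fraction_flat must be in [0, 1]")
    n_flat = round(fraction_flat * n_participants)
    rng = np.random.default_rng(seed)
    profiles = ["flat"] * n_flat + ["reactive"] * (n_participants - n_flat)
    out = []
    for i, profile in enumerate(profiles):
        spec = SessionSpec(seed=int(rng.integers(0, 2 ** 31 - 1)),
                           eda_profile=profile, participant_index=i,
                           **spec_overrides)
        out.append(gen_session(spec))
    return out


def gen_feature_cohort(n_per_class: int = 50, n_features: int = 14,
                       class_sep: float = 0.15, group_shift: float = 0.0,
                       seed: int = 0):
    """Synthetic per-epoch feature tables for the two groups, drawn from
    the same class-conditional log-normal band-power distributions
    (``group_shift = 0`` makes the group null exactly true).

    Returns ``{"G1": FeatureTable, "G2": FeatureTable}``.
    """
    from .evaluation import FeatureTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    classes = ("pleasant", "unpleasant", "neutral")
    mus = {c: rng.normal(0, class_sep, n_features) for c in classes}

    def one_group(name: str, shift: float) -> "FeatureTable":
        rows, labels = [], []
        for c in classes:
            z = rng.standard_normal((n_per_class, n_features))
            rows.append(np.exp(mus[c][None, :] + shift + z))
            labels += [c] * n_per_class
        X = pd.DataFrame(np.vstack(rows),
                         columns=[f"pow_{i}" for i in range(n_features)])
        return FeatureTable(X=X, y=pd.Series(labels), group=name)

    return {"G1": one_group("G1", 0.0), "G2": one_group("G2", group_shift)}


def write_session(bundle: SessionBundle, gt: GroundTruth,
                  path: str | Path) -> None:
    """Write all stream formats plus ground_truth.json and aoi.yaml."""
    from .io import write_aois, write_session_dir

    path = Path(path)
    write_session_dir(bundle, path)
    gt.to_json(path / "ground_truth.json")
    aois = {s.id: VIDEO_AOIS for s in bundle.stimuli if s.kind == "video"}
    write_aois(aois, path / "aoi.yaml")
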