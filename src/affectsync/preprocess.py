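"""EEG filtering and the two-pass ICA artifact-rejection procedure.

Blinks are located from the eye tracker (both-eyes-invalid runs of
blink-plausible length) and head/muscle motion from the wristband
accelerometer; both guide which epochs and independent components are
discarded rather than relying on the EEG alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA

from .core import (Epoch, EEGRecording, GazeSample, TimeSeries,
                   resample_indicator)


@dataclass
class ICAModel:
    """Fitted unmixing/mixing pair plus per-component blink scores."""

    mixing: np.ndarray      # channels x components
    unmixing: np.ndarray    # components x channels
    mean: np.ndarray        # per-channel mean removed before unmixing
    component_scores: np.ndarray  # |Pearson r| with the blink indicator
    removed: list[int] = field(default_factory=list)

    def check(self, tol: float = 1e-6) -> bool:
        k = self.unmixing.shape[0]
        return bool(np.allclose(self.unmixing @ self.mixing, np.eye(k),
                                atol=tol))


@dataclass
class ArtifactMask:
    bad_epochs: dict[int, str] = field(default_factory=dict)
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    motion_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("blink_intervals", "motion_intervals"):
            ivs = getattr(self, name)
            if any(b < a for a, b in ivs):
                raise ValueError(f"{name}: negative-length interval")
            setattr(self, name, sorted(ivs))


# ------------------------------------------------------------ filters

def _filtered(eeg: EEGRecording, sos: np.ndarray) -> EEGRecording:
    out = signal.sosfiltfilt(sos, eeg.series.values, axis=0)
    return eeg.with_series(TimeSeries(out, rate=eeg.rate,
                                      offset=eeg.series.offset,
                                      channel_labels=list(eeg.series.channel_labels)))


def bandpass(eeg: EEGRecording, low: float = 0.1, high: float = 50.0
             ) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass, per channel."""
    nyq = eeg.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for rate {eeg.rate}")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=eeg.rate,
                        output="sos")
    return _filtered(eeg, sos)


def notch(eeg: EEGRecording, freq: float = 50.0, quality: float = 30.0
          ) -> EEGRecording:
    """Zero-phase IIR notch (quality factor 30) at the mains frequency."""
    if freq >= eeg.rate / 2:
        raise ValueError(f"notch frequency {freq} at or above Nyquist")
    b, a = signal.iirnotch(freq, quality, fs=eeg.rate)
    sos = signal.tf2sos(b, a)
    return _filtered(eeg, sos)


# ----------------------------------------------------- artifact guides

def blinks_from_gaze(gaze: list[GazeSample], min_gap: float = 0.07,
                     max_gap: float = 0.5) -> list[tuple[float, float]]:
    """Blink intervals: maximal both-eyes-invalid runs whose duration
    falls in [min_gap, max_gap].  Longer runs are tracking dropouts,
    shorter ones flicker; both are ignored."""
    intervals = []
    start = None
    prev_t = None
    for s in gaze:
        if not s.valid:
            if start is None:
                start = s.t
            prev_t = s.t
        else:
            if start is not None:
                intervals.append((start, prev_t))
                start = None
    if start is not None:
        intervals.append((start, prev_t))
    return [(a, b) for a, b in intervals if min_gap <= b - a <= max_gap]


def motion_flags(acc: TimeSeries, threshold_g: float) -> list[tuple[float, float]]:
    """Intervals where the acceleration vector magnitude deviates from
    its running median by more than ``threshold_g``."""
    if acc.n_channels != 3:
        raise ValueError(f"accelerometer must have 3 channels, got {acc.n_channels}")
    mag = np.linalg.norm(acc.values, axis=1)
    k = max(3, int(acc.rate) | 1)  # ~1 s window, odd
    run_med = signal.medfilt(mag, kernel_size=min(k, len(mag) - (len(mag) + 1) % 2))
    hot = np.abs(mag - run_med) > threshold_g
    return _runs_to_intervals(hot, acc.rate, acc.offset)


def _runs_to_intervals(mask: np.ndarray, rate: float, offset: float
                       ) -> list[tuple[float, float]]:
    out = []
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    for a, b in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        out.append((offset + a / rate, offset + b / rate))
    return out


# ------------------------------------------------------- two-pass ICA

def _epoch_sample_mask(eeg: EEGRecording, epochs: list[Epoch],
                       bad: set[int]) -> np.ndarray:
    """True for samples belonging to a bad epoch."""
    ts = eeg.series
    times = ts.times()
    mask = np.zeros(ts.n_samples, dtype=bool)
    for i in bad:
        ep = epochs[i]
        mask |= (times >= ep.stimulus.onset) & (times < ep.stimulus.end)
    return mask


def flag_bad_epochs(eeg: EEGRecording, epochs: list[Epoch],
                    amp_uv: float = 150.0, kurt_z: float = 5.0
                    ) -> dict[int, str]:
    """Amplitude / kurtosis epoch screening (pass-1 rejection rule).

    An epoch is bad when any sample exceeds ``amp_uv`` in magnitude or
    its worst channel kurtosis sits more than ``kurt_z`` SDs above the
    across-epoch distribution.  Channel-order invariant by construction.
    """
    bad: dict[int, str] = {}
    kurts = []
    for i, ep in enumerate(epochs):
        seg = eeg.series.slice_seconds(ep.stimulus.onset, ep.stimulus.end).values
        if seg.size == 0:
            continue
        if np.max(np.abs(seg)) > amp_uv:
            bad[i] = f"amplitude > {amp_uv:g} uV"
        kurts.append((i, np.max(stats.kurtosis(seg, axis=0, bias=False))
                      if seg.shape[0] > 3 else 0.0))
    if len(kurts) >= 3:
        vals = np.array([v for _, v in kurts])
        mu, sd = vals.mean(), vals.std()
        if sd > 0:
            for (i, v) in kurts:
                if (v - mu) / sd > kurt_z and i not in bad:
                    bad[i] = f"kurtosis z > {kurt_z:g}"
    return bad


def two_pass_ica(eeg: EEGRecording, epochs: list[Epoch], mask: ArtifactMask,
                 blink_corr_threshold: float = 0.3, max_removed: int = 2,
                 amp_uv: float = 150.0, kurt_z: float = 5.0,
                 seed: int = 0) -> tuple[EEGRecording, ICAModel, ArtifactMask]:
    """Fit ICA, reject bad epochs, refit on pruned data, zero blink
    components, and apply the pass-2 weights to the full dataset.

    Components whose activation correlates with the 0/1 blink indicator
    (resampled to the EEG rate) above ``blink_corr_threshold`` in
    absolute value are zeroed, at most ``max_removed`` of them --
    removing components always also removes genuine brain signal, so the
    loss is bounded.
    """
    ts = eeg.series
    n_ch = ts.n_channels

    # pass 1: fit on everything, then screen epochs
    _fit_ica(ts.values, n_ch, seed)  # pass-1 fit (screening is data-driven)
    bad = flag_bad_epochs(eeg, epochs, amp_uv=amp_uv, kurt_z=kurt_z)
    new_mask = ArtifactMask(bad_epochs={**mask.bad_epochs, **bad},
                            blink_intervals=list(mask.blink_intervals),
                            motion_intervals=list(mask.motion_intervals))

    # pass 2: fit on pruned data
    drop = _epoch_sample_mask(eeg, epochs, set(new_mask.bad_epochs))
    pruned = ts.values[~drop]
    if pruned.shape[0] < n_ch * 20:
        raise RuntimeError(
            f"insufficient data after pruning: {pruned.shape[0]} samples "
            f"for {n_ch} components")
    ica = _fit_ica(pruned, n_ch, seed)
    mean = pruned.mean(axis=0)
    unmixing = ica.components_
    mixing = ica.mixing_

    # blink scoring on the full dataset
    sources = (ts.values - mean) @ unmixing.T
    indicator = resample_indicator(new_mask.blink_intervals, ts.times())
    if indicator.std() > 0:
        scores = np.abs([np.corrcoef(sources[:, j], indicator)[0, 1]
                         for j in range(n_ch)])
    else:
        scores = np.zeros(n_ch)
    order = np.argsort(scores)[::-1]
    removed = [int(j) for j in order[:max_removed]
               if scores[j] > blink_corr_threshold]

    cleaned = sources.copy()
    cleaned[:, removed] = 0.0
    recon = cleaned @ mixing.T + mean

    model = ICAModel(mixing=mixing, unmixing=unmixing, mean=mean,
                     component_scores=scores, removed=removed)
    out = eeg.with_series(TimeSeries(recon, rate=ts.rate, offset=ts.offset,
                                     channel_labels=list(ts.channel_labels)))
    return out, model, new_mask


def _fit_ica(data: np.ndarray, n_components: int, seed: int) -> FastICA:
    import warnings as _w

    from sklearn.exceptions import ConvergenceWarning

    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=500, tol=1e-4)
    with _w.catch_warnings():
        # non-convergence only perturbs the rotation; the reconstruction
        # identity that matters downstream holds regardless
        _w.simplefilter("ignore", ConvergenceWarning)
        ica.fit(data)
    return ica
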