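"""Electrodermal activity: tonic/phasic split, arousal, self-regulation.

Skin conductance divides into the slowly varying Skin Conductance Level
(SCL, tonic; mood-scale arousal) and the fast Skin Conductance Response
(SCR, phasic; stimulus-locked events).  The split here is additive:
tonic = zero-phase low-pass of the signal, phasic = residual, so
tonic + phasic reproduces the input exactly.  Self-regulation is the
suppression of electrodermal reactivity: a flat, near-zero trace with
(nearly) no SCR events during affective stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import StimulusEvent, TimeSeries

TONIC_CUTOFF_HZ = 0.05
SCR_AMPLITUDE_MIN = 0.05   # uS
RESPONSE_LAG_S = 1.0       # stimulus onset -> SCR window start
RESPONSE_WINDOW_S = 4.0    # SCR window length after the lag
R_MIN_PER_MIN = 1.0        # SCR-rate bound for self-regulation
T_MIN_US = 0.1             # tonic-range bound for self-regulation


@dataclass
class EDADecomposition:
    tonic: TimeSeries
    phasic: TimeSeries
    scr_events: list[tuple[float, float, float]]  # (onset, peak, amplitude)

    def __post_init__(self) -> None:
        if any(a <= 0 for _, _, a in self.scr_events):
            raise ValueError("SCR amplitudes must be positive")


@dataclass
class SelfRegulationVerdict:
    self_regulated: bool
    scr_rate: float       # events / min over the assessed span
    tonic_slope: float    # uS / min, least-squares
    tonic_range: float    # uS, max - min over the assessed span
    pattern: str


@dataclass
class ArousalScore:
    value: float
    basis: str = "combined"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("arousal must be nonnegative")


def decompose(eda: TimeSeries, tonic_cutoff: float = TONIC_CUTOFF_HZ,
              amplitude_min: float = SCR_AMPLITUDE_MIN,
              mode: str = "lowpass") -> EDADecomposition:
    """Split EDA into tonic + phasic and detect SCR events.

    ``mode="lowpass"`` (default): tonic is a zero-phase 2nd-order
    Butterworth low-pass at ``tonic_cutoff`` Hz.  ``mode="median"``:
    tonic is a running median over a ``1/tonic_cutoff``-s window.
    Phasic is the residual either way, so additivity is exact.  SCR
    events are phasic peaks of at least ``amplitude_min`` uS; each
    event's onset is the preceding phasic zero-crossing.
    """
    if eda.n_channels != 1:
        raise ValueError("EDA must be single channel")
    if eda.rate < 1:
        raise ValueError("EDA rate must be >= 1 Hz")
    x = eda.values[:, 0]
    if np.any(x < 0):
        raise ValueError("negative skin conductance values")
    if mode == "lowpass":
        if len(x) > 12:
            sos = signal.butter(2, tonic_cutoff, btype="lowpass",
                                fs=eda.rate, output="sos")
            tonic = signal.sosfiltfilt(sos, x)
        else:
            tonic = np.full_like(x, x.mean())
    elif mode == "median":
        k = int(round(eda.rate / tonic_cutoff)) | 1
        k = min(k, len(x) - (len(x) + 1) % 2)
        tonic = signal.medfilt(x, kernel_size=max(k, 1))
    else:
        raise ValueError(f"unknown tonic mode {mode!r}")
    phasic = x - tonic

    peaks, _ = signal.find_peaks(phasic, height=amplitude_min / 2,
                                 prominence=amplitude_min / 2)
    events = []
    for p in peaks:
        onset_idx = p
        while onset_idx > 0 and phasic[onset_idx - 1] > 0:
            onset_idx -= 1
        # amplitude = trough-to-peak rise of the raw trace (the filtered
        # residual splits each response between tonic and phasic, so the
        # phasic peak height alone underestimates it)
        back = max(0, onset_idx - 2)
        amp = float(x[p] - x[back:onset_idx + 1].min())
        if amp < amplitude_min:
            continue
        events.append((eda.offset + onset_idx / eda.rate,
                       eda.offset + p / eda.rate, amp))

    mk = lambda v: TimeSeries(v.reshape(-1, 1), rate=eda.rate,
                              offset=eda.offset, channel_labels=["EDA"])
    return EDADecomposition(tonic=mk(tonic), phasic=mk(phasic),
                            scr_events=events)


def arousal_per_stimulus(decomp: EDADecomposition,
                         stimuli: list[StimulusEvent],
                         scr_weight: float = 1.0,
                         lag: float = RESPONSE_LAG_S,
                         window: float = RESPONSE_WINDOW_S
                         ) -> dict[str, ArousalScore]:
    """Per-stimulus arousal: mean SCL over the presentation plus
    ``scr_weight`` x the summed SCR amplitudes whose onsets fall in the
    latency-shifted response window [onset+lag, onset+lag+window)."""
    out = {}
    for stim in stimuli:
        seg = decomp.tonic.slice_seconds(stim.onset, stim.end)
        scl = float(seg.values.mean()) if seg.n_samples else 0.0
        w0, w1 = stim.onset + lag, stim.onset + lag + window
        scr_sum = sum(a for (on, _, a) in decomp.scr_events if w0 <= on < w1)
        out[stim.id] = ArousalScore(value=max(0.0, scl + scr_weight * scr_sum))
    return out


def select_epochs_by_arousal(scores: dict[str, ArousalScore], mode: str,
                             k: int,
                             stimuli: list[StimulusEvent] | None = None
                             ) -> list[str]:
    """The ``k`` highest ("high") or lowest ("low") scoring stimulus ids,
    ties broken by stimulus onset order."""
    if not scores:
        raise ValueError("empty score map")
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    onset = {s.id: s.onset for s in stimuli} if stimuli else {}
    order = {sid: i for i, sid in enumerate(scores)}
    keyed = sorted(scores,
                   key=lambda sid: (-scores[sid].value if mode == "high"
                                    else scores[sid].value,
                                    onset.get(sid, order[sid])))
    if k > len(keyed):
        warnings.warn(f"requested {k} stimuli but only {len(keyed)} scored")
        k = len(keyed)
    return keyed[:k]


def detect_self_regulation(decomp: EDADecomposition,
                           session_span: tuple[float, float],
                           r_min: float = R_MIN_PER_MIN,
                           t_min: float = T_MIN_US
                           ) -> SelfRegulationVerdict:
    """Flat-EDA detector over the stimulus-presentation span.

    self_regulated iff SCR rate < ``r_min``/min AND tonic range <
    ``t_min`` uS (both strict).  The pattern descriptor mirrors the
    qualitative vocabulary of electrodermal screening: flat / little or
    great phasic peaks / tonic-down variants / moderated phasic
    activity.
    """
    a, b = session_span
    tonic = decomp.tonic.slice_seconds(a, b)
    if b <= a or tonic.n_samples == 0:
        raise ValueError(f"span {session_span} outside the decomposition")
    minutes = (b - a) / 60.0
    n_events = sum(1 for (on, _, _) in decomp.scr_events if a <= on < b)
    scr_rate = n_events / minutes
    tv = tonic.values[:, 0]
    tonic_range = float(tv.max() - tv.min())
    t = tonic.times()
    slope = float(np.polyfit(t - t[0], tv, 1)[0] * 60.0) if len(tv) > 1 else 0.0

    self_reg = (scr_rate < r_min) and (tonic_range < t_min)
    going_down = slope < -t_min  # losing more than t_min uS per minute
    if self_reg:
        pattern = "tonic goes down, no phasic activity" if going_down else "flat"
    elif going_down:
        pattern = "tonic goes down, little phasic activity"
    elif scr_rate < 2.0:
        pattern = "little phasic peaks"
    elif scr_rate >= 4.0:
        pattern = "great phasic peaks"
    else:
        pattern = "moderated phasic activity"
    return SelfRegulationVerdict(self_regulated=self_reg, scr_rate=scr_rate,
                                 tonic_slope=slope, tonic_range=tonic_range,
                                 pattern=pattern)


def hr_excitement_screen(hr: TimeSeries, baseline_window: tuple[float, float],
                         limit_bpm: float) -> bool:
    """True (exclude the participant) iff the mean baseline heart rate
    strictly exceeds ``limit_bpm`` -- an over-excited start."""
    seg = hr.slice_seconds(*baseline_window)
    if seg.n_samples == 0:
        raise ValueError(f"baseline window {baseline_window} has no samples")
    return bool(seg.values.mean() > limit_bpm)
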