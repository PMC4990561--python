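"""Alpha-band power and frontal asymmetry -> per-epoch valence.

Negative emotional valence shows as *more* alpha (here 7-10 Hz) power
over the right hemisphere than the left.  Valence is scored as the mean
log-power difference ln(P_left) - ln(P_right) over frontal electrode
pairs, so right-alpha dominance gives a negative value and the label
"unpleasant".  Note this sign convention follows the source method's
observation (right alpha ~ unpleasant); part of the asymmetry literature
models alpha as inverse activation and reads the direction the other way
-- see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Epoch, SessionBundle

#: Default frontal pairs (left, right); configurable.
FRONTAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "F4"), ("AF3", "AF4"), ("F7", "F8"), ("FC5", "FC6"),
)

ALPHA_BAND = (7.0, 10.0)
NEUTRAL_THRESHOLD = 0.1


@dataclass
class BandPower:
    """Per-channel power integrated over a frequency band (uV^2)."""

    power: dict[str, float]
    band: tuple[float, float]
    epoch: Epoch | None = None

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.power.values()):
            raise ValueError("band powers must be nonnegative")


@dataclass
class ValenceScore:
    value: float
    left_power: float
    right_power: float
    label: str


def band_power(epoch: Epoch, band: tuple[float, float] = ALPHA_BAND,
               window_s: float = 1.0) -> BandPower:
    """Welch PSD (Hann taper, ``window_s`` windows, 50% overlap)
    integrated over ``band``, per channel."""
    ts = epoch.data
    nper = int(round(window_s * ts.rate))
    if ts.n_samples < nper:
        raise ValueError(
            f"epoch has {ts.n_samples} samples; needs at least one "
            f"{window_s:g}-s window ({nper})")
    lo, hi = band
    if not 0 < lo < hi < ts.rate / 2:
        raise ValueError(f"band {band} outside (0, {ts.rate / 2})")
    freqs, psd = signal.welch(ts.values, fs=ts.rate, axis=0,
                              nperseg=nper, noverlap=nper // 2,
                              window="hann")
    sel = (freqs >= lo) & (freqs <= hi)
    powers = np.trapezoid(psd[sel], freqs[sel], axis=0)
    return BandPower(power=dict(zip(ts.channel_labels, powers)),
                     band=band, epoch=epoch)


def asymmetry_valence(bp: BandPower,
                      pairs: tuple[tuple[str, str], ...] = FRONTAL_PAIRS,
                      neutral_threshold: float = NEUTRAL_THRESHOLD
                      ) -> ValenceScore:
    """Mean ln(P_left) - ln(P_right) over electrode pairs.

    value < -threshold -> unpleasant (right-alpha dominance),
    value > +threshold -> pleasant, else neutral.
    """
    diffs, lp, rp = [], [], []
    for left, right in pairs:
        for ch in (left, right):
            if ch not in bp.power:
                raise KeyError(f"channel {ch} missing from band powers")
            if bp.power[ch] <= 0:
                raise ValueError(f"zero power in channel {ch}: log undefined")
        diffs.append(np.log(bp.power[left]) - np.log(bp.power[right]))
        lp.append(bp.power[left])
        rp.append(bp.power[right])
    value = float(np.mean(diffs))
    if abs(value) <= neutral_threshold:
        label = "neutral"
    elif value < 0:
        label = "unpleasant"
    else:
        label = "pleasant"
    return ValenceScore(value=value, left_power=float(np.mean(lp)),
                        right_power=float(np.mean(rp)), label=label)


def valence_per_stimulus(epochs: list[Epoch],
                         band: tuple[float, float] = ALPHA_BAND,
                         pairs: tuple[tuple[str, str], ...] = FRONTAL_PAIRS,
                         neutral_threshold: float = NEUTRAL_THRESHOLD
                         ) -> dict[str, ValenceScore]:
    """Valence for every non-rejected EEG epoch, keyed by stimulus id."""
    out = {}
    for ep in epochs:
        if ep.rejected:
            continue
        out[ep.stimulus.id] = asymmetry_valence(
            band_power(ep, band=band), pairs=pairs,
            neutral_threshold=neutral_threshold)
    if not out:
        raise ValueError("all epochs rejected; no valence computable")
    return out
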