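"""Core data carriers shared by every stage of the pipeline.

All modalities ride on :class:`TimeSeries`: a uniformly sampled value
matrix with a sampling rate and an *offset* placing sample 0 on the
session clock (the eye tracker's clock, which is the one stream that is
natively timestamped).  Session time of sample ``i`` is
``offset + i / rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: The 14-channel montage of the consumer EEG headset, in export order.
#: CMS/DRL references sit at P3/P4 and are not data channels.
EEG_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Left/right hemisphere split of the montage (midline-free headset).
LEFT_CHANNELS: tuple[str, ...] = ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1")
RIGHT_CHANNELS: tuple[str, ...] = ("AF4", "F8", "F4", "FC6", "T8", "P8", "O2")

STIMULUS_CATEGORIES = ("pleasant", "unpleasant", "neutral")


class FormatError(ValueError):
    """A file or structure violates the documented dialect."""


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel data on the session clock.

    Parameters
    ----------
    values : (n_samples, n_channels) float array
    rate : sampling rate in samples per second, > 0
    offset : session-clock time of sample 0, seconds
    channel_labels : unique per-channel names
    """

    values: np.ndarray
    rate: float
    offset: float = 0.0
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be a samples x channels matrix")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not math.isfinite(self.offset):
            raise ValueError("offset must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.values.shape[1])]
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.values.shape[1]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def end(self) -> float:
        """Session-clock time just past the last sample."""
        return self.offset + self.duration

    def times(self) -> np.ndarray:
        """Session-clock time of every sample."""
        return self.offset + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.values[:, idx]

    def shifted(self, offset: float) -> "TimeSeries":
        """Copy with a new session-clock offset (values shared)."""
        return replace(self, values=self.values, offset=offset)

    def slice_seconds(self, start: float, stop: float) -> "TimeSeries":
        """Samples with session time in the half-open window [start, stop)."""
        i0 = max(0, math.ceil((start - self.offset) * self.rate - 1e-9))
        i1 = min(self.n_samples, math.ceil((stop - self.offset) * self.rate - 1e-9))
        i1 = max(i0, i1)
        return TimeSeries(
            self.values[i0:i1].copy(),
            rate=self.rate,
            offset=self.offset + i0 / self.rate,
            channel_labels=list(self.channel_labels),
        )


@dataclass
class EEGRecording:
    """A 14-channel headset recording. Validates the fixed montage."""

    series: TimeSeries
    references: str = "CMS/DRL at P3/P4"

    def __post_init__(self) -> None:
        labels = list(self.series.channel_labels)
        if set(labels) != set(EEG_CHANNELS):
            missing = sorted(set(EEG_CHANNELS) - set(labels))
            extra = sorted(set(labels) - set(EEG_CHANNELS))
            raise FormatError(
                f"EEG channel set mismatch: missing {missing}, unexpected {extra}"
            )
        if self.series.rate not in (128, 256):
            raise FormatError(
                f"EEG rate must be 128 or 256 samples/s, got {self.series.rate}"
            )

    @property
    def rate(self) -> float:
        return self.series.rate

    def with_series(self, series: TimeSeries) -> "EEGRecording":
        return EEGRecording(series=series, references=self.references)


@dataclass
class GazeSample:
    """One binocular gaze sample. Coordinates in screen pixels, origin
    top-left, y down. ``valid_*`` follow the tracker's validity codes
    (code <= 1 counts as valid)."""

    t: float
    x: float
    y: float
    valid_left: bool = True
    valid_right: bool = True
    pupil_left: float | None = None
    pupil_right: float | None = None

    @property
    def valid(self) -> bool:
        return self.valid_left and self.valid_right


@dataclass
class StimulusEvent:
    """One affective stimulus presentation with optional normative ratings
    (1-9 valence/arousal scale of the standardized picture set)."""

    id: str
    category: str
    kind: str  # "image" | "video"
    onset: float
    duration: float
    iaps_valence: float | None = None
    iaps_arousal: float | None = None

    def __post_init__(self) -> None:
        if self.category not in STIMULUS_CATEGORIES:
            raise ValueError(
                f"category must be one of {STIMULUS_CATEGORIES}, got {self.category!r}"
            )
        if self.kind not in ("image", "video"):
            raise ValueError(f"kind must be image or video, got {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SessionBundle:
    """One participant's session: EEG + peripherals + gaze + audio +
    stimulus log, all expressed (after alignment) on one session clock."""

    eeg: EEGRecording
    peripherals: dict[str, TimeSeries]
    gaze: list[GazeSample]
    audio: TimeSeries
    stimuli: list[StimulusEvent]
    participant_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.audio.n_channels != 1:
            raise ValueError("audio must be single channel")

    def stimulus_span(self) -> tuple[float, float]:
        """Session-clock interval covering all stimulus presentations."""
        if not self.stimuli:
            raise ValueError("bundle has no stimuli")
        return (min(s.onset for s in self.stimuli),
                max(s.end for s in self.stimuli))


@dataclass
class Epoch:
    """A stimulus-locked slice over [onset, onset + duration)."""

    stimulus: StimulusEvent
    data: TimeSeries
    rejected: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.rejected and not self.reason:
            raise ValueError("rejected epochs must carry a reason")


def reject(epoch: Epoch, reason: str) -> Epoch:
    return Epoch(stimulus=epoch.stimulus, data=epoch.data,
                 rejected=True, reason=reason)


def resample_indicator(intervals: Sequence[tuple[float, float]],
                       times: np.ndarray) -> np.ndarray:
    """0/1 indicator of interval membership evaluated at ``times``."""
    out = np.zeros(len(times))
    for a, b in intervals:
        out[(times >= a) & (times < b)] = 1.0
    return out
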