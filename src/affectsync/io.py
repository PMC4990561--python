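"""Readers and writers for the session's plain-text stream formats.

Formats
-------
EEG          CSV, header row = the 14 channel labels, one sample per row;
             sampling rate and offset in two comment lines (``# rate=``,
             ``# offset=``).  EDF is read through :mod:`mne`.
Peripherals  per-signal CSV dialect: row 1 = start timestamp (seconds on
             the session clock), row 2 = sampling rate, rows 3+ = samples
             (ACC has three columns).  The header-row count is
             configurable because real wristband exports vary.
Gaze         TSV with columns ``t  x  y  validity_left  validity_right``
             and optional ``pupil_left  pupil_right``; validity codes
             follow the tracker convention (<= 1 valid, 4 fully invalid).
Stimulus log CSV with columns
             ``id,category,kind,onset,duration,iaps_valence,iaps_arousal``.
AOIs         YAML: stimulus id -> list of {label, x0, y0, x1, y1}.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (EEG_CHANNELS, EEGRecording, FormatError, GazeSample,
                   SessionBundle, StimulusEvent, TimeSeries)

#: Expected sampling rate per wristband signal in the synthetic dialect.
EMPATICA_RATES = {"EDA": 4.0, "BVP": 64.0, "ACC": 32.0, "HR": 1.0, "TEMP": 4.0}
MANDATORY_PERIPHERALS = ("EDA",)


# ---------------------------------------------------------------- EEG

def read_eeg(path: str | Path, format: str = "csv") -> EEGRecording:
    """Read an EEG recording from CSV or EDF.

    The channel set must be exactly the 14-channel headset montage;
    missing or extra channels raise :class:`FormatError` naming them.
    """
    path = Path(path)
    if format == "csv":
        return _read_eeg_csv(path)
    if format == "edf":
        return _read_eeg_edf(path)
    raise ValueError(f"unknown EEG format {format!r} (use 'csv' or 'edf')")


def _read_eeg_csv(path: Path) -> EEGRecording:
    rate, offset = 128.0, 0.0
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key.strip() == "rate":
                    rate = float(val)
                elif key.strip() == "offset":
                    offset = float(val)
                continue
            cells = line.split(",")
            if header is None:
                header = [c.strip() for c in cells]
            else:
                rows.append([float(c) for c in cells])
    if header is None:
        raise FormatError(f"{path}: no header row")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(header)))
    series = TimeSeries(values, rate=rate, offset=offset, channel_labels=header)
    return EEGRecording(series=series)


def _read_eeg_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [ch for ch in raw.ch_names if ch in EEG_CHANNELS]
    data = raw.get_data(picks=picks).T * 1e6  # volts -> microvolts
    series = TimeSeries(data, rate=float(raw.info["sfreq"]),
                        channel_labels=picks)
    return EEGRecording(series=series)


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the CSV dialect (values to 6 decimals)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# rate={rec.series.rate:g}\n")
        fh.write(f"# offset={rec.series.offset!r}\n")
        fh.write(",".join(rec.series.channel_labels) + "\n")
        np.savetxt(fh, rec.series.values, fmt="%.6f", delimiter=",")


# --------------------------------------------------------- peripherals

def read_empatica_dir(path: str | Path, header_rows: int = 2
                      ) -> dict[str, TimeSeries]:
    """Read the per-signal wristband CSVs from a directory.

    Each ``<SIGNAL>.csv`` carries its start timestamp (row 1) and rate
    (row 2); EDA is mandatory because arousal and self-regulation hang
    off it.
    """
    path = Path(path)
    out: dict[str, TimeSeries] = {}
    for f in sorted(path.glob("*.csv")):
        name = f.stem.upper()
        if name not in EMPATICA_RATES:
            continue
        out[name] = _read_empatica_csv(f, header_rows)
    for sig in MANDATORY_PERIPHERALS:
        if sig not in out:
            raise FormatError(
                f"{path}: mandatory signal {sig} missing "
                f"(expected {sig}.csv; found {sorted(out)})")
    return out


def _read_empatica_csv(path: Path, header_rows: int) -> TimeSeries:
    with open(path, newline="") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < header_rows:
        raise FormatError(f"{path}: fewer lines than the {header_rows} "
                          "header rows of the dialect")
    try:
        start = float(lines[0].split(",")[0])
        rate = float(lines[1].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header rows: {exc}") from None
    if rate <= 0:
        raise FormatError(f"{path}: nonpositive rate {rate}")
    data = [[float(c) for c in ln.split(",")] for ln in lines[header_rows:]]
    values = np.array(data) if data else np.empty((0, 1))
    n_ch = values.shape[1] if values.size else 1
    labels = [path.stem.upper()] if n_ch == 1 else [
        f"{path.stem.upper()}_{ax}" for ax in "xyz"[:n_ch]]
    return TimeSeries(values, rate=rate, offset=start, channel_labels=labels)


def write_empatica_dir(peripherals: dict[str, TimeSeries],
                       path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ts in peripherals.items():
        with open(path / f"{name}.csv", "w", newline="") as fh:
            fh.write(f"{ts.offset!r}\n{ts.rate:g}\n")
            np.savetxt(fh, ts.values, fmt="%.6f", delimiter=",")


# --------------------------------------------------------------- gaze

GAZE_COLUMNS = ["t", "x", "y", "validity_left", "validity_right",
                "pupil_left", "pupil_right"]


def read_gaze_tsv(path: str | Path) -> list[GazeSample]:
    """Read a tracker TSV export. Invalid samples are kept but flagged;
    non-monotone timestamps are a hard error."""
    df = pd.read_csv(path, sep="\t")
    missing = {"t", "x", "y", "validity_left", "validity_right"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gaze TSV missing columns {sorted(missing)}")
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) < 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone timestamps, first offending row {bad[0] + 3}")
    samples = []
    for row in df.itertuples(index=False):
        pl = getattr(row, "pupil_left", None)
        pr = getattr(row, "pupil_right", None)
        samples.append(GazeSample(
            t=float(row.t), x=float(row.x), y=float(row.y),
            valid_left=int(row.validity_left) <= 1,
            valid_right=int(row.validity_right) <= 1,
            pupil_left=None if pl is None or pd.isna(pl) else float(pl),
            pupil_right=None if pr is None or pd.isna(pr) else float(pr),
        ))
    return samples


def write_gaze_tsv(samples: list[GazeSample], path: str | Path) -> None:
    rows = [{
        "t": s.t, "x": s.x, "y": s.y,
        "validity_left": 0 if s.valid_left else 4,
        "validity_right": 0 if s.valid_right else 4,
        "pupil_left": "" if s.pupil_left is None else s.pupil_left,
        "pupil_right": "" if s.pupil_right is None else s.pupil_right,
    } for s in samples]
    pd.DataFrame(rows, columns=GAZE_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- stimulus log

def read_stimulus_log(path: str | Path) -> list[StimulusEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(StimulusEvent(
                id=row["id"], category=row["category"], kind=row["kind"],
                onset=float(row["onset"]), duration=float(row["duration"]),
                iaps_valence=float(row["iaps_valence"]) if row.get("iaps_valence") else None,
                iaps_arousal=float(row["iaps_arousal"]) if row.get("iaps_arousal") else None,
            ))
    return events


def write_stimulus_log(events: list[StimulusEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "category", "kind", "onset", "duration",
                    "iaps_valence", "iaps_arousal"])
        for e in events:
            w.writerow([e.id, e.category, e.kind, repr(e.onset), repr(e.duration),
                        "" if e.iaps_valence is None else e.iaps_valence,
                        "" if e.iaps_arousal is None else e.iaps_arousal])


# ---------------------------------------------------------------- AOIs

def read_aois(path: str | Path) -> dict[str, list[dict]]:
    """Load AOI rectangles: stimulus id -> [{label, x0, y0, x1, y1}, ...]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for stim_id, rects in raw.items():
        for r in rects:
            if not (r["x0"] < r["x1"] and r["y0"] < r["y1"]):
                raise FormatError(
                    f"AOI {r.get('label')} of {stim_id}: degenerate rectangle")
    return raw


def write_aois(aois: dict[str, list[dict]], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(aois, fh)


# --------------------------------------------------------- audio + dir

def read_audio_csv(path: str | Path) -> TimeSeries:
    """Mono audio stored in the same two-header-row CSV dialect."""
    ts = _read_empatica_csv(Path(path), header_rows=2)
    if ts.n_channels != 1:
        raise FormatError(f"{path}: audio must be mono")
    return TimeSeries(ts.values, rate=ts.rate, offset=ts.offset,
                      channel_labels=["audio"])


def write_audio_csv(audio: TimeSeries, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"{audio.offset!r}\n{audio.rate:g}\n")
        np.savetxt(fh, audio.values, fmt="%.6f", delimiter=",")


def write_session_dir(bundle: SessionBundle, path: str | Path,
                      meta_extra: dict | None = None) -> None:
    """Write a full session to a directory in the text formats above."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_eeg(bundle.eeg, path / "eeg.csv")
    write_empatica_dir(bundle.peripherals, path / "empatica")
    write_gaze_tsv(bundle.gaze, path / "gaze.tsv")
    write_audio_csv(bundle.audio, path / "audio.csv")
    write_stimulus_log(bundle.stimuli, path / "stimuli.csv")
    meta = dict(bundle.participant_meta)
    if meta_extra:
        meta.update(meta_extra)
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_session_dir(path: str | Path) -> SessionBundle:
    """Load a session directory written by :func:`write_session_dir`."""
    path = Path(path)
    meta = {}
    if (path / "meta.json").exists():
        with open(path / "meta.json") as fh:
            meta = json.load(fh)
    return SessionBundle(
        eeg=read_eeg(path / "eeg.csv"),
        peripherals=read_empatica_dir(path / "empatica"),
        gaze=read_gaze_tsv(path / "gaze.tsv"),
        audio=read_audio_csv(path / "audio.csv"),
        stimuli=read_stimulus_log(path / "stimuli.csv"),
        participant_meta=meta,
    )
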