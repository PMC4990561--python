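"""AOI dwell-time analysis over face stimuli and the empathy rule table.

Dwell is the share of *valid* gaze samples falling inside the eyes /
mouth rectangles while a scored stimulus (by default the face videos)
is on screen.  Gaze time on the eye region correlates positively with
affective empathy; together with the electrodermal self-regulation
verdict it yields the empathic / low-empathy / inquisitive call: very
high eye fixation (>80%) on a flat electrodermal trace reads as
inquisitive scrutiny rather than empathy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GazeSample, StimulusEvent
from .eda import SelfRegulationVerdict

EMPATHIC_EYES_PCT = 50.0
INQUISITIVE_EYES_PCT = 80.0


@dataclass
class AOISet:
    """Named rectangles per stimulus: id -> [{label, x0, y0, x1, y1}]."""

    rects: dict[str, list[dict]]

    def __post_init__(self) -> None:
        for stim_id, rects in self.rects.items():
            for r in rects:
                if not (r["x0"] < r["x1"] and r["y0"] < r["y1"]):
                    raise ValueError(
                        f"AOI {r.get('label')} of {stim_id}: invalid rectangle")
            eyes = [r for r in rects if r["label"] == "eyes"]
            mouth = [r for r in rects if r["label"] == "mouth"]
            for e in eyes:
                for m in mouth:
                    if (e["x0"] < m["x1"] and m["x0"] < e["x1"]
                            and e["y0"] < m["y1"] and m["y0"] < e["y1"]):
                        raise ValueError(
                            f"{stim_id}: eyes and mouth AOIs overlap")

    def for_stimulus(self, stim_id: str) -> list[dict]:
        return self.rects.get(stim_id, [])


@dataclass
class DwellReport:
    eyes_pct: float
    mouth_pct: float
    valid_time: float  # seconds of valid gaze during scored stimuli
    per_stimulus: dict[str, dict] = field(default_factory=dict)


@dataclass
class EmpathyVerdict:
    label: str  # empathic | low_empathy | inquisitive | indeterminate
    eyes_pct: float
    eda_pattern: str


def _inside(s: GazeSample, r: dict) -> bool:
    # closed rectangles: a sample on the edge counts as inside
    return r["x0"] <= s.x <= r["x1"] and r["y0"] <= s.y <= r["y1"]


def dwell_percentages(gaze: list[GazeSample], aois: AOISet,
                      stimuli: list[StimulusEvent],
                      kinds: tuple[str, ...] = ("video",)) -> DwellReport:
    """Eyes/mouth dwell percentages over the scored stimuli.

    Percentages are of valid-gaze time (invalid samples drop out of both
    numerator and denominator), aggregated across all scored stimuli;
    a per-stimulus breakdown rides along.
    """
    scored = [s for s in stimuli if s.kind in kinds and aois.for_stimulus(s.id)]
    if not scored:
        raise ValueError("no scored stimuli with AOIs defined")
    gaze = sorted(gaze, key=lambda s: s.t)
    tot_valid = tot_eyes = tot_mouth = 0
    per_stim: dict[str, dict] = {}
    mean_dt = ((gaze[-1].t - gaze[0].t) / (len(gaze) - 1)
               if len(gaze) > 1 else 0.0)
    for stim in scored:
        rects = aois.for_stimulus(stim.id)
        eyes = [r for r in rects if r["label"] == "eyes"]
        mouth = [r for r in rects if r["label"] == "mouth"]
        n_valid = n_eyes = n_mouth = 0
        for s in gaze:
            if not (stim.onset <= s.t < stim.end) or not s.valid:
                continue
            n_valid += 1
            if any(_inside(s, r) for r in eyes):
                n_eyes += 1
            elif any(_inside(s, r) for r in mouth):
                n_mouth += 1
        per_stim[stim.id] = {
            "eyes_pct": 100.0 * n_eyes / n_valid if n_valid else np.nan,
            "mouth_pct": 100.0 * n_mouth / n_valid if n_valid else np.nan,
            "n_valid": n_valid,
        }
        tot_valid += n_valid
        tot_eyes += n_eyes
        tot_mouth += n_mouth
    if tot_valid == 0:
        raise ValueError("no usable gaze: zero valid samples during "
                         "scored stimuli")
    return DwellReport(eyes_pct=100.0 * tot_eyes / tot_valid,
                       mouth_pct=100.0 * tot_mouth / tot_valid,
                       valid_time=tot_valid * mean_dt,
                       per_stimulus=per_stim)


def classify_empathy(report: DwellReport,
                     eda_verdict: SelfRegulationVerdict) -> EmpathyVerdict:
    """Rule table combining eye dwell with the electrodermal verdict.

    1. eyes > 80% on a flat trace      -> inquisitive
    2. eyes > 50% (strict)             -> empathic
    3. eyes <= 50%, moderated phasic   -> low_empathy
    4. otherwise                       -> indeterminate
    """
    eyes = report.eyes_pct
    flat = eda_verdict.self_regulated or eda_verdict.pattern == "flat"
    if eyes > INQUISITIVE_EYES_PCT and flat:
        label = "inquisitive"
    elif eyes > EMPATHIC_EYES_PCT:
        label = "empathic"
    elif eda_verdict.pattern == "moderated phasic activity":
        label = "low_empathy"
    else:
        label = "indeterminate"
    return EmpathyVerdict(label=label, eyes_pct=eyes,
                          eda_pattern=eda_verdict.pattern)


def gaze_eda_table(sessions: list[tuple[SelfRegulationVerdict, DwellReport]]
                   ) -> pd.DataFrame:
    """Per-session (EDA pattern, eyes %) rows plus per-pattern means.

    Mirrors the tabulation relating phasic/tonic electrodermal patterns
    to gaze-on-eyes percentages across a cohort.
    """
    if not sessions:
        raise ValueError("at least one session required")
    rows = [{"pattern": v.pattern, "eyes_pct": r.eyes_pct}
            for v, r in sessions]
    df = pd.DataFrame(rows)
    means = (df.groupby("pattern", sort=True)["eyes_pct"].mean()
             .reset_index().assign(row="group_mean"))
    df = df.assign(row="session")
    return pd.concat([df, means], ignore_index=True)[
        ["row", "pattern", "eyes_pct"]]
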