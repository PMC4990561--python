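"""Valence x arousal fusion into the 2D pleasure-arousal plane, the
normative-rating correlation, and the biometric trend rule table.

The valence (from frontal alpha asymmetry) and arousal (from
electrodermal activity) of a stimulus place it as a point in the 2D
pleasure-arousal plane of the PAD model; the categorical call follows
the valence label, with arousal carried for reporting.  Trend triples
over skin conductance, blood volume pulse, and temperature map onto the
classical correlate table: anger = (decrease, increase, increase),
fear = (increase, increase, decrease), happiness = (no change, normal,
no change).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .core import StimulusEvent
from .eda import ArousalScore
from .valence import ValenceScore

TRENDS = ("increase", "decrease", "no_change")

#: "Normal" blood volume pulse in the published correlate table is read
#: as no_change.
TREND_TABLE: dict[tuple[str, str, str], str] = {
    ("decrease", "increase", "increase"): "anger",
    ("increase", "increase", "decrease"): "fear",
    ("no_change", "no_change", "no_change"): "happiness",
}


@dataclass
class PADPoint:
    valence: float
    arousal: float
    stimulus_id: str
    category: str


@dataclass
class TrendTriple:
    gsr_trend: str
    bvp_trend: str
    temp_trend: str

    def __post_init__(self) -> None:
        for t in (self.gsr_trend, self.bvp_trend, self.temp_trend):
            if t not in TRENDS:
                raise ValueError(f"trend must be one of {TRENDS}, got {t!r}")


def pad_point(valence: ValenceScore, arousal: ArousalScore,
              stimulus_id: str, arousal_stimulus_id: str | None = None
              ) -> PADPoint:
    """Combine the two scores for one stimulus into a plane point.

    The category is the valence label; the dominance axis is not
    computed (2D usage).
    """
    if arousal_stimulus_id is not None and arousal_stimulus_id != stimulus_id:
        raise ValueError(
            f"valence is for {stimulus_id!r} but arousal for "
            f"{arousal_stimulus_id!r}")
    return PADPoint(valence=valence.value, arousal=arousal.value,
                    stimulus_id=stimulus_id, category=valence.label)


def correlate_with_iaps(points: list[PADPoint],
                        stimuli: list[StimulusEvent]
                        ) -> tuple[float, float]:
    """Pearson r between predicted and normative valence, and between
    the arousal score and normative arousal, across stimuli carrying
    normative ratings."""
    norms = {s.id: s for s in stimuli
             if s.iaps_valence is not None and s.iaps_arousal is not None}
    paired = [(p.valence, p.arousal,
               norms[p.stimulus_id].iaps_valence,
               norms[p.stimulus_id].iaps_arousal)
              for p in points if p.stimulus_id in norms]
    if len(paired) < 3:
        raise ValueError(
            f"need at least 3 stimuli with normative ratings, got {len(paired)}")
    pv, pa, nv, na = zip(*paired)
    r_val = stats.pearsonr(pv, nv).statistic
    r_aro = stats.pearsonr(pa, na).statistic
    return float(r_val), float(r_aro)


def classify_trends(t: TrendTriple) -> str:
    """Exact lookup in the biometric correlate table; any triple outside
    the three named rows is ``unknown``."""
    return TREND_TABLE.get((t.gsr_trend, t.bvp_trend, t.temp_trend),
                           "unknown")
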