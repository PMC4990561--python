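"""AOI dwell percentages over face videos and the empathy verdict.

Gaze time on the eye region correlates with affective empathy (> 50%
reads empathic), but very high eye fixation (> 80%) on a flat
electrodermal trace reads as inquisitive scrutiny instead.
"""

from affectsync import (SessionSpec, classify_empathy, decompose,
                        detect_self_regulation, dwell_percentages,
                        gen_session)
from affectsync.gaze import AOISet
from affectsync.synthetic import VIDEO_AOIS

for eyes_frac, profile in [(0.60, "reactive"), (0.92, "flat")]:
    bundle, _ = gen_session(SessionSpec(seed=3, gaze_eyes_frac=eyes_frac,
                                        gaze_mouth_frac=0.05,
                                        eda_profile=profile))
    aois = AOISet({s.id: VIDEO_AOIS for s in bundle.stimuli
                   if s.kind == "video"})
    report = dwell_percentages(bundle.gaze, aois, bundle.stimuli)
    verdict = detect_self_regulation(decompose(bundle.peripherals["EDA"]),
                                     bundle.stimulus_span())
    emp = classify_empathy(report, verdict)
    print(f"eyes {report.eyes_pct:5.1f}%  mouth {report.mouth_pct:4.1f}%  "
          f"EDA '{verdict.pattern}'  ->  {emp.label}")
# 60% eyes on a reactive trace -> empathic; 92% eyes on a flat trace ->
# inquisitive (the high-fixation / flat-EDA special case).
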