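"""Score per-stimulus valence from frontal alpha asymmetry.

Unpleasant stimuli elicit more alpha (7-10 Hz) power over the right
hemisphere; the valence score is the mean log-power difference
ln(P_left) - ln(P_right) over frontal pairs, so negative values read
as unpleasant.
"""

from collections import Counter

from affectsync import (SessionSpec, align_session, extract_epochs,
                        gen_session, valence_per_stimulus)

bundle, truth = gen_session(SessionSpec(seed=1, asymmetry_boost=2.0, snr=5.0))
aligned = align_session(bundle)
epochs = extract_epochs(aligned.eeg.series, aligned.stimuli)
scores = valence_per_stimulus(epochs)

agree = Counter()
for sid, score in scores.items():
    planted = truth.categories[sid]
    if planted != "neutral":
        agree[score.label == planted] += 1

sid = next(s for s in scores if truth.categories[s] == "unpleasant")
s = scores[sid]
print(f"stimulus {sid}: value {s.value:+.3f}  label {s.label}  "
      f"(left {s.left_power:.3f} / right {s.right_power:.3f} uV^2)")
print(f"planted sign recovered for {agree[True]}/{agree[True] + agree[False]} "
      "non-neutral stimuli")
# With a 2x right-alpha power boost at SNR 5, sign agreement should sit
# above 90%: the log-ratio of the pair powers is ~ -ln 2 against noise.
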