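# Methods

`affectsync` implements a multimodal pipeline for studying emotion from
synchronized EEG, peripheral (wristband) and eye-tracking recordings:
device synchronization, EEG artifact rejection, frontal-alpha-asymmetry
valence, electrodermal arousal and self-regulation, gaze-based empathy
scoring, and a nonparametric comparison of emotion classifiers across
participant groups.  This note documents the models, the parameters
that matter, the synthetic-data generator, and the limitations.

## Session model and synchronization

All modalities ride on a uniform `TimeSeries` (values, rate, offset):
session time of sample *i* is `offset + i/rate`.  The session clock is
the eye tracker's clock, the one natively timestamped stream; wristband
streams carry their own timestamps and pass through alignment
untouched.  The EEG headset stream is not timestamped.  A loud sound
played near the session start appears in the audio track and — through
the participant's evoked response — in the EEG.  The audio-side
landmark is the first sample exceeding 6 robust noise scales (1.4826 ×
MAD, so the spike cannot inflate its own threshold), refined to the
first threshold crossing; the EEG-side landmark is the time of maximal
cross-channel RMS deviation from baseline, earliest maximum on ties.
Alignment sets the EEG offset so the two landmarks coincide; it is
idempotent.  A single sync sound is assumed; recordings with repeated
markers are out of scope.

Epochs are half-open stimulus-locked slices `[onset, onset + duration)`
of exactly `round(duration × rate)` samples, so disjoint stimuli
conserve samples; a stimulus reaching outside the recorded span yields
an epoch flagged `rejected("truncated")` rather than an error.

## EEG preprocessing

Filtering is zero-phase (forward–backward): a 4th-order Butterworth
band-pass at 0.1–50 Hz and a 2nd-order IIR notch at 50 Hz with quality
factor 30.  Only corner frequencies are externally prescribed; the
realization (order, zero-phase) is this package's choice, verified in
tests by its measured response (≥ 20 dB at 50 and 60 Hz, < 3 dB at
45/55 Hz, exact linearity).

Artifact rejection is a two-pass ICA procedure guided by the other
modalities.  Blinks are maximal both-eyes-invalid gaze runs lasting
0.07–0.5 s (longer runs are tracking dropouts); head/muscle motion is
flagged where the accelerometer magnitude deviates from its ~1 s
running median by a configurable threshold.  Pass 1 fits ICA and
screens epochs: any |sample| > 150 µV, or a worst-channel kurtosis more
than 5 SDs above the across-epoch distribution, marks the epoch bad
(both thresholds configurable; the screening is channel-order
invariant).  Pass 2 refits ICA on the pruned data and applies those
weights to the full recording.  Components whose activation correlates
with the 0/1 blink indicator above |r| = 0.3 are zeroed, capped at two
components — every removed component also removes brain signal, so the
loss is bounded.  With nothing flagged the reconstruction is the
identity to machine precision.  The ICA backend is FastICA with a fixed
seed (default 0); non-convergence within the iteration budget only
perturbs the source rotation and never the reconstruction identity.

## Valence from frontal alpha asymmetry

Band power is Welch's PSD (1 s Hann windows, 50% overlap) integrated
over 7–10 Hz per channel.  Valence is the mean log-power difference
`ln(P_left) − ln(P_right)` over the frontal pairs (F3,F4), (AF3,AF4),
(F7,F8), (FC5,FC6) — log-differences are the standard asymmetry metric
and make the score invariant to overall gain.  Labels: value below
−0.1 → unpleasant, above +0.1 → pleasant, inside the band → neutral;
the ±0.1 neutral band is this package's calibration (three labels are
required but no boundary is prescribed anywhere) and is configurable.

Sign convention: *more right-hemisphere alpha ⇒ unpleasant* (negative
score).  This follows the observation the method is built on.  Note
that a sizeable part of the asymmetry literature treats alpha as
inverse cortical activation and reads the direction the other way;
users comparing against that convention should negate the score.

## Electrodermal activity

The decomposition is additive by construction: tonic = zero-phase
2nd-order low-pass at 0.05 Hz (a running-median mode is available),
phasic = residual, so tonic + phasic reproduces the input exactly.
SCR events are phasic peaks; the onset is the preceding phasic
zero-crossing and the amplitude is the trough-to-peak rise of the *raw*
trace (the filtered residual splits each response between tonic and
phasic, so the phasic peak height alone is biased low).  Events below
0.05 µS are discarded.  Arousal per stimulus is mean SCL over the
presentation plus the summed SCR amplitudes whose onsets fall in a
response window of 1–5 s after stimulus onset (1 s latency lag); window,
lag and weight are configurable.

Self-regulation — the suppression of electrodermal reactivity during
affective stimulation — is detected over the stimulus span:
`self_regulated` iff SCR rate < 1/min **and** tonic range < 0.1 µS,
both strict.  The bounds were chosen once so that a trivially flat
trace and an ordinarily reactive trace (≥ 2 SCR/min) separate cleanly;
the underlying criterion in the literature is qualitative ("flat or
nearly zero").  A pattern descriptor (flat / little or great phasic
peaks / tonic-down variants / moderated phasic activity) mirrors the
vocabulary used in electrodermal screening tables.  Sessions flagged
as antidepressant users in the metadata are reported separately and
never auto-classified, because antidepressants alter (mostly phasic)
EDA.  A heart-rate screen excludes participants whose baseline mean
exceeds a configurable bpm limit (over-excited start).

## Gaze and empathy

Dwell is computed over raw valid samples: the percentage of valid gaze
samples inside the eyes/mouth rectangles while a scored stimulus (the
face videos) is on screen; invalid samples leave both numerator and
denominator, and a sample on an AOI edge counts as inside.  Percentages
are therefore of valid-gaze time, not of wall-clock stimulus time — the
alternative reading would silently punish blinky participants.  An
I-VT-style fixation filter is deliberately not the default; dwell over
raw samples is rate-invariant up to resampling error.

The empathy rule table combines eye dwell with the EDA verdict, in
order: eyes > 80% on a flat trace → *inquisitive* (very high fixation
with no autonomic engagement reads as scrutiny, not empathy);
eyes > 50% → *empathic*; eyes ≤ 50% with moderated phasic activity →
*low_empathy*; otherwise *indeterminate*.  Both thresholds are strict
inequalities.

## Fusion

Valence (EEG) and arousal (EDA) for the same stimulus form a point in
the 2D pleasure–arousal plane; the categorical call is the valence
label, with arousal carried for reporting (the plane usage is
descriptive, not a decision rule; no dominance axis).  Predicted scores
are correlated (Pearson) with the normative 1–9 valence/arousal ratings
of the stimuli where available.  The biometric trend table maps
(skin-conductance, blood-volume-pulse, temperature) triples to anger =
(decrease, increase, increase), fear = (increase, increase, decrease),
happiness = (no change, no change, no change) — "normal" BVP is read as
no change — and every other triple to *unknown*.

## Classification harness and rank tests

Per-epoch features are the 14 per-channel alpha band powers plus the
four frontal pair log-asymmetries, labelled pleasant / unpleasant /
neutral.  Ten classifier configurations (a standard data-mining
workbench roster: SVM with linear polynomial kernel C=1, ridge
logistic, 100-tree random forest, a RIPPER-style rule learner, KNN with
1000 neighbours capped at the training size, Gaussian naive Bayes,
logistic regression, a C4.5-style entropy tree with ≥ 15 instances per
leaf, an RBF network with 2 k-means centers and min σ 0.01, and an MLP
with (features+classes)/2 hidden units, 1000 epochs, learning rate 0.4,
momentum 0.3) are evaluated by stratified 10-fold CV with a fixed seed;
fold counts degrade gracefully with a warning when a class is smaller
than the fold count.  Two roster entries have no scikit-learn twin and
are stood in for: RIPPER by a pruned entropy decision tree, and the RBF
network rebuilt from k-means RBF features feeding a logistic output.

The comparison statistics are implemented from their textbook formulas
(mid-ranks everywhere for ties):

* Friedman: χ²_F = 12/(n·k(k+1)) Σ R_j² − 3n(k+1), χ²(k−1);
* Iman–Davenport: F = (n−1)χ²_F/(n(k−1)−χ²_F), F(k−1, (k−1)(n−1));
* aligned ranks: observations aligned by block means, all n·k values
  ranked jointly, the aligned-ranks χ² statistic against χ²(k−1);
* Quade: blocks weighted by the rank of their range,
  F = (n−1)B/(A−B) against F(k−1, (k−1)(n−1)).

Treatments are the participant groups (G1 non-self-regulated, G2
self-regulated, All pooled) and blocks are the classifiers — the
question asked is group equivalence; a transposed mode compares
algorithms instead.  Ranking direction is ascending (the statistics are
direction-invariant).  No post-hoc tests are run.  A perfectly
column-ordered matrix drives χ²_F to its maximum n(k−1), where the
Iman–Davenport denominator vanishes; `iman_davenport` raises there and
the combined runner reports the limit as statistic ∞, p = 0.  On the
published 10 × 3 benchmark matrix the chain reproduces rank sums
16/21/23, χ²_F = 2.6 and p-values 0.2725 / 0.2855 / 0.3603 / 0.4396.

## Synthetic data generator

`gen_session` emulates one full protocol run — 31 affective images
(11 pleasant / 13 unpleasant / 7 neutral, 5 s each, order
counterbalanced by a cyclic Latin square) followed by 4 videos of 15 s,
after a 20 s baseline — with every planted quantity recorded in a
`GroundTruth` object.  EEG (128 Hz, 14 channels) is 1/f noise (σ 10 µV)
plus stimulus-locked 9 Hz alpha bursts whose amplitude is set per
channel so alpha power = SNR × in-band noise power (default SNR 5); the
boosted hemisphere (right for unpleasant, left for pleasant, power
factor 2 by default) plants the asymmetry.  Blink artifacts are 400 ms
half-cosines, frontal-dominant (AF3/AF4 strongest), at Poisson times
(8/min) during which gaze goes invalid for 200 ms.  The sync sound is a
20-σ burst at 5 s on the session clock; the EEG stream is delivered
*unaligned* with a configurable device lag.  EDA (4 Hz) is a tonic
drift plus a difference-of-exponentials SCR train (3/min, amplitudes
0.2–1 µS) for the reactive profile, or a near-zero flat "U" (range
< 0.05 µS) for the self-regulated profile.  Gaze (60 Hz) lands in the
eyes/mouth AOI rectangles with planted probabilities during videos.
BVP, heart rate, temperature and a gravity-dominated accelerometer
complete the wristband set.  Generation is a pure function of the spec;
a cohort helper plants a 21/22 flat/reactive split over 43 sessions.

What the generator does **not** emulate: volume-conducted source
topographies (channels are independent noise plus planted components),
heart-rate/EDA coupling, saccade dynamics or fixation sequences,
non-stationary alpha, electrode drift, or participant idiosyncrasies.
Passing recovery tests therefore demonstrate that the estimators invert
the generator's planted structure at realistic noise levels — not
field performance on recorded humans.

`gen_feature_cohort` generates per-epoch feature tables directly
(log-normal band-power features with class-dependent means) for
harness-level studies; the class separation default 0.15 was calibrated
once so mean CV accuracy lands in the high-30s percent range against a
33.3% three-class chance rate, the regime of the published benchmark.
Group-comparison simulations run at this feature level (150 epochs per
group) because the planted EEG structure is independent of the EDA
profile, making feature-level nulls equivalent and affordable.

## Numerical choices and tie-breaks

* Spike detection: earliest crossing / earliest maximum wins.
* Arousal selection ties: earlier stimulus onset wins.
* Empathy and self-regulation thresholds: strict inequalities.
* Filters: SOS form, `sosfiltfilt`; degenerate bands and Nyquist
  violations raise.
* SD of a single-row accuracy matrix: reported as 0 with a warning.
* Seeds: every stochastic component (ICA, CV folds, generators) takes
  an explicit seed; defaults are deterministic.

## Known limitations

**Rank tests on shared-data classifier accuracies overstate evidence
against group equivalence.**  The four tests assume independent blocks,
but all ten classifiers are scored on the same realized per-group
dataset, so dataset-level sampling luck (the spurious separability of
any finite draw) shifts entire columns coherently and is read as a
group effect.  In simulations with G1/G2 generated from identical
distributions the combined procedure rejects in roughly half of the
cohorts rather than ~5%, and the inflation does not shrink with sample
size (both the shared and the idiosyncratic accuracy noise scale as
1/√n).  With fully independent matrix cells the same tests reject at
~6.5% — the implementations are sound; the design is the issue.  A
published non-rejection under this design therefore reflects the
particular draw, not a calibrated test; conclusions of "no group
difference" from such pipelines deserve caution.

**Chi-square p-values are unreliable below ~5 blocks.**  At n = 2–4
blocks and k = 3 the exact within-block permutation distribution has
only a few atoms (four at n = 2), so the continuous χ² tail cannot
track the exact p to better than ~0.1–0.3 mid-distribution.  What does
hold — verified by exhaustive enumeration — is that the χ² p always
lies inside the exact p-interval [P(>obs), P(≥obs)].  With the 10
blocks of the benchmark matrix the approximation is adequate.

Other limitations: EDF is read-only (CSV is the writable format); no
wavelet-enhanced ICA; no deconvolution-based SCR model; no fixation
clustering or heat maps; the dominance axis is not computed; single
sync spike only.
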