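# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limits of what the test suite can show.

## The relative episode definition

An acute hypotensive episode is annotated on the MAP channel alone. Both
moving averages are **trailing** (right-aligned) and evaluated at the same
index: a causal convention usable online, and the one under which the two
curves are directly comparable at each minute. The drop test
`MA_5 <= 0.8 * MA_60` is inclusive ("20% or greater"). Within a partially
missing averaging window the mean is taken over the available samples; an
index whose whole window is missing, or with fewer than `width` prior
samples, has no average and can host no onset — consequently the first 59
minutes of a record are onset-free.

Candidate onsets are confirmed by the validity rule: all ten MAP samples
after detection must be observed and above 20 mmHg. A candidate too close
to the record end to complete the horizon is rejected (the rule cannot be
verified). The episode ends at the first index where both averages are
defined and the gap is again under 20%; a closed episode shorter than the
10-minute horizon is discarded outright rather than truncated, which makes
the 10-minute minimum duration an invariant of the output. When a
candidate fails validity the scan resumes at the next index (the same drop
may be confirmed a few minutes later, once e.g. a missing sample has left
the horizon); after a confirmed episode the scan resumes at its end.
Indices are 0-based and episode intervals half-open `[onset, end)`.

Two readings of the validity rule are possible — the one implemented
(floor/non-missing only, plus discarding short-gap events) and a stricter
one requiring the 20% gap itself to persist for 10 minutes. The first is
the literal reading; the discard step is what guarantees the minimum
duration either way.

The conventional fixed-threshold annotator (>= 90% of non-missing readings
below 60 mmHg over >= 30 min, qualifying windows merged into maximal
intervals) is provided for comparison only.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
cardiovascular physiology. Per patient: a baseline drawn per channel (MAP
U(75,105) mmHg, HR U(60,100) bpm, SpO2 U(94,99)% clipped at 100), a slow
sinusoidal drift (2 mmHg amplitude, 3-6 h period), white noise (sd 2/3/0.8
for MAP/HR/SpO2), record length U(360,720) min, missing-completely-at-
random samples (rate 0.02), and isolated non-physiological spikes (rate
0.001 per sample; MAP 250, HR 300, SpO2 10). Artifact spikes are high-side
for MAP deliberately: a low-side MAP spike would drag the 5-minute average
through the relative threshold and manufacture false episodes, a situation
bedside monitors' built-in artifact filtering largely prevents in real
exports; the range filter and the window quality filter are exercised
equally well by the high-side spikes.

A record carries an episode with probability `ahe_prevalence` (default
0.03, matching the low prevalence typical of ICU cohorts). A planted
episode depresses MAP by 25% of its immediately pre-onset level, entering
through a ~2-minute sigmoid transition completing just after the nominal
onset and recovering the same way after 20-40 minutes. Across the plateau
the depression deepens by 0.4 mmHg/min. The deepening reflects untreated
hypotension drifting downward, and it matters numerically: a *flat* 25%
plateau against a 20% threshold leaves the moving-average gap open for
only ~15 minutes (the 60-minute average catches up), so detection lag plus
noise would park every event on the 10-minute discard boundary. With the
deepening slope the gap stays open through the plateau and closed-event
durations sit comfortably above the minimum. The MAP floor (> 21 mmHg) is
enforced throughout.

Each episode is preceded by a **precursor**: an HR ramp and a MAP
down-trend rising linearly from zero over the `precursor_lead` minutes
before onset and relaxing back to zero across the episode. The default
lead is 90 minutes — beyond the largest studied gap (60 min) — so the
predictive signal weakens with lead time but never vanishes on the studied
grid; default amplitudes for learnability studies are +20 bpm and
-8 mmHg at onset. The precursor is what makes forecasting *learnable* and
gives the qualitative expectation that discrimination decays as the gap
grows.

What the generator does **not** model: hemodynamic dynamics, treatment
responses, informative (non-random) missingness, circadian structure,
cross-channel physiological coupling beyond the precursor, and waveform-
level signal. Tests passing on these cohorts therefore demonstrate the
pipeline's *correctness and calibration*, not clinical performance; the
AUROC values it reports are properties of the planted signal, not of any
real cohort.

Cohort generation is a pure function of its config: each patient consumes
an independent child stream of the seeded generator.

## Windowing

Positive windows occupy `[onset - gap - obs, onset - gap)`; one per
episode. When a prior episode exists the window must start at least 120
minutes after that episode's end, enforcing approximate independence of
successive positives. Negative windows require that no annotated episode
intersects `[start - 120, start + obs + 120)`; the margin constrains
*events only*, so a window near the record edge qualifies when the
in-record part of its margin is event-free. Negatives are packed greedily
left to right: an accepted window advances the cursor by one window
length, a blocked start jumps to the first position clearing the blocking
episode's guard. Negatives do not depend on the gap and are shared across
gap lengths. The quality filter counts erroneous samples (missing or
out-of-physiological-range, jointly over all channels) on the raw window
and rejects strictly above 10%.

## Preprocessing

All steps are window-local; nothing outside the window is ever read.
Out-of-range values (defaults: the static normalization ranges) become
NaN; imputation backfills then forward-fills; normalization maps each
channel to [0, 1] by its static range and clips (clipping is moot under
the default ranges, which coincide with the plausibility bounds, but
configurable ranges may differ). A window with a fully missing channel is
rejected rather than filled with a cohort constant — the 10% quality
filter already excludes such windows at the studied lengths. The decay
model's unfilled representation keeps values, an observation mask, the
per-channel time since the last observation (`delta_1 = 0`, accumulating
across unobserved steps), and the last observed value; the substitution of
the training-set channel mean at never-observed positions happens inside
the model, where that mean is known.

## Models and training

Both deep models are NumPy implementations with hand-derived
backpropagation, verified against central finite differences in the test
suite (tolerance 1e-3 relative on sampled coordinates).

**LSTM**: standard gates, forget bias initialized to 1, Glorot-uniform
weights, two stacked layers of 60 units over `[timesteps, 3]` inputs,
inverted dropout 0.4 on the final hidden state, sigmoid dense head
(44,461 parameters at 60 units — checked against the closed form). Adam
(beta 0.9/0.999), cosine-annealing warm restarts (base 3e-3, period 10
epochs, floor 0), L2 1e-3 applied to every parameter including biases,
batch 64, binary cross-entropy, parameters returned at the best validation
loss. The base learning rate and restart period are free choices fixed
during development on synthetic toys.

**GRU-D**: input decay `exp(-max(0, w delta + b))` with one weight per
channel pulls an unobserved input from its last observed value toward the
training-set mean; hidden decay (full matrix from the 3 deltas to the 100
hidden units) shrinks the state between stale observations; the mask is an
extra input to every gate. Decay weights initialize at zero, so decay
factors start at 1 and the untrained cell behaves as a plain gated unit —
the reduction the acceptance suite checks explicitly. Training uses the
fixed learning rate 1e-4 and dropout 0.3; other hyperparameters match the
LSTM.

For null-calibration experiments the `shuffle_labels` switch permutes
training *and* validation labels, so model selection is as label-blind as
gradient descent; the corresponding measurement permutes test labels as
well. With real test labels a shuffled-label model's AUROC does not
concentrate at 0.5 — the classifier aligns by chance with the genuine
structure of the test windows, in either direction — so the permutation
null is the correct reference for "no information in the labels".

## Evaluation

AUROC is computed by the rank-sum identity (ties count half); the test
suite pins it to an all-pairs concordance count and to an independent
library implementation. Bootstrap CIs are percentile over 300-1000
resamples of windows (a cluster-by-patient variant exists, since windows
within a patient are correlated); resamples lacking a class are redrawn.
PPV with no positive predictions is reported as NaN, never 0. The
per-patient classification rate is the fraction of a patient's test
windows correct at the operating threshold (default 0.5, sweepable), with
summary counts at 0.85/0.90 cutoffs.

## Problem sizes in the shipped studies

The acceptance suite runs at workstation scale by design: annotator/oracle
agreement on 100 mixed records; recovery and null calibration on 100
records each; windowing guards on 100 two-patient cohorts; learnability on
300-patient cohorts with gaps {10, 30, 60} min, three seeds, 15 epochs;
permutation-null on five seeds at 8 epochs; bootstrap coverage on 200
binormal datasets of 100 scores at 300 resamples. The full 6x6x4 grid,
1000-resample bootstraps and 100-epoch training are available through the
same interfaces for larger runs.

## Known limitations

* Closed-form detection lag: the 5-minute average needs ~3-5 minutes of
  depressed samples to cross the threshold, so annotated onsets trail the
  physiological drop; the recovery tests budget +/-5 minutes for this.
* The greedy negative packing is maximal for its stride but not globally
  maximal over all placements; it is deterministic, which we value more.
* The synthetic precursor is linear and deterministic in shape; real
  pre-hypotensive signatures are heterogeneous. Absolute AUROC values on
  synthetic cohorts say nothing about clinical cohorts.
* Fine-tuning updates all parameters; no layer freezing is implemented.
* SVM kernel/cost and fine-tuning epoch budget are conventional defaults
  (RBF, C=1, 30 epochs), exposed in the respective specs.
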