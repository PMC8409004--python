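# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Acoustic front-end

Audio is ingested as mono float64 in [−1, 1]; multi-channel sources are
mixed by arithmetic mean *before* anti-aliased polyphase resampling to
8 kHz (exam recordings carry both speakers on one track, and no published
convention exists for the original channel handling — mixing first is this
package's choice).

MFCC extraction follows the classical recipe with every knob pinned in
`FeatureConfig`:

| parameter | default | meaning |
|---|---|---|
| window | 25 ms (200 samples), rectangular | analysis frame; Hamming selectable |
| hop | 10 ms (80 samples) | frame stride; T = 1 + ⌊(n − 200)/80⌋ |
| DFT | 256-point, frame zero-padded | periodogram P = \|DFT\|²/200, one-sided |
| filterbank | 26 triangles, 0–4000 Hz | centers evenly spaced in Mel; peak 1 at the center bin |
| cepstrum | DCT-II, orthonormal | natural log of energies, floored at ε = 1e−10 |
| output | [log-energy, c₂…c₁₃] | c₁ discarded, replaced by ln Σx² of the raw frame |

Choices worth stating explicitly, because the conventional literature
varies: the analysis window defaults to rectangular (the most literal
reading of a "periodogram estimate"); logs are natural throughout; the
substituted energy is log-compressed so it lives on the same scale as the
cepstral coefficients; the final dimensionality is 13 ([energy, c₂…c₁₃]).
There is no pre-emphasis, liftering, delta features, or per-recording
normalization. The ε floor makes all-zero audio well-defined (energy
column ln ε, cepstral columns exactly 0). One useful invariant follows:
scaling a waveform by a > 0 shifts the energy column by 2·ln a and leaves
cepstral columns untouched (with the rectangular window, above the floor).

## Hierarchical LSTM

Hour-scale recordings produce hundreds of thousands of MFCC frames — far
beyond a single recurrence's practical memory. The model therefore runs at
two levels with hidden dimension 64 at both:

* frames are grouped into non-overlapping segments of 2000; within a
  segment, 10 consecutive 13-dim vectors are concatenated into one 130-dim
  step input (non-overlapping grouping, not subsampling), the last segment
  zero-padded to a multiple of 10;
* the low-level LSTM's last *valid* hidden state summarizes each segment;
  the high-level LSTM runs over the segment summaries; an MLP
  (64-dim hidden layer, ReLU — the head nonlinearity is unspecified in the
  source architecture, ReLU is our choice) and a softmax produce the
  2-class probabilities. All initial states are zero.

Recurrences are computed over padded step grids for vectorization, but the
output is gathered at each sequence's true length, so padded steps have
exactly zero influence and zero gradient.

## Variable-length CNN

Seven convolutional blocks of two kernel-3 / stride-1 / padding-1
convolutions, each followed by ReLU, with max pooling (kernel 4, stride 4).
Published descriptions of this architecture are ambiguous on two points,
both configurable here:

* *ReLU placement*: per-convolution (default) or a single ReLU after the
  block's pool;
* *number of pooling blocks*: 6 or 7. The default is 7, making one
  pre-pool position span 4⁷ frames ≈ 164 s (~2.5 minutes) of audio; with 6
  reductions a position spans ≈ 41 s. The saliency stride is always derived
  from the config, never hard-coded.

Channel widths default to (16, 32, 32, 64, 64, 128, 128) — deliberately
modest so desk-scale CPU training stays fast; they are configurable.
Inputs shorter than one position are right-zero-padded; a recording of T
frames owns max(1, ⌊T/4⁷⌋) positions and a trailing remainder is dropped.
In batches, a validity mask keeps padded positions out of the global
average. Global average pooling plus a *linear* classifier makes the model
length-invariant and underpins the saliency construction below.

Convolution weights use He initialization (normal, sd √(2/fan-in), zero
biases): with 14 stacked ReLU convolutions, fan-in-uniform initialization
measurably attenuates activations layer by layer and the network starts
from a vanished-signal regime; He scaling preserves activation variance
through depth. Linear/LSTM weights use the conventional uniform
±1/√fan-in, with the LSTM forget-gate bias started at +1.

## Training

Adam with learning rate 1e−4, betas (0.99, 0.999), batch size 4, epochs
per task/model (NC-vs-DE: LSTM 8, CNN 32; NDE-vs-DE: LSTM 32, CNN 64).
Cross-entropy is weighted by inverse class frequency (dementia is the
minority class in the cohorts this targets). A single seed fans out to
initialization and per-epoch shuffling; identical seed + data reproduce
the loss trace bit-for-bit. Predicted label is the argmax of the softmax,
ties resolved to the negative class.

## Saliency and SAF

Let F ∈ R^{C×L} be the pre-pool feature map and (w, b) the DE row of the
linear classifier. The raw saliency track is r_t = w·F_t + b; since the
recording logit is w·mean(F) + b, mean(r) equals the DE logit *exactly*
(up to floating point; the package asserts agreement within 1e−5). The
bias is included per position so this identity holds; a bias-free variant
is a one-flag change.

Nearest-neighbor expansion to seconds is realized as span membership:
second s (the interval [s, s+1)) takes the value of position ⌊s/stride⌋,
clamped to [0, L−1] — equivalent to nearest-neighbor on position centers
for uniform spans and well-defined at the edges.

SAF[+] of a test is the fraction of its administered seconds with
per-second DE[+] > 0; SAF[−] uses ≤ 0, so the two always sum to 1 for the
same recording and test. Seconds are attributed to a test when their
integer index lies in the half-open test interval; sub-second intervals
that contain no integer index are excluded with a warning. Cohort tables
average SAF[+] over true positives and SAF[−] over true negatives only
(false predictions contribute to neither); the sd is the sample (n−1)
estimator, reported as 0 for n = 1 along with n so readers can discount
it. Tests whose larger sample count falls below a configurable minimum
(default 10) are routed to a separate low-sample table rather than the
main one.

## Labeling, splits, metrics

* **180-day rule.** Among diagnoses on/before the recording date or within
  180 days after it, the closest in absolute days wins; an exact tie
  between a before and an after diagnosis resolves to the on/before one
  (status at the time of testing). If the only diagnoses are > 180 days
  after, the recording is NC when the closest of them is NC, otherwise
  UNLABELED and excluded from modeling. NDE = NC ∪ MCI. Every (date,
  timeline) pair maps to exactly one of {NC, MCI, DE, UNLABELED}.
* **Splits.** Random at the participant level (all of a participant's
  recordings travel together), folds balanced within ±1 participant, an
  optional held-out test fraction (default 20%; configurable because the
  original held-out proportion is not published).
* **Metrics.** Confusion metrics at threshold 0.5 (a score exactly at the
  threshold predicts negative); ROC and PR AUCs by trapezoidal integration
  of the exact step curves; weighted F1 is the support-weighted mean of
  per-class F1; fold summaries report mean ± sample sd. Short-segment
  evaluation extracts one uniform-random contiguous 5/10/15-minute frame
  window per recording per round (five rounds), returning whole recordings
  flagged when shorter than the request.
* **Duration analysis.** Per-test group comparisons (NC–MCI, MCI–DE,
  NC–DE, DE–NDE) use Welch's unequal-variance t-test by default (Student's
  selectable), with star codes * p<0.05, ** p<0.01, *** p<0.001.

## Synthetic cohorts

The generator emulates the *structure* the analysis relies on, not the
phonetics of real speech:

* repeat recordings per participant (1–3, probabilities 0.5/0.3/0.2) with
  statuses sorted by severity, so impairment progresses and never
  regresses; diagnosis entries sit on recording dates, so the 180-day rule
  reproduces the intended label for every recording by construction;
* per-test administered durations from truncated normals (floor
  5 s × scale) whose class-conditional means/sds (seconds) follow the
  observed timing of the standard exam battery, e.g. Boston Naming Test
  NC 405.9 ± 176.8 vs DE 611.1 ± 260.2; a `duration_scale` shrinks
  everything proportionally (desk default 0.1, ~1–2 min recordings; a
  full-scale profile with scale 1.0 exists but is not exercised by the
  tests);
* two alternating "speakers" (examiner f0 100–140 Hz, participant
  160–220 Hz), utterances 0.8–2 s of five-harmonic tone complexes,
  amplitude-modulated at a syllable rate, separated by exponential pauses.

Impairment effects are monotone in one `effect_scale` and act on two
independent pathways: timing (duration priors interpolate from a
class-neutral baseline to the class-conditional priors) and short-time
acoustics (pause fraction 0.25 → +0.20, syllable rate 4 Hz → −40%, f0
jitter 2 Hz → ×5, harmonic roll-off 0.75 → −0.20, at full scale for DE;
MCI receives half the shift). At effect scale 0 all classes are
identically distributed by construction — the generator's own null.
Utterance loudness is RMS-normalized so amplitude alone never separates
classes; waveform peaks are clipped to ≤ 1.

**What passing tests show — and do not.** The desk-scale parameter-recovery
experiment (120 recordings of ~1–2 min, 5-fold participant-level CV, LSTM
at 8 epochs) demonstrates that the pipeline recovers a strong, known
class-conditional acoustic effect (mean CV AUC ≥ 0.90) and returns to
chance (AUC ≈ 0.43 on the pinned seed) when the effect is removed. It says
nothing about performance on real clinical audio: tone-complex speech has
none of the linguistic content, examiner variability, recording artifacts,
or label noise of real exams, and the desk-scale effect size is chosen to
be strong. Problem sizes in the suite (120 recordings, 60–120 s, LSTM
only for the recovery experiment) are the package's desk-scale profile,
chosen to keep a full CPU run of the suite in a few minutes; the CNN's
learning dynamics are exercised on constructed separable data instead
because its full-protocol epoch counts make full CV training an
hours-long CPU job.

## Known limitations

* No speech-to-text, no speaker diarization: the models see only
  short-time spectral structure.
* The NumPy networks are CPU-oriented; full-scale training (hour-long
  recordings, 64 epochs) is out of desk reach, which is why the package
  ships the synthetic desk-scale protocol instead of claiming clinical
  reproduction.
* Whether a second that straddles two tests should be split between them
  is unspecified in the SAF definition; this implementation assigns each
  integer second to at most one test by index membership.
* The saliency position span (~2.5 min vs ~41 s) depends on the 6-vs-7
  pooling-block reading; both are supported, the default follows the
  2.5-minute reading.
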