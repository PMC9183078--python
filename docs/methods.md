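# Methods

## The task and the protocol

Gait detection from a body-worn tri-axial accelerometer is treated as
binary classification of short windows: each 2 s window (200 samples x 3
axes at 100 Hz) is gait or non-gait. The question the package answers is
not "how accurate is a gait detector" but "how much does *personalising* a
general detector help, and whom does it help".

The protocol is leave-one-subject-out (LOO). For a cohort of N subjects,
each subject in turn is held out; a **general** model is trained on the
pooled, per-subject-balanced windows of the other N-1 subjects; a
**personalised** model is the general model fine-tuned on a stratified 60%
of the held-out subject's own windows at one tenth of the general learning
rate; both are scored on the remaining 40%. Each subject's comparison is
repeated (default 5 repetitions, 3 in the shipped study scale) with
repetition-derived seeds perturbing the general model's initialisation and
batch shuffling, the personal split, and the fine-tuning shuffle; results
are averaged per subject. The headline numbers are the unweighted mean over
subjects of (personalised - general) accuracy and its per-subject maximum;
an evaluation-window-weighted variant is reported alongside because the two
averaging conventions differ when subjects contribute unequal window
counts.

Accuracy is the fraction of correctly classified windows. Balancing makes
0.5 the chance level everywhere, which keeps per-subject accuracies
directly comparable.

## Synthetic cohorts

Clinical gait recordings with per-second video annotation are rarely
redistributable, so the package generates cohorts with the same structure.
The simulator is a *signal-shape* model, not a biomechanical one: its only
obligations are (a) the formats and failure modes of real data — per-second
annotation that does not align with behaviour, transition seconds, flipped
sensors, class imbalance — and (b) a learnable, subject-specific gait
signature with genuine outlier subjects.

Per subject, activity alternates between gait and non-gait bouts with
exponential durations (mean `bout_mean_s`, floor 3 s; the floor keeps whole
annotated seconds inside bouts so transition exclusion is exercised without
dominating). During gait the gravity axis carries a 1 g offset plus a
sinusoid at the step frequency (cadence/60 Hz) with a 0.4-weight second
harmonic; its amplitude alternates between consecutive steps by
(1 ± asymmetry), emulating left/right asymmetry; the other two axes carry
phase-shifted copies at half amplitude. Tremor, when present, adds a
sinusoid at `tremor_freq` on all three axes throughout (tremor does not
pause when walking stops — this is what makes outlier non-gait resemble
typical gait in variance and confuses the general model). Non-gait is
gravity plus noise plus occasional slow postural drifts. Gaussian noise
(sd `noise_sd`) is added everywhere. A flipped mounting negates the
gravity-axis channel. Each whole second wholly inside a bout receives that
bout's label; seconds spanning a bout boundary are left unlabelled.

Archetype parameter ranges (uniform draws, fully determined by the profile
seed):

| parameter          | typical    | mildly impaired | outlier    | units     |
|--------------------|------------|-----------------|------------|-----------|
| cadence            | 95–115     | 70–95           | 40–70      | steps/min |
| step amplitude     | 0.25–0.45  | 0.15–0.30       | 0.08–0.20  | g         |
| asymmetry          | 0–0.1      | 0.1–0.3         | 0.3–0.6    | —         |
| tremor amplitude   | 0          | 0–0.05          | 0.05–0.15  | g         |
| tremor frequency   | —          | 4–6             | 4–6        | Hz        |
| noise sd           | 0.02–0.05  | 0.03–0.07       | 0.05–0.10  | g         |
| mean bout length   | 15–30      | 12–25           | 8–20       | s         |

Flip probability is 0.15 per subject. Ranges were chosen once so that
typical subjects are easy for a peer-trained model while outliers are hard
but perfectly learnable from their own data — the regime in which
personalisation has something to recover. Nothing in the generator is
calibrated to a real signal corpus; consequently, passing tests demonstrate
that the *protocol machinery* behaves as claimed (leakage-free, seeded,
sensitive to representation gaps), not that any particular accuracy level
transfers to real patients. Real-data features the generator does not
emulate include non-stationary cadence, turning, stair gait, device
non-linearity and annotation errors.

## Preprocessing conventions

- Time is seconds from recording start; second i is the half-open interval
  [i, i+1); sample k sits at k/rate.
- Resampling: per-axis linear interpolation onto the grid t0 + k/rate,
  k = 0 … floor((t_end - t0)·rate); no extrapolation.
- Flip correction: if the mean of the gravity-axis channel is negative the
  channel is multiplied by −1. The gravity axis defaults to the axis with
  the largest absolute mean, which works for any fixed mounting. The rule
  is idempotent and preserves each sample's vector magnitude.
- Device calibration (gain/offset harmonisation across devices) exists as
  an identity hook: simulated cohorts carry no device bias, and the seam is
  where a real-data deployment would plug an estimator in.

## Segmentation and balancing

Candidate windows start every 0.4 s from t = 0 and cover 200 samples; a
candidate is emitted only if all covered samples share one label other
than unlabelled (half-open index ranges; a window needs its full sample
complement — no padding). Balancing undersamples the majority class to the
minority count, seeded, preserving order. Balancing is applied **per
subject** rather than once on the pooled corpus: this keeps every LOO
pretraining pool and every personal split balanced, so per-subject accuracy
stays interpretable against 0.5. The majority class is whichever is larger
for that subject, which handles gait-heavy synthetic schedules as well as
the usual non-gait surplus.

## Features and the NN

Per window: mean and population variance (divide by n; with n = 200 the
distinction from the sample variance is immaterial but must be pinned for
oracle tests) of x, y, z and of the per-sample vector magnitude, in the
fixed order (means x,y,z,vm, then variances). vm is computed per sample
before averaging. Feature z-scoring (statistics from the pretraining pool
only, frozen through fine-tuning) is on by default for the NN because
sigmoid units saturate on raw g²-scale variances; the flag is recorded in
every run log and config snapshot.

## Models and training

Both classifiers end in a single sigmoid output unit trained with binary
cross-entropy. For the CNN, hidden activations are ReLU; a ReLU *output*
cannot represent a two-class probability under cross-entropy, so the output
unit is sigmoid. The second convolution is 8 filters of kernel 16 by
default ("halving the filter size"); a `wide_second_conv` flag provides the
16-filters/kernel-32 alternative reading. Convolutions are valid (no
padding); max-pooling uses pool size = stride = 3 with the trailing
remainder dropped; ties in the pool take the first maximum. The resulting
stack on a 200-sample window is 169 → 56 → 41 → 13 → flatten 104 → 3 → 1,
and the parameter counts are 41 (NN) and 2127 (CNN).

The optimiser is deliberately the smallest fully specifiable one: plain
mini-batch gradient descent (NN lr 0.05, CNN lr 0.01, batch 32; NN 150
epochs, CNN 60), seeded so that initialisation (symmetric Glorot-uniform
weights, zero biases), shuffling and dropout masks all derive from one
generator — identical data and config give bit-identical models. Analytic
gradients are verified against central finite differences (relative 1e-5)
in the test suite. CNN parameters and inputs are float32 (training cost);
the NN stays float64.

**Stuck-model rule.** Small networks occasionally stall in a poor basin.
A fit whose final training accuracy is below 0.6 is discarded and retrained
from a freshly derived seed, up to 5 attempts; if all attempts stall the
best is kept and a warning logged.

**Fine-tuning.** Personalisation deep-copies the general model and
continues SGD on the tune set at 0.1x the general learning rate. The epoch
count defaults to the general epoch count: at a 10x smaller rate this still
only tweaks a model that already fits, but it provides enough steps to
de-saturate an output the general model got confidently wrong — which is
precisely the situation on an outlier subject, where a short fine-tune
(e.g. 20 epochs) provably leaves the model at chance. The general model is
never modified; frozen feature statistics travel with the copy.

## Shipped study scale

The reference study simulates 12 subjects (10 typical, 2 outliers) at
600 s each — roughly 1000 balanced windows per subject, matching the
per-subject corpus of a realistic annotated session — with 3 repetitions.
The NN runs at its full 150 epochs; the CNN runs at 6 epochs, which on
this corpus already reaches ≈0.98 pooled training accuracy, so further
epochs change the comparison only marginally. These sizes are the
package's own defaults for a desk-scale run; all are config-overridable.

## Numerical and degenerate-input choices

- Empty or single-class training sets, absent classes at balancing, and
  classes with fewer than two windows at splitting raise errors naming the
  subject.
- `slide_windows` requires window and stride to cover whole samples.
- Stratified splits take round(fraction x class size) per class, clamped so
  both parts stay non-empty.
- All derived seeds come from `numpy.random.SeedSequence` and stay below
  2^31.
- Checkpoints serialise layer parameters to JSON; Python float repr makes
  the round-trip bit-exact.

## Known limitations

The simulator's outliers are hard for the *general* model yet cleanly
learnable from their own data; real severely-impaired gait can be
intrinsically ambiguous, and the achievable personalised accuracy there is
an empirical question this package cannot answer. Per-second annotation is
emulated as exact; annotation noise is not modelled. The LOO protocol
retrains the general model for every repetition, which is statistically
conservative but computationally the dominant cost.
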