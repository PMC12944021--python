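# Methods

## Problem and scope

`densehar` performs *dense* human activity recognition: given a window
`X = [x_1 … x_T]` of tri-axial acceleration from two body-worn sensors
(lower back and right thigh, n = 6 channels, 50 Hz, units g), it assigns an
activity label to **every frame** rather than one label per multi-second
window. The label repertoire is nine daily-life activities — walking,
running, standing, stair ascent/descent, sitting, lying, cycling seated and
cycling standing — with a six-activity subset for an older cohort. The
pipeline covers: a synthetic cohort simulator, signal plumbing (CSV I/O,
windowing, resampling, channel selection), four sequence-labelling
architectures, training with leave-one-participant-out cross-validation
(LOPO-CV), majority-vote ensembling across fold models for cross-cohort
transfer, and evaluation with imbalance-aware metrics and paired t-tests.

## Sequence labellers

All four families map an n×T window to a T×C row-stochastic matrix for
*arbitrary* T; no input padding is used to equalise window lengths.

- **CNN**: stacked 1-D convolutions. Each kernel computes
  `o_t = ReLU(Σ_{i=1..k} w_i·x_{t+i−1} + b)` at valid positions advancing by
  the stride. Stride-shortened feature sequences are symmetrically
  edge-padded to ⌈T/stride⌉ and restored to length T by nearest-neighbour
  upsampling before the next block and before the head. Edge replication
  and nearest-neighbour (rather than zeros) avoid fabricating
  zero-acceleration frames.
- **GRU**: gated recurrent units with update gate
  `z_t = σ(W_z x_t + U_z h_{t−1} + b_z)`, reset gate
  `r_t = σ(W_r x_t + U_r h_{t−1} + b_r)`, candidate
  `h̃_t = tanh(W_h x_t + U_h (r_t ∘ h_{t−1}) + b_h)` and state
  `h_t = (1−z_t) ∘ h_{t−1} + z_t ∘ h̃_t`. The gate activation is the
  logistic sigmoid. Bidirectionality is a config flag: a second cell runs
  over the time-reversed window and per-frame states are concatenated.
- **ConvRec / ReConv**: conv block before / after the recurrent block; the
  length-restoration rule above keeps every block frame-aligned.

Each conv or recurrent layer is followed by dropout and batch
normalisation. Batch statistics are pooled over batch and time per feature;
running statistics are frozen and used at evaluation, so evaluation-mode
forward passes are deterministic. The head is a shared per-frame affine map
with a softmax over the C classes — the minimal dense-labelling head.
Argmax ties break to the lowest class index.

The engine is pure NumPy with hand-written backward passes (convolution,
backprop-through-time, batch-norm, dropout, affine head), verified in the
test suite by finite-difference-free equation oracles and by layer-vs-scan
equivalence; optimisation uses adaptive moment estimation (Adam) with
conventional moment decays (0.9 / 0.999, ε = 1e-8) and the learning rate
from the model configuration.

### Named preset

The tuned recurrent architecture is a two-block bidirectional GRU with 128
hidden units per layer and dropout 0.3 between recurrent layers. The
published block description is ambiguous about whether the second block adds
a third layer; both readings ship as presets (`three_layer`, default, =
128/128/128; `two_layer` = 128/128). Desk-scale runs use a reduced preset
(one bidirectional layer, 32 units) so CPU-only LOPO-CV stays in minutes;
this trades a little capacity for tractability and is the preset used by the
bundled pipeline checks.

## Training protocol

Training windows are fixed at T = 200 frames (4 s at 50 Hz), cut
consecutively without overlap; the final shorter remainder window of each
recording is kept, since the models accept variable length. Windows are
shuffled per epoch, bucketed by length, and optimised by Adam on the mean
per-frame cross-entropy (probabilities clipped at 1e-12). The initial
train/validation/test partition for hyperparameter tuning is a grouped
random split by participant (default 70/15/15, seeded). Early stopping
monitors validation weighted F1 with a patience of a few epochs; the epoch
count and batch size are not externally prescribed, so the defaults
(max 12 epochs, patience 3, batch 16 — the quick experiment runner uses
6/2/32 and the desk-scale pipeline checks 10/3/32) are documented package
choices that bound desk-scale cost.

**Random search**: hyperparameters are drawn uniformly from discretised
grids of the published ranges — CNN layers 1–5, kernels/layer
{32…1024}, kernel and stride size 1–11, GRU layers 1–3, units {32…256},
dropout {0.3, 0.6}, learning rate {0.001…0.1} (log grid) — 50 draws per
architecture family by default, duplicates re-drawn. Whether the original
50-draw search was per family or global is not stated; per family is
implemented.

**LOPO-CV**: one fold per participant; the held-out participant never
contributes training or validation windows (asserted in code). Within a
fold, ~15 % of the remaining participants (at least one) form the
validation group. Held-out recordings are predicted densely as a single
variable-length window. Fold failures are collected and raised together,
never dropped.

**Cross-cohort ensemble**: all fold models predict every frame of an unseen
recording; the modal label wins, vote ties are resolved by the largest
summed class probability across models, and an exactly tied sum falls back
to the lowest class index so the vote is deterministic.

**Metrics**: one-vs-rest precision/recall/F1/accuracy per class over the
union of truth and predicted label sets. Macro averages are unweighted over
classes with non-zero support; weighted averages use truth-share weights
(so weighted recall equals overall accuracy). Zero-support classes stay in
the confusion matrix — out-of-repertoire predictions count as false
positives — but are excluded from averages. Condition comparisons use
two-sided paired t-tests on per-participant weighted F1 (the pairing unit
for the reported mean ± SD spreads), significance at p < 0.05, no
multiple-testing correction. Zero-variance difference vectors are flagged
as degenerate rather than producing NaNs.

## Synthetic cohorts

No frame-labelled dual-sensor recordings ship with the package; a simulator
generates cohorts whose *statistical structure* matches the study
populations so every downstream stage is testable offline.

- **Label process**: a semi-Markov chain — an embedded activity-to-activity
  transition matrix plus exponential dwell times with per-activity means
  (walking 30 s, sitting 60 s, stairs 8 s, …), truncated below at 1 s to
  avoid degenerate one-frame bouts. The initial activity is drawn from the
  dwell-weighted stationary distribution. `expected_activity_shares`
  computes the exact long-run frame shares (stationary distribution of the
  embedded chain weighted by E[max(1, Exp(m))] = 1 + m·e^(−1/m)), which the
  tests compare against empirical label frequencies. The default young
  profile gives sitting+standing+walking ≈ 85 % of frames and puts stair and
  standing-cycling classes below 5 % each, reproducing the strong class
  imbalance of free-living data. Real per-activity proportions are not
  restated in the source publications, so these shares are documented
  package choices, not measured values.
- **Signal model**: per activity and sensor, gravity projection (static
  orientation, magnitude within [0.9, 1.1] g) + a small harmonic stack at
  the movement cadence (amplitude ∝ 1/harmonic) + Gaussian noise
  (SD 0.05 g). Axis convention: x is vertical when standing, per sensor.
  Postures have zero cadence; locomotion is distinguished by cadence
  (walking 1.8 Hz, running 2.7 Hz, stairs 1.4/1.6 Hz) and amplitude. The
  geometry deliberately encodes the sensor asymmetries seen in real data:
  the lower back is nearly identical across sitting and standing (trunk
  stays upright) while the thigh separates them; the thigh is nearly
  identical across sitting and lying while the back separates them; stairs
  keep near-walking orientations and adjacent cadences so walking/stairs
  genuinely overlap.
- **Cohorts**: the young profile has 22 participants, ~98 ± 33 min each,
  nine activities; the old profile has 18 participants, ~42 ± 6 min, the
  six-activity subset, cadence scaled by 0.78 and amplitudes by 0.85, with
  an extra 0.55 damping of stair dynamics so old-cohort stairs drift toward
  standing-like signals. These scalings encode slower movement in older
  adults; the specific factors are documented configuration values, not
  biomechanical claims. Desk-scale variants (default 8 young + 6 old
  participants × 5 min) keep all dynamics and shrink only size.
- **Seeding**: one master seed; per-participant child seeds by a fixed
  `SeedSequence([master, index])` splitting rule; identical (profile, seed)
  reproduce label sequences bitwise.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and impact artefacts, sensor drift and
re-orientation, walking aids, within-bout cadence variability,
transition-phase frames (bouts switch instantaneously), annotation noise,
and between-participant biomechanical idiosyncrasies beyond the seed. The
synthetic problem is easier than real HAR; pipeline-recovery thresholds
(e.g. desk-scale LOPO weighted F1 ≥ 0.85) validate the machinery, not
real-world accuracy, and the published cohort-level F1 values are not
reproducible without the real datasets.

## Signal plumbing choices

- **Resampling** (downsampling to 25/20/15/10 Hz): rational-factor polyphase
  resampling with a sharp Kaiser-windowed anti-alias FIR (64 taps per
  phase, β = 14), so gait harmonics do not alias and cascaded resampling
  agrees with direct resampling to ~1e-7 relative on band-limited signals.
  Plain decimation is available as a config alternative for sensitivity
  checks. Output length is round(T·target/source).
- **Label resampling**: nearest-source-frame mapping, which moves activity
  transitions by at most one output frame.
- **Windowing**: half-open [start, end) on 0-indexed frames; non-overlapping;
  remainder kept; concatenation reconstructs the input exactly (property
  tested over random lengths).
- **CSV dialect**: header `timestamp,back_x,back_y,back_z,thigh_x,thigh_y,
  thigh_z,label`, '.' decimal, one row per frame, label map in a sidecar
  `<file>.labels` table. A dialect descriptor (column aliases, 3-channel
  layouts, drop-vs-error for unknown labels) adapts other public column
  namings without code changes. Non-monotone timestamps are stably sorted
  with a warning.

## Experiments

`run_experiment` reproduces the five study designs (architecture
comparison, sampling-frequency ablation, sensor-location ablation,
window-length check, combined-cohort training) on synthetic cohorts,
deterministic given (spec, seed). Desk-scale defaults (8+6 participants ×
5 min, reduced-width models, 6 epochs) keep each experiment in minutes on
one CPU; the full 22+18 profile at study durations sits behind
`scale="full"`. Hyperparameter search is optional per experiment —
mirroring a tune-once-then-reuse protocol — with the tuned GRU preset as
the default.

Directional effects the simulator supports by construction: pooling the two
cohorts for training improves old-cohort recognition relative to young-only
training (checked over three seeds; the old cohort's slowed, damped
dynamics are otherwise unseen), and thigh-only input outperforms
lower-back-only input (the generator gives the thigh the larger, more
activity-specific signatures). The site contrast is exercised through the
`location` experiment rather than asserted as a hard suite invariant, since
at desk scale its margin depends on cohort size.

## Known limitations

- The NumPy engine is CPU-bound and single-threaded per operation; it is
  sized for desk-scale studies, not for the full 1024-kernel/256-unit search
  space at study-scale data volumes.
- Training determinism is exact in-process; across BLAS backends the final
  parameters can differ at floating-point level.
- No event/bout-level metrics, no transition-segment scoring, no
  calibration analysis; LSTM/attention/transformer variants and data
  augmentation are out of scope.
- `paired_f1_test` reports raw p-values; comparing many conditions invites
  multiplicity concerns the package intentionally leaves to the analyst.
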