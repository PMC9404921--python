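# Methods

## Problem and approach

`ecgssl` implements contrastive self-supervised representation learning for
stress/affect classification from single-lead ECG.  The premise: labeled
physiological data is scarce and expensive, but unlabeled ECG is plentiful.
A 1-D CNN encoder f(·) is therefore pretrained on unlabeled segments with a
SimCLR-style pretext task — pull the embedding of a segment x and a randomly
augmented view x′ together, push all other segments in the minibatch apart —
and then fine-tuned with a small softmax head on whatever labeled segments
exist.  The package also implements the two benchmarks such a claim is
judged against: the identical CNN trained from random initialization
(fully supervised), and an RBF-SVM on nine classical heart-rate-variability
(HRV) features.

## Model

**Encoder f(·).**  Three convolutional blocks, each one conv layer
(channels-last, "same" padding) → ReLU → max-pool(4) → dropout(0.1), with
filters 32 → 64 → 128 and kernels 32 → 16 → 8; then a dense layer of 80
units applied at every remaining time position (equivalent to a width-1
convolution) with an L2 weight penalty, a ReLU, and a flatten.  For a 5 s
segment at 256 Hz (L = 1280) the representation h has 20 × 80 = 1600
features.  The per-position reading of the 80-unit layer honors the stated
layer order (dense before flatten); the L2 "size" is interpreted as the
penalty coefficient (default 3.0) — both are configurable, and neither
interpretation is asserted as uniquely correct.

**Projection head g(·).**  One dense layer with 256 units maps h into the
contrast space z.  The head is **linear by default**.  A softmax variant is
available (`projection_activation="softmax"`), but measurement shows it
cannot drive the pretext task: softmax confines every z to the probability
simplex, where pairwise cosine similarities are compressed into [0.94, 1.0]
and the NT-Xent loss stays at its chance value log(2N−1) (5.37 → 5.13 over
8 epochs, versus 4.33 for the linear head on the same data and seed).  With
no usable contrast gradient, "pretraining" degenerates into weight decay
and transfers a slightly damaged initialization.  The linear head is
therefore the package's default; the softmax head is retained as a config
switch for comparison runs.

**Objective.**  Cosine similarity sim(z₁, z₂) = z₁ᵀz₂ / (‖z₁‖‖z₂‖) and the
NT-Xent loss: for a minibatch of N segments and their views (2N embeddings,
rows 2k/2k+1 paired), each anchor's loss is
−log[exp(sim(z_x, z_x′)/τ) / Σ_{y≠x} exp(sim(z_x, z_y)/τ)] with the
denominator over the other 2N−1 embeddings (one positive, 2(N−1)
negatives); the reported loss is the mean over all 2N anchors.  τ defaults
to 0.1.  The implementation is verified against a brute-force double-loop
enumeration (≤ 1e−9 over 200 random batches) and its analytic gradient
against central finite differences (≤ 1e−7).  At N = 1 the loss is exactly
zero (numerator equals denominator).

**Siamese branches.**  Branch one receives x unaltered; branch two receives
x′, with fresh augmentation draws per segment per epoch (views are never
cached, so the pretext task cannot memorize fixed pairs).  Upstream
training never touches ground-truth labels; this is enforced by test
(shuffling labels leaves the loss history bit-identical).

**Downstream classifier.**  Identical encoder architecture plus a dense
softmax head with one unit per class.  Pretrained encoder weights (when
given) are copied bit-exactly; the head is always freshly initialized; all
layers are fine-tuned.  The projection head never transfers.

**Training.**  Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7), upstream lr 1e−4 and
batch 32, downstream lr 1e−3 and batch 128 — the conventions for this task
family.  The network stack (conv/pool/dropout/dense layers, backprop, Adam)
is implemented in NumPy in `ecgssl.nn`, with Glorot-uniform initialization,
float32 compute, and full determinism given a seed.  The complete
parameter gradient path is finite-difference checked in the test suite.

## Augmentations

Six label-free operators produce x′ (defaults in parentheses, all
configurable): amplitude scaling (c ~ U(0.5, 2)), negation, horizontal
flip (time reversal), additive Gaussian noise at a target SNR (15 dB),
permutation of contiguous chunks (20), and smooth time warping (cubic
spline through knot speeds ~ N(1, 0.2²) at 4 interior knots, integrated
into a monotone time map).  Specs name one or two operators applied
sequentially; order matters.  `timewarp+scale` is the default composition
(temporal plus amplitude variation).  Operator contracts under test:
negation and flipping are involutions, permutation and flipping preserve
the value multiset, time warping at sd 0 is the identity, achieved SNR is
within 0.5 dB of target at L = 2560.

## Preprocessing

Fixed order: polyphase rational resampling to 256 Hz (anti-aliased;
700 → 256 is the exact ratio 64/175) → zero-phase high-pass at 0.8 Hz
(mean removal, then Chebyshev type-II, order 4, 40 dB stop-band, stop edge
at half the pass-band, `sosfiltfilt`) → per-subject z-score → amplitude
clip at ±10 SD (sensor saturation) → non-overlapping windows (10 s or 5 s)
with uniform condition labels — windows spanning a label change are
discarded as ambiguous supervision → optional SMOTE balancing.

SMOTE oversamples every class to the majority count by convex combinations
s_i + u(s_j − s_i), u ~ U(0, 1), of a minority row and one of its k = 5
nearest minority neighbours (Euclidean; k shrinks to class size − 1 for
tiny classes).  Original rows are preserved.  Balancing a 242/88/48 corpus
yields 726 segments.  By default balancing runs before splitting,
reproducing the published protocol; `--smote-train-only` /
`EcgPreprocessor(smote=False)` plus per-fold balancing is the leakage-safe
alternative.

## Baselines

**R-peak detection** is Pan–Tompkins-style: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving integration, adaptive-threshold peak picking with a
200 ms refractory period, and refinement of each peak to the local maximum
of the squared band-passed signal.  Against the generator's ground truth it
recovers 60/60 beats with ≤ 20 ms timing error on a clean 60 bpm record.

**HRV features** (from the RR series in ms): HR = 60000/AVNN,
AVNN = mean(RR), SDNN = sd(RR), RMSSD = √mean(ΔRR²), pNN50 = fraction of
|ΔRR| > 50 ms, and Welch band powers of the 4 Hz-interpolated, detrended RR
series over VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz, with TP their
sum (conserved by construction).  Frequency powers require a ≥ 30 s span
and are reported as missing (NaN), never zero, below it — note this means
5–10 s windows carry only time-domain features into the SVM.  The SVM is
RBF, C = 1, preceded by train-fold-only imputation and standardization.

## Evaluation protocol

"10 folds" is Monte-Carlo cross-validation: ten independent random splits
at a fixed test-train ratio (a ratio sweep from 10-90 to 90-10 is
incompatible with partition k-fold).  A ratio of "70-30" means 70% test,
30% train.  Folds whose training half misses a class are redrawn (max 5).
Accuracy is aggregated as mean ± sd over fold accuracies, not pooled
predictions; confusion matrices are pooled.  Splits are segment-level by
default — matching the published protocol, which implies within-subject
leakage across splits — and a `subject_wise=True` mode keeps each
subject's segments on one side.  The SSL pipeline pretrains once on the
full corpus (standard for label-free pretext tasks) and fine-tunes per
fold.  Two ablation drivers mirror the published designs: a ratio sweep
per single augmentation with a no-augmentation control column, and an
ordered 6 × 6 augmentation-pair grid at one split (diagonal = single).

## Synthetic data

The generator emulates the structure of small wearable stress studies, not
cardiac electrophysiology.  Each subject has a baseline heart rate
(U(60, 80) bpm), a per-condition HR shift (+10 bpm per stress level), a
per-condition RR-jitter SD (50 → 30 → 15 ms for levels 0/1/2 — stress
raises HR and suppresses HRV), an amplitude gain, baseline wander (two
sub-0.5 Hz sinusoids, amplitude ~0.15), white sensor noise (sd ~0.05), and
an optional hard saturation ceiling.  Beats are a P-Q-R-S-T sum of five
Gaussians placed at RR onsets, with RR = 60/HR plus AR(1) jitter
(coefficient 0.8).  Ground-truth R-peak times ride along in record
metadata as the oracle for detector accuracy.  What it does **not**
emulate: real QRS morphology variation, ectopy/arrhythmia, electrode
artifacts, respiratory sinus arrhythmia, or between-condition differences
more subtle than programmed HR/HRV shifts.  Tests passing on this data
show the machinery is correct and that the pipeline recovers programmed
effects; they do not certify accuracy on real ECG.

## Study-scale experiment

`ecgssl.experiments.pretraining_benefit` is the package's headline
contrast, sized for a single CPU core: 6 subjects × three 110 s condition
blocks at 256 Hz, 5 s windows (~396 segments of L = 1280), the standard 20
upstream epochs, and 40 downstream epochs (scaled down from the full-size
150-250; this affects both arms equally).  An earlier scale-down of the
upstream task to 12 epochs (~150 optimizer steps) left the pretext task
undertrained and its benefit within split noise, so the full upstream
count is kept.  Both arms share data, split (70-30 test-train, the
scarce-label regime), architecture and hyperparameters, differing only in
encoder initialization.  Over seeds 1–5 the measured gains
(SSL − supervised) were −1.8, +2.9, +1.4, +1.1, +2.2 percentage points
(median +1.4), and an independent seed base (42–46) gave the same median:
positive but modest, as expected for a corpus whose class structure is
already largely recoverable from 30% supervision.

## Numerical choices and edge cases

- float32 network compute; float64 everywhere precision is asserted
  (NT-Xent, cosine, HRV, filters).
- Ties in argmax predictions break toward the lowest class index.
- Non-overlapping windows by default (overlap not implemented; the
  windowing function is the single place it would go).
- `resample_record` warns on upsampling; rejects non-positive rates.
- Zero-variance records are rejected at z-scoring with the subject named.
- Single-class SMOTE input is returned unchanged with a warning; a
  1-member class is an error.
- Degenerate `permute(n_segments=1)` is an explicit identity.
- Max-pool drops a trailing remainder shorter than the pool width;
  encoder input lengths that pool below one position are rejected with
  the offending block named.

## Known limitations

- The pretraining benefit on synthetic data is small (see above); the
  generator's class structure is largely linearly recoverable from
  morphology, which limits how much a pretext task can add.
- SMOTE-before-split reproduces the published protocol but leaks synthetic
  neighbours across folds; use the leakage-safe mode for honest estimates
  on real data.
- Segment-level splits share subjects between train and test; subject-wise
  mode exists but changes the problem difficulty materially.
- The NumPy training stack is single-threaded BLAS-bound; full-size runs
  (thousands of 10 s segments, hundreds of epochs) are feasible but slow.
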