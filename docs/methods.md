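# Methods

`ecgfusion` re-implements a heartbeat-classification method that fuses
the magnitude and phase of the continuous wavelet transform (CWT) of
single-lead ECG beats in a convolutional network. This note documents
the models, the parameters that matter, the synthetic study conditions,
and the numerical choices the implementation makes where the design was
genuinely open.

## Signal model and preprocessing

The input is a single-channel ECG voltage trace (modified lead II in
the MIT-BIH layout) with beat annotations. The preprocessing chain is:

1. **Band-pass denoising, 5–20 Hz.** Realized as an order-3 Butterworth
   filter applied forward–backward (`sosfiltfilt`), i.e. zero phase, so
   R-peak positions are not displaced. Only the band edges are
   prescribed by the method; the order and the zero-phase realization
   are implementation choices.
2. **Resampling to 250 Hz** by polyphase filtering with anti-aliasing;
   the output length is `round(n * fs_out / fs_in)` (the polyphase
   result is trimmed/edge-padded by at most one sample to meet this
   contract). Annotation indices are rescaled by `fs_out / fs_in` and
   rounded to nearest.
3. **R-peak detection**, a transparent Pan–Tompkins-style detector:
   derivative → squaring → 150 ms moving-window integration → candidate
   peaks at ≥200 ms spacing → adaptive threshold at 0.5× the running
   median (last 8) of recent accepted peak heights, applied on the
   amplitude (square-root of the integrated energy) scale → snap to the
   local maximum of the filtered signal within ±100 ms → a
   local-dominance rule (a peak must be the signal maximum within its
   own ±200 ms neighborhood) plus a final refractory pass keeping the
   larger of two close peaks. The amplitude-scale threshold matters:
   wide-QRS ventricular beats carry ~4× less squared-derivative energy
   than normal beats (and the 5–20 Hz filter attenuates them further),
   so an energy-scale threshold at 0.5 silently drops the V class.
4. **Segmentation** into 180-sample windows centered on each detected
   peak (90 before, 90 after); windows crossing a record boundary are
   discarded and counted.
5. **Per-beat min–max normalization** to [0, 1]; constant windows are
   degenerate and skipped with a warning. A detected beat takes the
   class of the nearest annotation within 75 ms; unmatched detections
   are dropped.

## CWT features

The CWT is the L1-normalized inner product
`W(tau, a) = (1/a) * sum_t x[t] conj(Psi((t - tau)/a))` with the
complex Morlet mother wavelet
`Psi(t) = (2 pi sigma^2)^{-1/2} exp(-t^2/(2 sigma^2)) exp(i omega0 t)`,
`sigma = n / omega0`. Defaults: `n = 6` cycles (prescribed) and
`omega0 = 6` rad/sample (the classical admissibility-safe Morlet
carrier; the method fixes `n` but not `omega0`). The L1 (1/a)
normalization is retained exactly as the method defines it, although L2
(1/sqrt(a)) is more common elsewhere.

Per scale the sum is evaluated as an FFT convolution with the
conjugated, time-reversed scaled wavelet, truncated at ±6·sigma·a
samples. At 6 sigma the Gaussian envelope is ~1.5e-8 of its peak, which
keeps the convolution within 1e-6 relative error of the untruncated
Riemann sum (the package carries a direct O(N²) evaluation,
`cwt_direct`, as an oracle; the equivalence is asserted in the tests on
interior samples). Edges are zero-padded by default; a circular mode
exists and is exactly shift-covariant.

The scale grid is 180 log-spaced scales whose Morlet pseudo-frequencies
`f = omega0 * fs / (2 pi a)` span 1 Hz to 0.45·fs, so a 180-sample beat
yields a square 180×180 matrix before resizing (minimizing resize
distortion). The ridge of a sinusoid's scalogram sits at
`a = omega0 * fs / (2 pi f)`; the tests check this at 5/10/20/40 Hz to
within one grid step.

**Scalogram** `S = |W|²` is log-compressed (`log1p`) and min–max mapped
per image to [0, 255] (its dynamic range is huge and beat-relative
contrast is what matters). **Phasogram** `P = angle(W)` in (−π, π]
(zero coefficients get phase 0) is mapped by the fixed linear transform
(−π, π] → [0, 255] with no per-image scaling, so phase values are
comparable across beats. Both are bilinearly resized to 224×224 and
stored as single-channel 8-bit images.

## Network and fusion strategies

The classifier is a customized AlexNet for 224×224×1 inputs: Rescaling
(÷255) → Conv1 11×11/stride 4/valid/96 → BN → MaxPool 3×3/2 → Conv2
5×5/same/256 → BN → MaxPool → Conv3 3×3/same/384 → BN → Conv4
3×3/same/384 → BN → Conv5 3×3/same/256 → BN → MaxPool → Flatten →
FC 4096 → Dropout 0.5 → FC 4096 → Dropout 0.5 → FC 5 softmax, with
ReLU after each BN/dense. Kernel sizes, strides and padding are not
free choices: they are uniquely recovered from the published output
shapes and parameter counts ((224−11)/4+1 = 54; 11·11·96+96 = 11,712;
5·5·96·256+256 = 614,656; batch-norm 4 parameters/channel of which the
2 running statistics are non-trainable, 2·(96+256+384+384+256)=2,752).
The full-size model totals 46,749,765 parameters.

Fusion variants over the scalogram/phasogram pair:

* **S1/S2** — base model on one modality;
* **S3** — early fusion, 224×224×2 input (only Conv1 grows: +11,616);
* **S4** — two single-modality branches through BN4, channel-axis
  concatenation (12×12×768), shared tail from Conv5 (total 50,477,957);
* **S5** — branches through Flatten, feature concatenation (12,800),
  tail from FC6 (total 76,693,637);
* **S6** — branches through FC6 with that layer's dropout removed,
  concatenation (8,192), tail from FC7 (total 93,474,949);
* **S7a–h** — late fusion of the S1 and S2 class-probability outputs:
  element-wise mean (a) or a meta-classifier on the concatenated
  10-dimensional probability vector (order: 5 scalogram then 5
  phasogram probabilities) — linear SVM C=1, decision tree, random
  forest with 500 trees, logistic regression C=1, Gaussian naive Bayes,
  kNN k=11, ridge with L2 strength 0.5. Ties break to the lowest class
  index everywhere.

The layer stack is implemented in-package on numpy (explicit
forward/backward per layer, im2col convolutions, Adam) — a small
transparent engine sufficient for these exact topologies. Weight
initialization is He-uniform, seed-controlled.

Training follows the prescribed schedule: Adam with learning rate 1e-4
(default moments), batch size 32, at most 30 epochs, early stopping
with 5 epochs of patience. The monitored quantity is the loss on a 10%
stratified holdout of the training split (the method names the patience
but not the monitor), and the best-validation weights are restored.
Dropout is disabled at inference. Batch-norm running statistics use
momentum 0.6 so they track within ~10 batches; with few batches per
epoch (the small-data regime this package trains in) a slow momentum
makes early validation scores meaningless and triggers spurious early
stops, while with many batches per epoch the choice is uncritical.

Grad-CAM is available for any convolutional layer: the gradient of the
target-class logit is captured at that layer, channel-mean gradients
weight the activations, and the rectified sum is bilinearly upsampled
and max-normalized to [0, 1].

## Evaluation metrics

Per class, one-vs-rest: precision TP/(TP+FP), sensitivity TP/(TP+FN),
specificity TN/(TN+FP), F1 = harmonic mean of precision and
sensitivity; 0/0 is reported as 0 with a warning. Aggregates are
support-weighted; weighted sensitivity equals overall accuracy exactly
(asserted). The aggregate F1 is the harmonic mean of the weighted
precision and weighted sensitivity — this is the convention the
reference result tables follow, and it differs in the second decimal
from the support-weighted mean of per-class F1 (also available via
`f1_mode="weighted"`). The multiclass MCC is the Gorodkin R_K statistic
over the full K×K matrix, which reproduces the reference summary values
to 4 decimals; a support-weighted binary variant is provided behind a
flag for comparison. Percentages are rounded to 2 decimals.

The embedded reference confusion matrices (`ecgfusion.reference`) carry
two caveats documented there: the printed source tables mix
round-half-up with truncation in the last digit (tolerance 0.015 in the
regression tests), and one printed per-class cell (S1, class V, F1) is
internally inconsistent with its own printed precision/sensitivity pair
and is excluded from regression.

## Synthetic study conditions

The generator renders beats as sums of Gaussian bumps (P, Q, R, S, T)
— the standard dynamical-ECG simplification — with class recipes over
the five AAMI groups: N full PQRST; S with the P wave merged into a
slightly narrowed QRS arriving on a 25%-shortened RR; V with no P,
QRS width ×2 and inverted T; F the pointwise mean of the N and V
renders; Q with a 4-sample rectangular pacing spike 60 ms before R.
Per-beat amplitude (±5%) and time-stretch (±3%) jitter give
within-class variability while keeping a nearest-centroid classifier on
raw noiseless beats ≥95% accurate — the floor that makes end-to-end
accuracy checks meaningful. Records concatenate beats at RR ~
Normal(0.8 s, 0.05 s) truncated at 0.3 s, with white noise (default
sd 0.02 of the unit R amplitude), a 0.3 Hz sinusoidal baseline wander
(default amplitude 0.1), and exact R-peak annotations. The default
class mix (0.60, 0.10, 0.15, 0.05, 0.10 for N, S, V, F, Q) is
imbalanced in the same ordering as the clinical corpus but far less
extreme, so a few hundred beats still contain enough minority-class
examples to train on.

What the generator does **not** emulate: autonomic heart-rate
variability, multi-lead projections, electrode artifacts,
within-record morphology drift, and the 80:1 clinical class imbalance.
Passing synthetic tests therefore demonstrates that the pipeline is
internally correct and that fusion behaves as designed on separable
data; it does not certify clinical-grade performance.

## Scaled-down end-to-end conditions

The full-size network (224×224 inputs, 46.7M parameters) is built and
audited exactly, but training end to end uses a reduced configuration
of the same topology: 500 synthetic beats, 96×96 images, width scale
0.25 (channel and dense widths at a quarter), 15 epochs. 96 is the
smallest input size for which the three valid 3×3/2 poolings stay
consistent (96 → 22 → 10 → 4 → 1). Under these conditions the
single-modality models reach ≥97% test accuracy, smoothed training
loss decreases monotonically until convergence (below 10% of the
initial loss; at the converged floor minibatch fluctuation dominates),
and the fused strategies (S5, S7a, S7d) match or exceed the best
single modality.

## Known limitations

* The 0.72 s beat is short relative to the largest wavelet scales, so
  edge effects at low pseudo-frequencies are unavoidable; properties
  are asserted on interior samples, and images inherit the edge zones.
* The QRS detector is tuned on the synthetic morphology contract, not
  benchmarked against reference detectors on clinical records.
* The WFDB reader covers the single-segment, format 212/16 layout the
  target databases use; exotic header features (skew, multi-frequency
  frames) are out of scope.
* Late-fusion combiners are trained on the base models' predictions
  over the training split. Out-of-fold retraining of the deep models
  per fold would be cleaner against leakage but is disproportionate
  here; `cross_validation_folds` supports callers who want it.
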