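# Methods

## Problem and model

`ctiqa` predicts a perceptual quality score for a single grayscale CT slice
without a reference image.  The predictor is a hybrid of three parts fitted
in two phases:

1. **CNN trunk** `F` — a stack of fused inverted-bottleneck convolution
   blocks with squeeze-excitation, ending in a 1x1 widening convolution and
   global average pooling.  During phase 1 a single linear head on the pooled
   features regresses the quality score of *source-domain* images (natural-
   image-like textures with MOS-style annotations); the trained trunk
   parameters are the transferable knowledge.
2. **Connector** `C` — one fully connected layer from the pooled feature
   vector to `grid_side^2` values, a ReLU, and a row-major reshape to a
   single-channel `grid_side x grid_side` map.  It is the bridge that lets
   transformer stages consume CNN evidence.
3. **Windowed transformer** `S` — SwinV2-flavoured stages (window attention
   with scaled cosine similarity and a learnable per-head temperature,
   residual post-normalization, relative-position bias, cyclic window
   shifting on alternate blocks, 2x2 patch merging between stages).  The
   feed-forward sublayer of every block is replaced by **MK-CA**: the window
   tokens are transformed in parallel by an MLP path `u` and a KAN path `v`
   (a spline-parameterized Kolmogorov-Arnold layer applied per eta-head
   channel slice), fused by two cross-attentions — queries from `u` against
   keys/values from `v` and vice versa — whose outputs are summed.  A final
   layer norm, token mean-pool and linear unit produce the score.

Phase 2 assembles trunk + fresh connector + fresh transformer and fine-tunes
on the *target-domain* (CT-like) corpus under the same optimizer family and
loss; optionally the trunk stays frozen.  The loss in both phases is the L2
sum over the minibatch; Adam with cosine-annealed learning rate does the
optimization.  Scores can be clipped to the active range at inference.

### KAN layer

Each edge (i, j) carries `w_b[i,j] * silu(u_i)` plus a B-spline expansion
with `G + k` learnable coefficients on a uniform knot grid over `[-1, 1]`
(`G = 5` intervals, order `k = 3`, knots extended k-fold past the ends; the
basis is evaluated by the Cox-de Boor recursion).  Initialization is
near-linear: base weights ~ N(0, 1/sqrt(in_dim)), spline coefficients ~
N(0, 0.1), so splines learn residual shape on top of a smooth skeleton.
No adaptive grid refinement is performed.  Inputs outside the grid fall back
to the silu base path alone (their spline basis is zero); with post-norm
token magnitudes this happens regularly and is accepted — the spline then
acts on the central portion of the activation distribution.

### Architectural choices the source material leaves open

* **Attention scope of MK-CA** — the cross-attentions operate within each
  attention window (the same token partition as the window-attention
  sublayer), keeping cost linear in image size.
* **Projections** — each cross-attention direction has its own learned
  Q/K/V/output projections; the two directions share nothing.
* **eta (KAN heads)** — applies only to the KAN path's channel split
  (default 16); the MLP path and both cross-attentions use the block's
  attention head count.
* **Position bias** — a learned relative-position-bias table per window
  displacement (the continuous log-spaced bias of SwinV2 is unnecessary at
  desk-scale grid sizes).
* **Initialization scale** — all transformer projections use sd = 1/sqrt(n_in).
  This matters structurally here: with residual *post*-normalization every
  sublayer output is renormalized to unit variance before being added, so
  an undersized projection does not merely start slow — it permanently
  dilutes the input-dependent signal relative to the additive stream, and
  fine-tuning collapses to a constant predictor.  (Diagnosed on the desk-
  scale preset; the 1/sqrt(n_in) scale removes the failure.)
* **Trunk normalization** — per-pixel channel normalization with eps = 1e-3.
  The first stage expands a single input channel, so channel vectors are
  narrow and nearly constant; a conventional 1e-5 eps produces exploding
  1/sqrt(var) gradients at initialization (observed: gradient norms ~1e11)
  that poison Adam's second-moment estimates.

## Synthetic corpora

The generator emulates the *structure* of the two data sources the transfer
recipe needs, not their content.

**Source domain** ("natural" images): band-limited random textures — white
noise shaped by a per-image 1/f^alpha spectrum, alpha ~ U(1, 2.2) — degraded
combinatorially: every pristine texture x every distortion type x every
severity level, with a score per record.  Distortion *types* are 5
parametric kinds x 5 severity-profile multipliers (0.6-1.4), echoing how
photographic IQA benchmarks enumerate many named distortions drawn from a
few families; 81 pristine x 25 types x 5 levels reproduces the benchmark's
10,125-record cardinality.

**Target domain** (CT-like slices): elliptical body phantoms with 4-8
internal structures of varying attenuation, smoothed and lightly textured.
Each slice is degraded by a mixture of 1-3 distinct kinds applied in a fixed
physical order (tone scale, brightness, resolution loss, blockiness, then
noise) so later stages never erase the perceptual trace of earlier ones —
mirroring a CT chain where quantum noise arrives after system blur.  The
slice score is the mean of the per-kind severity-linear scores; a target
score bin is drawn round-robin across the four unit bins of the 0-4 scale
before severities are drawn, so every bin is populated deterministically
once n >= 4 (the corpus contract asks for coverage at n >= 40).

**Distortion bank and calibration.**  Kinds: additive Gaussian noise,
Gaussian blur (reflective boundaries, mean-exact), nonlinear contrast
compression (gamma tone curve), brightness shift with clipping, and
blockiness (blend toward the 8x8 block-mean image; its MSE grows as the
square of the blend weight, making severity monotonicity structural).  Two
design constraints shaped the bank:

1. *Observability under the training protocol.*  Inputs are min-max
   normalized before the network sees them, so a purely affine intensity
   change is invisible to any model; the contrast kind is therefore a
   nonlinear tone curve and the brightness shift is large enough that
   clipping saturates structure.  A score component that the preprocessing
   provably erases could never be regressed, which would misrepresent the
   emulated task (real radiologist scores *are* predictable from normalized
   slices).
2. *Cross-kind perceptual calibration.*  Severity parameters are scaled so
   the RMS departure from pristine is comparable across kinds at equal
   level (within the physical ceilings of blur/blockiness, which cannot
   exceed the image's high-frequency energy).  Equal level then means a
   similar quality drop whichever kind produced it, as in graded-distortion
   benchmarks.

Ground-truth scores are linear in severity (4 at pristine, 0 at maximum
severity) with optional Gaussian jitter (sd 0.1 by default; the test
fixtures use 0 so rank recovery is exactly checkable).  Natural-image MOS
values on the 1-5 scale are mapped affinely onto 0-4.

**What the generator does not emulate:** dose/physics-accurate CT noise
(streaks, beam hardening, photon statistics), anatomical realism, DICOM
semantics, inter-rater variability structure, and the content diversity of
photographic corpora.  Passing the end-to-end tests therefore shows the
*procedure* works — the architecture can learn severity cues and transfer
between visually distinct domains — not that it reaches clinical-grade
accuracy on real CT.

## Training defaults

Paper-scale preset: Adam, lr 1e-4, cosine annealing to ~0, 100 epochs,
minibatch 4, L2 sum loss, 512x512 inputs — retained as configuration but
not exercised by the test-suite.

Desk-scale preset (the fixture the tests run): 64x64 inputs, trunk feature
width 32, connector grid 16x16, two transformer stages of two blocks at 32
and 64 channels, window 4, eta 16.  Phase 1: 40 epochs, lr 3e-3 on a
60-record texture corpus.  Phase 2: 60 epochs, lr 1e-3 on a 200-slice
phantom corpus (70/15/15 split), dihedral flip/rotation augmentation, and
best-validation-s checkpoint selection (both behind config flags, off by
default at paper scale).  Inference in the desk-scale preset averages each
slice's prediction over its 8 dihedral orientation variants (quality is
orientation-invariant, so the average only removes prediction variance).
The higher learning rates compensate for the short schedules; sizes were
chosen so a full two-phase run plus evaluation completes in minutes on one
CPU core.

Numerical notes: gradients come from reverse-mode automatic differentiation
over the pure-numpy forward pass; optimization is deterministic given the
seed (data order, init and augmentation all flow from it), so identical
seeds give hash-identical checkpoints.  Gradient clipping exists as a knob
but is off by default.  The L2 *sum* reduction follows the loss as defined;
the mean reduction is offered because the sum couples the effective step
size to the minibatch size.

## Evaluation protocol

Pearson r, Spearman rho (average ranks under ties — the classical
rank-difference formula assumes distinct ranks; with ties it is equivalent
to Pearson on midranks), Kendall tau-b with tie terms, the aggregate
s = |r| + |rho| + |tau| in [0, 3], and R^2 against the reference.
Correlations on constant vectors raise an explicit error instead of
returning zero, since silent zeros would corrupt s.  Range-wise analysis
groups reference scores into [0,1), [1,2), [2,3), [3,4] (half-open bins,
top bin closed — the only partition without double counting) and reports
per-group counts, group accuracy and residual summaries.  Scan-level scores
are the arithmetic mean of slice scores.  Residuals (predicted - reference)
are exported as CSV for external paired significance testing.

## Known limitations

* The KAN spline grid is static; tokens outside [-1, 1] use only the silu
  base path.
* Desk-scale held-out splits are small (tens of slices), so split metrics
  carry visible sampling noise; the range-wise accuracies on such splits are
  indicative only.
* The blur and blockiness kinds have physical ceilings on their achievable
  RMS departure, so severity calibration across kinds is approximate at the
  highest levels.
* No batch-level normalization or dropout; regularization comes only from
  architecture size, augmentation and early selection.
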