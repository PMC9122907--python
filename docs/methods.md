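# Methods

This note documents the models, conventions and numerical choices behind
`fazseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## The segmentation model family

All networks are fully convolutional encoder–decoder (U-Net style)
architectures for binary segmentation of 2-D en-face OCTA images. The
family covers:

* **Unet** — the conventional baseline: four resolution levels with
  channel doubling (64 → 512), a widened bottleneck (1024), transposed
  convolutions and concatenating skip connections;
* **Unet_AB** — the same with channel-attention blocks;
* **Upsampling / Add variants** — transposed convolutions replaced by
  parameter-free 2× nearest-neighbour upsampling and/or concatenation
  replaced by elementwise addition;
* **fixed-width variants** — every convolution carries the same number
  of filters (128 or 64);
* **LWBNA_Unet** — the lightweight bottleneck-narrowing-with-attention
  network: fixed width 128, upsampling, additive skips, plus a
  channel-narrowing midblock at the bottleneck.

A *convolutional block* is a 3×3 same-padding convolution (with bias),
batch normalization, then ReLU; each resolution level applies two such
blocks. 2×2 max pooling descends a level; a dropout layer (default rate
0.2, zero parameters) follows every pooling and upsampling step.

The *attention block* rescales channels by data-dependent weights:
global average pooling over space gives a channel vector, one dense
C → C map with bias produces pre-activations, and the weight per channel
is `logistic(relu(·))`. Because the logistic is applied to a rectified
value, every attention weight lies in **[0.5, 1)**: low-priority
channels are damped by at most a factor of two rather than deleted, so
later layers can still revise their importance. (In float32 the upper
bound can round to 1.0 under extreme saturation; it is never exceeded.)

The *narrowing midblock* sits after the two bottleneck conv blocks of
the fixed-width add-skip layout: one plain 128→128 convolution, then
channel-halving convolutions 128→64→32→16 (each followed by attention),
a restoring convolution 16→128, an additive skip connection from the
midblock input, and a final attention block. The narrowing/restore
convolutions use bias + ReLU without batch normalization, the same
convention as the transposed convolutions of the conventional family.
The floor (16 by default) is configurable down to 8 or up to 64 for
ablation studies; too aggressive narrowing (8) is expected to suppress
high-level features needed for reconstruction — the device behaves like
a channel whose width gates which features reach the decoder.

### Reconstructed details and their calibration

The published description of this family leaves several layout details
implicit. They were reconstructed so that every preset reproduces its
published total parameter count *exactly* (the machine totals are the
only quantitative fingerprint of the architecture, so they act as the
calibration oracle):

* fixed-width totals follow P(F) = 162·F² + 153·F + 3, which pins the
  block inventory (18 conv blocks, 9 attention blocks) and, notably, a
  **3×3 output convolution to three sigmoid channels** (27F + 3): the
  training masks were evidently handled as RGB images. `predict()`
  averages the three sigmoid channels into one probability map.
* decoder conv widths are **half the incoming skip width**, floored at
  the base width (doubling models: 256, 128, 64, 64);
* transposed convolutions are 3×3, stride 2, mapped to the skip width,
  with bias but no batch normalization;
* additive-skip models keep the bottleneck at the deepest encoder width;
  concatenating models widen it ×2;
* in add models the skip is added directly after upsampling (the only
  channel-consistent order);
* attention placement: after every encoder and decoder level; the
  widened bottleneck carries attention only in the transposed-conv
  family; the fixed-width family carries one extra attention block
  before the output head. These placements are encoded as explicit
  config flags (`att_bottleneck`, `att_final`).

Parameter counting follows the Keras convention: batch-normalization
moving statistics (2 of the 4 per-channel parameters) are non-trainable
but included in the total.

## Training protocol

Adam with α = 1e-4, β₁ = 0.9, **β₂ = 0.99** (the published value; the
conventional 0.999 is selectable), ε = 1e-7; batch size 5 with per-epoch
shuffling; He-normal initialization; soft dice loss (or MSE). Early
stopping monitors the validation loss with min_delta = 1e-8 and
patience = 40, restoring the best weights. The soft dice loss for one
sample is `1 − (2·Σ(g·p) + s) / (Σg + Σp + s)` with smoothing s = 1e-6;
on hard predictions it reduces to 1 − D. Masks are replicated to the
three output channels; the per-epoch dice metric uses predictions
hardened at 0.5, matching the test-time pipeline.

Every source of randomness (weight init, shuffling, dropout) derives
from integer seeds, so a run is bit-reproducible on one machine.
Replicate training uses per-repeat seeds `base + index`.

The engine itself is NumPy: convolutions are evaluated as per-kernel-tap
GEMMs against row-contiguous blocks of the padded input (no im2col
buffer), with exact adjoint backward passes verified in the test suite
against numeric differentiation and adjoint identities.

## FAZ morphometry

The measurement pipeline hardens the probability map at 0.5 (`>=`
convention), labels 8-connected foreground regions (4-connected
background), traces each region's outer boundary with Moore
neighbourhood following (Jacob's stopping criterion), selects the
contour enclosing the largest area (first in scan order on ties), and
reports, at the physical scale (default 3 mm image width):

* **area** A — shoelace area of the boundary-pixel-centre polygon
  (OpenCV-compatible) or, alternatively, the pixel count of the filled
  region. The polygon convention undercounts the pixel area by roughly
  half the perimeter (a relative gap ≈ 1/r for compact regions of
  radius r px); the two agree within 5% only for radii ≳ 22 px. For
  comparisons against continuous ground truth (e.g. Bland–Altman of
  predicted vs generating-polygon areas at small image sizes) the
  pixel-count convention is the right estimator and is the one used.
* **perimeter** P — by default the Vossepoel–Smeulders-weighted chain
  length (0.948 per axial step, 1.340 per diagonal step), which is a
  nearly unbiased estimate of the underlying smooth boundary length;
  the raw polyline length is available as `perimeter="chain"`. Segments
  longer than one pixel step (analytic polygons) are always measured
  exactly, so an axis-aligned square contour of side s yields P = 4s
  and CI = π/4 under either convention, while a rasterized disc yields
  CI ≈ 0.99 under the default and ≈ 0.90 under the raw chain length
  (the jagged chain overstates a smooth perimeter by ~5%, which the
  squared term in CI doubles).
* **circularity** CI = 4πA/P², 1 for a perfect circle. Discretization
  can push CI marginally above 1; a small allowance is accepted.

An image with no foreground region yields an explicitly flagged
"no FAZ" result, never a silent zero.

## Agreement and discrimination statistics

Bland–Altman: differences d = a − b give bias = mean(d), sample SD,
limits of agreement bias ± 1.96·SD, and a 95% CI of the bias
(± 1.96·SD/√n). Pearson's r is the standard product-moment coefficient.

Group discrimination from a single FAZ parameter uses univariate
logistic regression fitted by iteratively reweighted least squares
(tolerance 1e-8, ≤ 100 iterations; statsmodels GLM provides the IRLS).
Since the logistic score is monotone in the feature, the ROC is computed
in the raw-feature orientation, making the AUC identical to the
Mann–Whitney rank AUC (ties receive half credit); a label flip maps AUC
to 1 − AUC and an inverse association appears as AUC < 0.5. The AUC
standard error follows Hanley & McNeil — a modelling choice, as is the
1.96 multiplier in the limits of agreement.

## Synthetic OCTA generator

The generator emulates the qualitative structure of en-face scans of
the superficial vascular plexus: a dark, roughly central avascular
region with an irregular star-convex boundary
r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ)) rasterized at a jittered centre;
bright persistent-random-walk vessel strokes clipped to zero inside the
FAZ over low-intensity speckle; then, in order, capillary-dropout
ellipses, salt-and-pepper flips, horizontal scan-line bands, and
Gaussian blur. The continuous generating polygon provides analytic
ground truth for area and perimeter. Per-sample substreams come from a
counter-based generator keyed by `base_seed + index`, so datasets are
byte-reproducible and O(n).

Default magnitudes follow reported normal-eye FAZ morphometry on a 3 mm
field: generating radii average ≈ 0.30 mm (area mode ≈ 0.28 mm², range
≈ 0.06–0.5 mm²), six boundary harmonics with amplitude scale 0.10.
"Clear" and "noisy" strata mimic visually clear scans versus heavily
degraded ones.

What the generator does **not** model: OCT speckle statistics and
decorrelation noise, realistic capillary topology (the walks do not
form a perfused network), projection artifacts from deeper plexuses,
pathology-specific boundary changes, or inter-grader ambiguity in the
ground truth. Passing tests on this data therefore demonstrate that the
implementation is correct and that the pipeline is internally
consistent — not that clinical-grade accuracy would be reached on real
scans.

## Scaled-down experiment sizes

The end-to-end experiments run at reduced scale, chosen once as the
package's standard check sizes:

* **segmentation accuracy / area agreement** — the LWBNA_Unet preset at
  96×96 inputs, 60 training / 20 validation clear synthetic samples,
  up to 15 epochs of the standard protocol (Adam, α = 1e-4, batch 5,
  dice loss), evaluated on 20 held-out clear samples (mean dice and the
  Bland–Altman bias of pixel-count areas against analytic truth).
* **training reproducibility** — three replicate trainings with
  distinct seeds of a narrow family member (fixed width 32, narrowing
  floor 8) at 64×64 (60/20 train/val, 10 test), 12 epochs at step size
  1e-3, comparing the spread of mean test dice. The narrow member and
  the larger step are chosen so that every replicate reaches its
  convergence plateau inside the check's runtime budget — replicate
  agreement is meaningful only between converged runs, and at α = 1e-4
  a ~150-update schedule sits mid-take-off, where seed-to-seed spread
  reflects take-off timing rather than the converged behaviour the
  claim concerns.
* **cohort discrimination** — two cohorts of 100 synthetic samples
  whose generating radii are normal with means one SD apart; measured
  areas feed the logistic ROC. The expected AUC for two equal-variance
  normals one SD apart is Φ(1/√2) ≈ 0.76.

## Known limitations

* The engine is CPU-bound NumPy; it is meant for correctness and
  moderate-scale experiments, not large-scale training.
* Batch normalization uses per-batch statistics with ε = 1e-3 and
  moving-average momentum 0.9. The Keras-style 0.99 makes inference
  statistics lag roughly a hundred updates behind the network, which in
  short schedules (a few hundred updates) can leave inference-mode
  predictions far behind training-mode ones; 0.9 tracks fast enough for
  the schedules used here. Very small batches still give noisy
  statistics.
* Contour tracing returns one outer contour per region; nested
  foreground inside holes is not re-entered (adequate for FAZ-like
  masks, not for arbitrary topology).
* The attention upper bound 1.0 is open in exact arithmetic but can be
  attained in float32 under extreme saturation.
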