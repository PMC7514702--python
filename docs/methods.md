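# Methods

## Problem and model

Genome-wide in situ hybridization (ISH) surveys image the spatial
expression pattern of each gene in brain tissue. Associating those
patterns with functional gene-ontology (GO) categories requires a compact
per-gene feature vector that preserves both local texture and global
location of expression while tolerating small translations between
sections. This package learns such representations with a convolutional
denoising autoencoder (CDAE) and evaluates them by per-category
L2-regularized logistic regression under a balanced 5-fold protocol.

The CDAE is a mirror-symmetric encoder/decoder built from four layer
types:

- **conv / deconv** — stride-1 cross-correlations with odd filters
  (default 3x3), zero padding of `filter_size // 2` so spatial dimensions
  are preserved, one bias per feature map, ReLU activations except the
  final decoder layer, which uses tanh. Deconvolutions are ordinary
  convolutions applied to the unpooled maps; their weights are learned
  independently of the encoder (tied weights are deliberately not used —
  the reference architecture lists distinct decoder layers).
- **maxpool** — 2x2 disjoint maximum, halving each spatial dimension.
- **unpool** — value-duplicating 2x2 upsampling: every source cell fills
  its 2x2 output block with the same value. No pooling switches are
  recorded, so unpooling needs no side information from the encoder.

The size-preserving convolution choice is forced by the published shape
arithmetic: a 960x480 input through four pooling stages must reach a
60x30 single-map bottleneck (1800 features); any valid-convolution
reading breaks that count.

The reference ("best-AUC") architecture stacks four blocks of two
4-filter 3x3 convolutions plus pooling, then a 4-filter and a single-filter
bottleneck convolution; the decoder mirrors it with four unpool +
two-deconvolution blocks and a final single-filter tanh deconvolution.
After training, the decoder is removed and the flattened bottleneck
activations are the per-gene representation.

## Training

Each presentation of an image applies, in order: normalization,
fresh masking corruption (exactly `round(rate * H * W)` pixels set to
zero, drawn uniformly without replacement, redrawn every presentation so
the network rarely sees the same input twice), a full forward pass, and a
plain SGD step on the mean-squared error between the reconstruction and
the *uncorrupted* normalized image. Evaluation-time encoding never
corrupts its input. Defaults: denoising rate 0.20, batch size 16,
learning rate 0.05 multiplied by 0.9 after every epoch, 50 epochs.
Epoch-level image order is reshuffled from the training seed.

Numerical choices:

- Arithmetic is float32 by default (the workload is memory-bandwidth
  bound; float64 halves throughput for no benefit at these tolerances).
  Networks can be built in float64, which the finite-difference gradient
  tests use.
- MSE is averaged over all batch elements and pixels.
- A non-finite batch loss aborts training with a diagnostic rather than
  silently continuing.
- ReLU and max-pooling are non-differentiable on measure-zero sets (kinks
  and ties); the backward pass uses the standard subgradients (inactive
  ReLU passes zero; pooling routes to the first argmax). Gradient
  verification therefore runs either on all-tanh networks or with biases
  shifted so every ReLU is strictly active and no pooling block ties.

## Initialization

Weights are drawn per layer from a seeded generator. Two policies exist:

- **identity-leaning** (default): each filter passes one input channel
  through its centre tap (cycling through the input channels across
  output maps) plus fan-in-scaled uniform noise, U(-L, L) with
  L = sqrt(6/fan_in), at a quarter of the usual amplitude. At
  initialization the encoder then behaves like a noisy
  information-preserving downsampler: every bottleneck unit responds to
  its spatial neighbourhood from the first epoch.
- **uniform**: plain fan-in-scaled uniform init.

The identity-leaning default exists because the bottleneck is a *single*
feature map under ReLU: its pre-activation over the image is one
spatially correlated field, so under purely random init the sign of one
draw decides the fate of the whole map, and maps that start inactive for
every training image receive no gradient and never recover. Measured at
desk scale, purely uniform init leaves anywhere from 2 to 18 of 18
bottleneck units active depending on the seed; the identity-leaning
policy keeps all of them active for every seed tried, and downstream
classification quality stops depending on initialization luck. Biases
start at zero in both policies.

Additionally, each SGD step's gradient is globally norm-clipped (default
ceiling 1.0, configurable, disable with ``grad_clip=None``). The
value-duplicating unpooling sums four output-side gradients into every
bottleneck cell per stage — a 4^P amplification through P unpooling
stages — which makes the first high-learning-rate epochs prone to
destructive spikes at small image sizes; the clip caps those spikes
without affecting ordinary steps.

## Normalization

Two per-image normalization modes are provided: a linear map of [0, 1] to
[-1, 1] (the default, so the tanh output layer can cover the target
range) and per-image z-scoring (mean 0, sd 1; rejected for constant
images). Z-scored targets can exceed the tanh range, so the z-score mode
is offered for experimentation rather than as the training default.

## Synthetic corpora

The generator emulates the structure of expression-masked ISH sections at
desk scale: a dark exterior, an elliptical brain region at mid-gray, and
pixelwise Gaussian noise (sd 0.05), clipped to [0, 1]. Genes positive for
a category additionally receive that category's motif inside the
ellipse — a Gaussian expression blob at a category-specific location
(default), a horizontal laminar band (evoking layered structures such as
the cerebellar cortex), or a directional sinusoidal texture — scaled by
`motif_strength` (amplitude 0.45 at strength 1) and jittered by a few
pixels per image so translation tolerance matters. Category sizes are
drawn from a configurable range within [15, 500] against a larger
negative pool, mirroring the heavy imbalance of real GO annotation
tables. The default corpus is 200 genes, 4 non-overlapping categories of
15-25 positives, 96x48 images (the 2:1 aspect of real sections, and
divisible by 2^4 so the four-stage reference architecture applies).

What the generator does **not** emulate: histology staining variation,
slice-to-slice registration error, multi-slice series, anatomical texture
beyond noise, or correlated annotation structure (the GO graph). Passing
end-to-end tests on these corpora therefore demonstrates that the
pipeline recovers planted, localized category signal at small scale — not
that it reproduces published full-corpus accuracies.

## Classification protocol

Categories with 15-500 positives are kept (smaller sets cannot be tested
reliably; larger ones are semantically too broad). For each category,
positives and negatives are shuffled and split independently into five
near-equal subsets, paired into folds — every fold then preserves the
class ratio. Evaluation is two-phase: each fold is held out once; on the
remaining four folds, each serves once as inner validation to choose the
L2 regularization strength (logarithmic grid 1e-3..1e3, seven values,
first-best on ties) maximizing inner mean ROC AUC; the model (per-column
standardization fit on training data only, then logistic regression) is
refit on all four folds and scored on the held-out fold. AUC uses the
Mann-Whitney convention (ties half-credited). The summary metric averages
fold AUCs within a category, then category means without weighting; the
alternative of pooling predictions across folds is not used.

Negatives for a category are all genes not annotated to it, without
subsampling or class weighting.

## Problem sizes

Default test and pipeline runs use 96x48 or smaller images, tens to a few
hundred genes, and tens of epochs; the full 960x480 architecture is
exercised for shape and encoding checks rather than full training. These
sizes keep the complete suite runnable on a laptop-class single core.

## Known limitations

- Desk-scale training (hundreds of images, 50 epochs) moves the weights
  only modestly under the decaying schedule; representation quality
  depends noticeably on initialization, which is why the initialization
  policy is part of the documented design (see above).
- The value-duplicating unpooling amplifies gradients flowing into the
  bottleneck (each cell's gradient is the sum over its duplicated block),
  which at small image sizes makes early high-learning-rate epochs the
  least stable part of training.
- Single-feature-map ReLU bottlenecks can lose units permanently (a unit
  inactive for every training image receives no gradient).
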