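# Methods

`gaseg` implements fully unsupervised segmentation of geographic atrophy
(GA) — the bright atrophic lesions of dry age-related macular degeneration
in infrared cSLO fundus images — and the apparatus needed to study it
without clinical data: a synthetic fundus generator, a preprocessing chain,
three classical unsupervised baselines, and a shared pixel-wise evaluation
protocol with temporal fusion for longitudinal series.

## The W-net model

The core model is a W-net: a fully convolutional autoencoder whose encoder
and decoder are both U-nets (contracting/expansive paths with skip
connections, two 3x3 conv + batch-norm + ReLU stages per level, 2x2 max
pooling down and nearest-neighbour upsampling + convolution up).  The
encoder ends in a K-way channel softmax, so its output at every pixel u is
a probability distribution p(u = A_k) over K latent classes; the decoder
maps that probability map back to an image.

Training is unsupervised and uses two losses:

* **Reconstruction**: MSE = (1/n) Σ_k (Y_k − Ŷ_k)², n the number of pixels.
* **Soft normalized cut**:

      J(V, K) = K − Σ_k  [Σ_{u,v} w(u,v) p(u=A_k) p(v=A_k)]
                       / [Σ_{u,t} w(u,t) p(u=A_k)]

  with pairwise affinities
  w(u,v) = exp(−(I_u−I_v)²/σ_I²) · exp(−‖X_u−X_v‖²/σ_X²) for ‖X_u−X_v‖ < r,
  else 0 (and w(u,u)=1).  J lies in [0, K], equals 0 for the trivial K=1
  partition, and decreases as classes become coherent in intensity and
  space.  A class with vanishing mass is guarded with ε=10⁻⁸ in its
  denominator.

Each training batch does one forward pass followed by two successive
optimization steps, each with its own Adam optimizer: (1) the
reconstruction error is back-propagated through the whole W-net;
(2) the soft-N-cut loss is back-propagated through the encoder only.
Because the pairwise affinity graph is quadratic in pixel count, the
soft-N-cut loss is evaluated on average-pooled inputs: both the image (for
the affinities) and the probability map are pooled by `pool_factor`
(256→128 in the full-scale configuration), and pooled per-pixel
distributions are renormalized (average pooling already preserves the
simplex up to float error).

After training, `argmax` over the probability map gives a K-class
segmentation.  K defaults to 3: with only two classes the latent
representation is too restrictive, while the third class absorbs vessels
and darker retina, and the lesion concentrates in the brightest class.
Mapping latent classes to {lesion, background} is done once per trained
model — automatically by highest mean image intensity
(`auto_map_classes`), or, when reference masks are available, by
maximizing pooled F1 over all 2^K−1 class subsets.

### Defaults and scaling

| parameter | default | note |
|---|---|---|
| K (classes) | 3 | 2 is too restrictive; 3 gives lesion/retina/vessel strata |
| kernel size | 3 | all convolutions |
| depth / base features | 5 / 64 | 1024 features at each U-net bottleneck |
| epochs | 250 | full-scale configuration |
| Adam learning rates | 1e-3 (reconstruction), 1e-3 (N-cut) | full-scale nets |
| pool_factor | 2 | soft-N-cut on the pooled grid |
| σ_I, σ_X, r | 0.1, 4, 5 | intensities in [0,1]; pixels |
| batch size | 8 | |

`depth` and `base_features` scale the architecture down for CPU
experiments; the mini configuration used throughout the tests is depth 3,
16 base features on 64×64 inputs (pooled 32×32 graphs).

### Optimization behaviour and the training schedule

Two numerical facts shaped the training defaults, both established with
the package's own diagnostics:

1. **The affinity graph is informative but the loss landscape is not
   benign.**  On lesion phantoms, spectral clustering of the very same
   affinity matrix recovers the lesion nearly perfectly (J ≈ 0.003), yet
   first-order minimization of the soft loss from random probabilities
   converges to smooth spatial partitions (J ≈ 0.3–0.4): once the softmax
   saturates, moving a class boundary produces gradient only within the
   affinity radius of the boundary band, and distant basins are
   unreachable.
2. **Reconstruction pressure is what seeds intensity structure.**  Before
   any partition step, MSE training alone drives the per-pixel
   probabilities into soft, strongly intensity-correlated codes (|corr|
   ≈ 0.8 per channel at max-probability ≈ 0.57 on phantoms).

Consequently `WNetConfig.ncut_warmup_epochs` (default 0, i.e. the plain
alternating scheme) lets the first epochs run reconstruction-only; when
the partition step starts, hardening locks the intensity-coded classes
onto affinity boundaries instead of freezing an arbitrary spatial
partition.  The mini-scale runs use a warm-up of 20 epochs out of 60, an
N-cut learning rate of 1e-2, and a wider pooled-grid affinity
(σ_X=8, r=10 on 32×32): the radius must be comparable to the width of the
boundary-capture zone at the pooled resolution, otherwise a converged
boundary a few pooled pixels away from the true intensity cliff feels no
pull from it, and the hardening rate must be strong enough to contract a
bright class that initially overshoots the lesion into the surrounding
bright background (at 3x weaker rates that halo is a stable second mode,
reached from some initialisations/datasets, with a visibly worse final J
of ~0.35 vs ~0.2).  Because the final soft-N-cut value separates the two
modes without labels, `WNet.fit_restarts` offers k-means-style restart
selection: train `n_init` models, keep the lowest final J.  Two further
choices matter:

* **Reflect padding** in every convolution.  With zero padding a fully
  convolutional network can read absolute position from border artefacts,
  and the unsupervised objective exploits that to emit a fixed spatial
  partition; reflect padding keeps the network translation-equivariant so
  classes must be driven by content.
* **Batch normalisation** after each convolution (batch statistics during
  training, running estimates at inference), without which the
  double-objective optimization stalls at mini scale.

### The numerical engine

The networks run on a small numpy engine (`gaseg.nn`) with manual
backpropagation: same-padded convolutions evaluated as k² shifted-view
GEMMs, ReLU, 2×2 max pooling (ties to the first window element), batch
norm, nearest-neighbour upsampling, channel softmax, Adam and momentum
SGD.  Every layer's backward pass is verified against central finite
differences in float64 (relative error ≲ 1e-8 in the test suite); float32
is used for training.  The soft-N-cut gradient with respect to the
probabilities is analytic,

    dJ/dp_k(u) = −[2 (W p_k)_u d_k − a_k d(u)] / d_k²,

with a_k the class association, d_k its degree-weighted mass and d(u) the
pixel degree; it is chained through the renormalization, the average
pooling and the softmax, and is checked against finite differences of the
loss itself.

## Synthetic fundus phantoms

The generator emulates the statistical structure of registered IR cSLO
frames of dry-ARMD eyes: bright lesions with irregular star-convex
boundaries (a circle whose radius is modulated by a random 6-harmonic
Fourier series; amplitude = `boundary_irregularity`), optional boundary
blur, a textured background (Gaussian-filtered noise around intensity
0.35), dark curvilinear vessels (random-walk strokes applied
multiplicatively, ~45% attenuation), smooth polynomial illumination
shading shared by all frames of a series, additive Gaussian sensor noise,
and final clipping to [0,1].  Longitudinal series grow by binary dilation
of the previous mask, so the subset relation mask_{t−1} ⊆ mask_t holds
pixel-exactly, with an optional de-novo lesion event at a chosen frame.
Defaults: 2 lesions of radius 8–16% of the image side, contrast 0.5,
4 vessels, 15% shading, noise σ=0.02.

What the phantoms do **not** model: speckle statistics of real cSLO,
registration artefacts beyond a plain black frame, pathology other than
GA, texture inside the lesion, and realistic vessel trees.  Tests passing
on phantoms therefore demonstrate the correctness and the qualitative
behaviour of the algorithms, not clinical performance.

## Preprocessing

Registered clinical exports carry near-black borders and per-visit gain
differences.  The chain is: (1) crop the maximal border of rows/columns
that are entirely ≤ 0.02 (≈5/255 — borders are near-zero, not exactly
zero, after compression); (2) bilinear resize to 256×256 (nearest
neighbour for masks, which must stay binary); (3) joint homogenization of
each series: every frame is affinely standardized to the mean/std of the
series' median frame, then one series-wide affine maps the joint range to
[0,1].  This equalizes global statistics only — a deliberate minimal
stand-in for joint illumination correction, replaceable by any stronger
method with the same contract (equal per-frame mean/std, monotone per
frame, idempotent).  Low-frequency shading inside a frame is left alone;
the residual defect is then common to the whole series.

## Baselines

* **Gabor + k-means**: filters h(x,y) = 1/(2πσ_xσ_y)·exp(−½(x′²/σ_x²+y′²/σ_y²))
  ·cos(2πu₀x′) over 4 frequencies {0.05, 0.1, 0.2, 0.3} cyc/px × 4
  orientations, σ = 1/(2u₀); responses pass tanh(0.25·r), are smoothed
  into texture energy (σ = 3/u₀), joined with normalized pixel
  coordinates, standardized per column and clustered with k-means.  For
  soft memberships (ROC analysis) fuzzy c-means (m=2) is initialized from
  the k-means centers, so its argmax reproduces the hard clustering.
* **Chan–Vese**: two-phase active contour without edges minimizing
  ∫inside|I−c1|² + ∫outside|I−c2|² plus a length penalty (μ=0.1 for
  intensities in [0,1]); level-set evolution delegated to scikit-image
  with checkerboard initialization (topology changes come free), energy
  history recorded, and the brighter phase reported as the lesion.
* **Per-image CNN + superpixel refinement**: a small CNN (two 3×3 conv
  layers of width p, a 1×1 classifier to q channels) is trained from
  scratch on each image; each iteration whitens the response map per
  channel (zero mean/unit variance over the image — this is what keeps
  the cluster count from collapsing), takes per-pixel argmax labels,
  forces every SLIC superpixel to its modal label, and back-propagates
  the cross-entropy between responses and refined labels (SGD, lr 0.1,
  momentum 0.9).  The final cluster count q′ satisfies 1 ≤ q′ ≤ q; the
  brightest cluster is reported as the lesion when a binary mask is
  needed.

## Evaluation protocol

Lesion pixels are positive; precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R) = TP/(TP+0.5(FP+FN)) (the two forms are identical and both
are asserted).  Degenerate conventions: empty truth + empty prediction →
all three scores 1; empty truth + non-empty prediction → precision 0,
recall 1, F1 0; empty prediction + non-empty truth → precision 0.  ROC
curves sweep a per-pixel lesion-probability map over its unique values
(endpoints (0,0), (1,1) appended); AUC is the trapezoid integral and
equals the pairwise-ranking probability with ties at half.  Temporal
fusion (Seg_{t−1}) replaces mask_t by its pixel-wise union with the
previous frame's predicted mask — recall can only increase (GA only
grows), precision may pay for it.  Series evaluation reports per-frame
scores, per-series means, and pooled mean ± std; seeded 12/6 train/test
series splits with 8 repetitions mirror the study protocol for small,
uneven series collections.

## Problem sizes in the shipped tests

The test-suite and acceptance runs use mini-scale configurations chosen
for a laptop-class CPU: 64×64 phantoms, a depth-3/16-feature W-net
trained 60 epochs (20 warm-up) on 40 images and tested on 10, 96×96
baseline phantoms, and ≤16×16 instances for the brute-force loss oracle.
These sizes exercise every code path of the full-scale configuration.
The W-net recovery experiment uses multifocal phantoms (4 lesions, ~16%
of the frame) — the advanced-GA regime the clinical series exhibit; see
the limitation below on very small lesions.

## Known limitations

* Gradient-based soft-N-cut optimization does not, in general, reach the
  spectral optimum; very small lesions (a few pooled pixels across) can
  remain inside a larger class even though the affinity graph isolates
  them — the same undersegmentation risk the method shows on low-contrast
  clinical images.
* Batch-norm inference uses running statistics; a model applied to images
  with very different global statistics than its training set should be
  re-homogenized first (the preprocessing chain exists for this reason).
* The phantom generator's texture realism is best-effort and not
  validated against clinical images; clinical conclusions require the
  real data path (PNG series + expert masks) and are out of scope here.
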