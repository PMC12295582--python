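# Methods

## Problem and model

Dermoscopic archives rarely record the patient's skin tone, yet tone is a
confounder for any classifier trained on them.  `mstai` estimates, for a
single dermoscopic photograph, a *membership distribution* over the ten
Monk Skin Tone (MST) scales rather than a single hard label.  The premise
is that neither an MST swatch nor the normal skin in an image is one RGB
point: both are distributions of pixels in the RGB cube, and the honest
comparison is between densities.

The pipeline has four stages.

**1. Frame removal.**  Many dermoscopy photographs carry a black (or
white) vignette.  A fixed seven-step classical detector finds it: extreme
whites are painted black (channel mean ≥ 256·W_th, W_th = 0.95);
grayscale by the per-pixel channel **maximum** (contrast-enhancing);
min–max normalization; thresholding at B_th = 0.05; removal of
8-connected dark components smaller than O_th = 64 px; filling of bright
holes smaller than H_th = 64 px inside the dark mask; finally the convex
hull of the surviving bright content becomes the region of interest (ROI)
and its complement the frame.  The four thresholds are heuristic settings
for dermoscopy archives and are exposed as `FrameParams`.

The printed form of the thresholding step assigns 1 to non-dark pixels
while the prose calls the dark regions "objects"; we resolve the polarity
by running the component cleanup on the dark complement, which reproduces
the intended behavior on vignetted images.  Other fixed choices:
8-connectivity is not configurable (it is part of the algorithm);
channel-mean comparison in step 1 happens on the integer channel sum, so
the boundary cannot drift with float rounding; a constant image
normalizes to all-zeros (treated as all-dark, hence no usable ROI); an
empty foreground yields an empty ROI and the image is flagged
"excluded: insufficient skin area".

The hull is computed over pixel *centers* with exact integer
cross-product tests (vertices from `scipy.spatial.ConvexHull`; collinear
point sets handled as lattice segments), so the result is deterministic,
platform-independent and checkable pixel-exactly against a brute-force
all-pairs half-plane oracle.

**2. Lesion exclusion.**  The lesion's color differs sharply from normal
skin and must not enter the estimate.  Masks come from a `MaskProvider`:
an external mask file (production; e.g. the output of an FCN trained on
the public lesion-segmentation challenges), an in-memory array, a small
trainable per-pixel segmenter, or none.  The bundled segmenter is a
logistic model over quadratic RGB features trained with a hand-written
Adam optimizer on the smoothed Jaccard loss
`−log((Σ X·Y + ε)/(Σ X + Σ Y − Σ X·Y + ε))`, ε = 1e−7, with joint
geometric augmentation (flips, translation, rotation, scale, shear,
perspective).  Default hyperparameters are the standard recipe (Adam,
lr 1e−4, batch 32, 20 epochs, 256×256 inputs in [0,1]); note a linear
color model trained from scratch typically needs a larger learning rate
or more epochs than a pre-trained network — the tests use lr 0.02–0.1.
Evaluation metrics: DICE = 2|X∩Y|/(|X|+|Y|) and the Jaccard loss above
(soft masks during training, hardened at 0.5 after the sigmoid for
reported DICE).  Both metrics raise on two empty masks rather than
returning a convention value, because silent defaults would corrupt
averages.  Frame and lesion removal commute: the skin mask is the
complement of their union.

**3. Per-image color density.**  Skin pixels are mapped to [0,1]³ by
dividing by 255 (all compared densities share the space, so the scaling
Jacobian cancels).  A variational Bayesian Gaussian mixture
(`sklearn.mixture.BayesianGaussianMixture`) with at most K = 8
components is fitted independently per image.  Priors: Dirichlet-process
weight concentration 1/K; data-driven covariance prior (sklearn
defaults); `reg_covar` = 1e−6 so flat swatch clouds stay positive
definite; `max_iter` = 500 (fits on a few thousand pixels genuinely need
300–400 iterations; capping lower visibly changes the weights).  The
variational treatment lets surplus components shrink, and overlapping
split components at one mode are normal behavior — the density, not the
component count, is the estimand.  Clouds above 100 000 pixels are
subsampled with a seeded generator.  Log-densities are evaluated by
log-sum-exp over per-component Cholesky-based Gaussian log-pdfs and are
finite for any finite input.

**4. Divergence and membership.**  The ten MST reference densities are
fitted with the same settings to clouds drawn around the published
swatch RGBs with isotropic sd 0.02 in normalized units (≈ 5 intensity
levels, the scatter of a photographed flat patch).  Each reference P_m is
compared with the skin density Q by a Kullback–Leibler divergence on a
cubic lattice of cell centers `(i+0.5)/N` per axis, N = 100 by default —
one million points, matched to the 256 discrete states per channel
(finer grids change nothing material; coarser N = 64 is used for the
desk-scale benchmark).  Both densities are renormalized over the lattice
before the sum, making D a proper discrete KLD (non-negative by Gibbs'
inequality, zero only for identical grid profiles); raw density sums
would otherwise depend on grid volume.  log Q is floored at log(1e−300)
in the discrete domain so D stays finite where Q has no support;
occurrences are counted and logged (loudly only when the floored region
carries P mass).  Divergences map to similarities s_m = 1 − D_m/max_m D_m
and through a softmax to ten scores in (0,1) summing to 1; if every
divergence is zero all s_m are set to 0 (uniform membership) instead of
dividing by zero.  Ranking ties break toward the smaller scale id so runs
are reproducible.

## Baselines and evaluation

The two comparison methods reduce a pixel set to its mean RGB and rank
scales by Euclidean distance to the reference mean-RGB points, reused
through the same softmax: *Image K-means* over all pixels (frame and
lesion included) and *Skin K-means* over detected skin only.  Despite the
names there is no iterative clustering — both are nearest-reference
assignments; the names are the field's.

Agreement between a method's ranking and the gold-standard ranking from
an annotated skin rectangle is measured over the top-k scales (k ≤ 4):
Kendall's τ with the strict >0 concordance rule over C(k,2) pairs;
Spearman's ρ = 1 − 6Σd²/(k(k²−1)); and NDCG with gain 2^m − 1 on the
gold membership scores and discount log₂(i+1).  Conventions fixed here:
the top-k item set comes from the gold ranking, A_i = 1..k; an item
outside the method's top-k keeps its full ten-scale detected rank (so ρ
can fall below −1 for badly wrong methods — the bound holds whenever the
two top-k sets coincide); τ and ρ are undefined at k = 1 and raise.  The
complementary "1 − DCG/IDCG" form is available as `ndcg(...,
as_printed=True)` for auditability; the default is the standard ratio
(1 = gain-optimal order).

Method means are compared with a two-tailed test that assumes the metric
is uniform over its range: σ = (b−a)/√12, i.e. 0.5774 for correlations on
(−1,1) and 0.2887 for NDCG on (0,1), with the statistic referred to the
standard normal (the known-σ limit of the t-test).  This is a very
conservative σ — real per-sample spreads are far smaller — so
significance claims are understated.  A conventional Welch test is
deliberately not the default, to keep the reported p-values comparable
with the package's stated procedure.

## Synthetic data and the benchmark

`fixtures` renders dermoscopy-like images with exact ground truth: a
frame (dark/white corner vignette or full border), an elliptical lesion,
and skin pixels drawn i.i.d. from a known Gaussian mixture, clipped to
[0,255] after noise (pre-clip parameters are kept so moment tests can
avoid saturated regions).  The generator is bit-reproducible given its
seed.  It does **not** model hair, rulers, illumination gradients or
spatially coherent tone regions; consequently, passing tests demonstrate
the estimator's statistical correctness under its own model, not
robustness to real-world artifacts (the pipeline's exclusion category
exists precisely because real archives contain such images).

The benchmark (`mstai.benchmark`) is a desk-scale analog of a
manual-annotation validation campaign.  Conditions, fixed once: 64×64
images; frame styles cycling dark vignette / none / full border / none /
white vignette; skin = three-component mixture whose component means
scatter with sd 16 intensity units around the scale's swatch (multi-tone
skin straddling neighboring scales — the regime where a single mean-RGB
point misleads) with per-component sd 6; one lesion per image, its true
mask standing in for a trained segmenter for *all* methods; a fixed
16×16 pure-skin annotation rectangle provides the gold standard through
the same VB-GMM + KLD machinery.  Scales are visited round-robin, so the
benchmark is balanced by construction.  At these conditions the density
method clearly dominates both baselines on rank correlation; on NDCG all
skin-scoped methods score ≥ 0.97 because softmax memberships are flat
(gains differ by at most a factor ≈ 3), so NDCG separates only grossly
wrong rankings such as the whole-image baseline's.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: references
fitted from 2 000-pixel swatch clouds; per-image fits on a few thousand
skin pixels; recovery checks at 10⁴ pixels; grid 100³ for analytic
checks and 64³ for the 300-image (tests) / 150-image (script) benchmark.
These sizes were chosen so the full cycle runs comfortably on one CPU
while leaving every qualitative conclusion unchanged at larger sizes.

Degenerate inputs are defined, not crashed on: constant images, empty
hulls, all-masked images, zero divergences, flat swatches and collinear
hull inputs all have documented behavior above.  All randomness flows
from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

- RGB only; no illumination correction or alternative color spaces.
  Lighting and instrumentation confounds are unmodelled.
- The bundled segmenter is a color model: it cannot separate a lesion
  whose color matches normal skin; production use should supply masks
  from a real segmentation network via the `file` provider.
- Reference densities derive from the published flat swatch colors, not
  from calibrated swatch photographs; the swatch JSON is editable data.
- A membership distribution over ten scales is the output by design;
  collapsing it to a single label discards exactly the information the
  method exists to preserve.
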