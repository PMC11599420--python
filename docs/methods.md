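# Methods

## Model

The translator is a one-sided GAN mapping a "simulated" image domain X into
a "realistic" domain Y.  A ResNet-style generator (7×7 stem, two stride-2
downsampling stages, a residual trunk, two nearest-neighbour upsampling
stages, 7×7 tanh head; instance normalisation and reflection padding
throughout) is trained against a 3-layer patch discriminator.  Pixel range
inside the networks is [−1, 1]; losses that assume [0, 1] rescale at their
boundary.  There is no reverse generator and no cycle-reconstruction term
anywhere: content preservation is delegated entirely to the two content
losses below.

**Patch-contrastive term.**  Features are tapped at five encoder depths
(the input image itself, the stem, both downsampling stages and the middle
of the residual trunk).  At each tapped layer, S spatial locations are
drawn uniformly without replacement; the translation's feature at a
location is the query, the input's feature at the same location the
positive, and the other S−1 sampled input locations the negatives
("internal" negatives only).  Both sides pass through the same two-layer
MLP projection head (one per layer, created lazily at first forward so its
width binds to the encoder) and are unit-normalised; the InfoNCE loss with
temperature τ is averaged over locations and layers.  The same construction
applied to domain-Y images and their own translations acts as an identity-
style regulariser discouraging the generator from rewriting images that are
already in the target style.

**Semantic term.**  `1 − MS-SSIM(x, G(x))`, both rescaled to [0, 1].
Local statistics use an 11-tap Gaussian window (σ = 1.5), and the pyramid
is built by 2×2 average pooling (odd trailing rows/columns cropped).  The
contrast-structure ratio cs enters at every scale; the luminance-bearing
term ss only at the coarsest scale; per-scale spatial means are clamped to
a floor of 1e-6 (a weighted geometric mean is undefined for negative
factors) and combined with the canonical five-scale weights
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333), stored normalised to sum exactly
to one.  Scores are computed per channel and averaged, preserving
sensitivity to colour-texture swaps between classes.  When an image is too
small for all configured scales, the scale count is reduced to the largest
valid value and the weights renormalised — at 64×64 with an 11-tap window
this gives three scales.  A `composition="product"` toggle evaluates the
literal per-scale cs·ss product instead of the canonical split, for
comparison studies.  The semantic pair is input-vs-translation by default
(`semantic_pair`); pairing the identity branch instead is available for
study.

**Objective and optimisation.**  `L_GAN + λx L_Patch(X) + λy L_Patch(Y) +
λss L_semantic`, with λx = λy = λss = 1 by default.  λss = 0 reverts
exactly to the plain contrastive (CUT-style) objective; λx = λy = 0 removes
the patch terms.  The adversarial part trains in least-squares form
(labels 1/0) by default; the saturating log form is a config switch.  Adam
(lr 2e-4, β = (0.5, 0.999)), one discriminator step on (y, G(x) detached)
then one generator step per iteration, batch size 1, linear LR decay over
the second half of the run.  Defaults τ = 0.07, S = 256 patches,
embed dim 256 follow the contrastive-translation lineage; the fixture-scale
configuration (`--fixture-scale`, and what the tests and the acceptance
script use) shrinks the backbone to ngf = ndf = 8, three residual blocks,
S = 64, embed dim 64 so a 500-step run fits in a couple of minutes on one
CPU core.

## Differentiation engine

No autodiff framework is a dependency; the package carries a small
reverse-mode engine over NumPy (`constructs.autodiff`).  Ops are coarse
(one tape node per convolution, via im2col and BLAS matmuls; separable
Gaussian filtering as banded matrix products) and every op's gradient is
validated against central finite differences in the test suite.
Everything is float32 in the networks; the loss-level public functions
accept float64 and preserve it, which is what the 1e-6-level oracle
comparisons in the tests rely on.

## Determinism

Every random stream derives from the run seed: weight init, data order,
patch sampling and the segmentation trainer use disjoint seeded
`default_rng` streams, and the per-step streams are *stateless* (seeded by
`(seed, stream, step)`), so a run resumed from a checkpoint consumes
exactly the randomness an unbroken run would — resume-equivalence is
bit-for-bit and tested.  Checkpoints are single `.npz` archives holding
generator, discriminator, projection heads, both Adam states, the step
counter and the resolved configuration with its fingerprint.

## Synthetic scenes

The fixture generator emulates the statistical structure the method
assumes, with no asset files: class regions are nested level sets of a
band-limited Gaussian random field (smooth, organ-like curved boundaries;
per-class area fractions fixed by quantile thresholds, each class
guaranteed ≥ 2% coverage with bounded resampling retries) plus an elongated
tool-like rectangle.  The X style renders the mask with flat per-class
colours and a mild vertical shading gradient; the Y style uses a different
palette modulated by per-class correlated noise texture (unit-variance
field scaled by a per-class amplitude), a random-direction linear
illumination gradient, additive Gaussian specular highlights and a radial
vignette.  The X palette is deliberately non-tissue-like with hues far from
the Y palette — so a per-pixel classifier trained on one domain fails on
the other and the fixtures pose a genuine translation problem — while the
per-class *luminance ordering* matches the Y palette, as it does in actual
anatomy renders, so structural similarity to the input does not contradict
the target style.  Training splits draw X and Y from disjoint seed sets
(unpaired, as one-sided translation assumes); the eval split reuses one
structure seed per scene for both styles, which provides a known perfect
translator for harness-level oracle tests.

What the fixtures do **not** model: perspective geometry, occlusion,
smoke/blood dynamics, instrument reflections, inter-patient appearance
variation and video temporality.  Passing the scaled-down study shows the
losses and harness behave as designed, not that the method reaches any
particular quality on real surgical data.

## Evaluation

Per-image metrics: pixel accuracy; mean class accuracy (mean per-class
recall over classes present in the truth); mean IoU and mean Dice over
classes present in prediction or truth — classes absent from both are
excluded rather than scored 0/0.  Aggregates are per-image means ± sd (not
a pooled confusion matrix), matching how such studies report spread.  The
segmentation model for both schemes is a compact two-level U-Net trained
with inverse-frequency class-weighted cross-entropy (the thin tool class is
~4% of pixels and is otherwise drowned out).  The U-Net is deliberately
normalisation-free: feature normalisation discounts global colour
statistics, which are precisely the domain cue the consistency evaluation
exists to measure.  The downstream evaluation fine-tunes with half the
pretraining step budget and reports both the all-class mean Dice and the
Dice of a designated foreground class (class 1, the large-organ analogue).

## Scaled-down study conditions

128 + 128 unpaired 64×64 training scenes, 32 paired eval scenes, 32
labelled real-style scenes for the frozen segmentation model and 16 for
the downstream test set; 500 training steps per translator; three training
seeds.  These sizes were chosen so the whole study runs in minutes on one
CPU core while every claimed direction (translation beats identity
passthrough under the consistency evaluation; the semantic term declines
over training; translated-pretrain + real-fine-tune beats translated-only
downstream) remains measurable.  The full-vs-ablation comparison at this
scale is stochastic and is asserted as a majority over seeds, mirroring the
small margin the ablation shows at full scale.

## Known limitations

* CPU-scale NumPy training: minutes per 500-step run at 64×64; the
  architecture choices (8-channel backbone) trade capacity for runtime.
* MS-SSIM anchors the translation's luminance structure to the input; on
  domain pairs whose class luminance orderings disagree, the semantic term
  and the adversarial term genuinely conflict and the weight λss becomes a
  real trade-off rather than a free regulariser.
* The InfoNCE negatives are internal only; no learned negative mining.
* Single-image model: no temporal consistency across frames.
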