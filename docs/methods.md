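# Methods

## Problem and model

The task is binary per-pixel classification of multispectral imagery:
*Silybum marianum* (milk thistle) patches versus other vegetation, in a
setting where the two classes look nearly identical in the visible bands and
are separated by two complementary cues — higher near-infrared reflectance
(the target canopy is vigorous while the surrounding graminaceous sward is
drying) and higher local spatial variance of NIR (large discrete plants make
a rough canopy; the sward is flat).

The classifier is a one-hidden-layer perceptron with `tanh` hidden units and
a logistic output, `y(x) = σ(v·tanh(u x + b₁) + b₂)`, read as
`p(t = 1 | x)`. Training minimizes `F(ω) = G + Σₖ αₖ E_w(k)` where `G` is
the Bernoulli cross-entropy and the weight vector is partitioned into
`n + 3` groups: one per input feature (all of that feature's first-layer
connections), the hidden biases, the hidden-to-output weights, and the
output bias. Relevance determination is automatic: each group's decay
hyperparameter αₖ is re-estimated from the data with the evidence
(marginal-likelihood) approximation

    γₖ = |W(k)| − αₖ · traceₖ(A⁻¹),   αₖ ← γₖ / (2·E_w(k)),

with `A` the Hessian of `F` at the current weight minimum and γₖ the
effective number of well-determined parameters in the group. Groups the
data does not determine end with large αₖ and collapsed weights; relevant
groups keep small αₖ and large norms.

## Training procedure and numerical choices

- **Inner optimizer.** Deterministic batch L-BFGS with the analytic
  gradient (standard backpropagation plus the `αₖωⱼ` decay terms). The
  accepted iterates are non-increasing in `F`; if a line search fails
  immediately the incoming weights are kept.
- **Curvature for the evidence step.** The exact Hessian of `F` is
  assembled analytically: the outer-product (Gauss–Newton) term
  `Σᵢ yᵢ(1−yᵢ) JᵢJᵢᵀ` plus the network-curvature term coupling each hidden
  unit's input weights with its output weight through `tanh'` and `tanh''`.
  The evidence update's derivation assumes `A` is the positive-definite
  curvature at a minimum; when the exact `A` fails its Cholesky
  factorization, or yields a negative raw γₖ (both signatures of an
  optimizer that stopped short of a true minimum), the update falls back to
  the Gauss–Newton form, for which `γₖ ∈ [0, |W(k)|]` holds analytically.
  Group traces of `A⁻¹` are computed by Cholesky solves; a dense-inverse
  oracle pins this path in the tests.
- **Clamps.** γₖ is clamped to `[0, |W(k)|]` and αₖ to
  `[α_min, α_max] = [0.1, 10⁶]`. A group with `γₖ = 0` or with fully
  collapsed weights (`E_w = 0`) is assigned `α_max` outright: the data
  determine nothing in it, so the prior takes over. The floor `α_min = 0.1`
  exists because the update has a degenerate self-consistent solution that
  exploits the `tanh` scale freedom (`u → u/c, v → c·v` leaves the fit
  unchanged near the linear regime): the output-weight group's α can
  collapse while its norm diverges, after which every feature group's norm
  stops reflecting relevance. A floor equivalent to a baseline weight decay
  removes that solution and is negligible for any group whose penalty is of
  order one.
- **Outer loop.** Up to 20 cycles of (optimize weights, re-estimate α),
  stopping when `maxₖ |Δαₖ|/αₖ < 10⁻³`, then one final weight polish at the
  settled α's. Twenty cycles rather than a shorter loop because the α
  iteration is visibly unconverged at 10 cycles on some seeds, which can
  leave a noise feature with a transiently small α.
- **Other defaults.** 8 hidden units; initial `αₖ = 0.01`; zero biases and
  uniform `±1/√fan-in` weight initialization from a seeded generator;
  predictions clipped at `ε = 10⁻¹²` inside logarithms so `G` stays finite
  at saturation; decision threshold 0.5 with exact ties assigned to the
  target class (a documented deterministic tie-break).
- **Features.** Texture is the *population* (divide-by-count) variance in a
  7×7 window, computed on the globally centered band via two uniform
  filters with reflect padding, so the layer keeps the image shape; the
  centering avoids catastrophic cancellation and the loop-based oracle in
  the tests pins the convention at 10⁻¹² accuracy. Inputs are standardized
  to the training set's mean and deviation; the parameters are frozen and
  reused for validation and whole-scene deployment. Zero-variance features
  get a floored scale with a logged warning.
- **Protocol.** Labeled pixels come from axis-aligned pure-class sampling
  rectangles; the majority class is undersampled without replacement to the
  minority count, and the balanced pool is split 70/30 with a ceiling
  training size (so 2868 pixels split as 2008/860). All randomness flows
  from one master seed through fixed per-operation child streams, making
  every stage and the full pipeline bit-reproducible.

## The synthetic-scene generator

Real surveys of this kind are rarely deposited, so the generator produces
the study conditions directly:

- **Ground truth.** A Gaussian-smoothed white-noise field (smoothing length
  `patch_scale = 25` px) thresholded at its empirical quantile gives
  contiguous patches with an exact target coverage (default 0.45) — the
  "large interleaved patches" structure of an uncultivated field. Default
  scene size 240×240 px at a nominal 0.5 m/px keeps the 7×7-window boundary
  band a small areal fraction, as in a field whose patches span tens of
  meters.
- **Reflectance.** Per band: class mean + smooth within-class variation
  (shared smoothing length 4 px) + white sensor noise. Defaults: NIR means
  0.50 (target) vs 0.35 (other) with smooth sd 0.03 and sensor sd 0.035;
  green/red means identical between classes (0.12/0.10) with smooth sd
  0.002 and sensor sd 0.015. Target-class NIR additionally carries
  independent speckle of amplitude `texture_contrast = 0.06`, which is what
  makes the 7×7 local variance discriminative.
- **Calibration rationale.** The defaults are chosen so that each
  informative cue is *individually imperfect* — a single NIR threshold
  reaches roughly 95% and a single texture threshold roughly 97% — while
  their fusion reaches the ~99% regime. This matters for relevance
  recovery: if either cue separates the classes perfectly on its own, the
  trained network can drop the other as redundant, and a saturated
  cross-entropy lets noise-feature weights drift. The visible bands' smooth
  component is kept very small relative to their sensor noise because
  labeled pixels are sampled from a few dozen polygons and split 70/30 at
  the *pixel* level: any band whose smooth field varies appreciably between
  polygons acquires a real, validating in-sample correlation with class,
  which would defeat the "uninformative by construction" role of green and
  red.
- **What the generator does not emulate.** No radiative transfer or canopy
  BRDF, no georeferencing or orthomosaic artifacts, no mixed boundary
  pixels (class transitions are hard edges), no class imbalance beyond the
  areal coverage, and Gaussian noise throughout. Passing tests therefore
  demonstrate the correctness and behavior of the method under its own
  assumptions — contiguous patches, NIR/texture contrast, uninformative
  visible bands — not performance on any particular real survey.

## Problem sizes used in tests and the acceptance script

The shipped checks run the full pipeline on 240×240 scenes with 17 + 13
sampling rectangles of 11×11 px (≈ 3 100 balanced pixels, in the vicinity of
the 2 868-pixel protocol the dataset arithmetic reproduces exactly), ten
seeds for relevance recovery and three for end-to-end performance; the
dataset-protocol check uses the exact 4745/1434 labeled-pixel counts. These
sizes were chosen as the smallest at which patch structure, boundary
effects, and the evidence updates all behave as they do at field scale.

## Known limitations

- The evidence approximation is local (Laplace); with few training pixels
  or an unconverged inner loop the γ estimates are noisy, and relevance
  recovery is statistical, not guaranteed per seed.
- Whole-scene agreement is bounded by boundary pixels, whose 7×7 texture
  window straddles both classes; the generator's hard class edges make this
  slightly harsher than a real canopy transition.
- The α floor trades a small bias (a baseline decay on all groups) for
  robustness against the scale-degenerate solution; relevance rankings are
  unaffected but absolute α values at the floor should be read as "at most
  0.1".
- Binary output only; multi-class mapping would need a softmax head and a
  re-derived Hessian.
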