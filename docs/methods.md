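# Methods

`orchardvit` implements a vision-transformer classifier for orchard fruit
images together with a family of classification losses designed for
class-imbalanced data, a procedural generator of labeled fruit images, and
seeded training/evaluation pipelines. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not show.

## The loss family

For a one-hot label with predicted probability `p` at the true class, the
three losses are

- cross-entropy: `CE(p) = -log p`
- focal loss: `FL(p) = -(1-p)^γ log p` (Lin et al.'s focusing idea:
  well-classified samples are down-weighted)
- measured focal cross-entropy (MFCE):
  `MFCE(p) = -[w_ce(p) + w_f(p)(1-p)^γ] log p`, with the two-way softmax
  gate

  ```
  w_ce(p) = exp((1-p)·dv) / (exp(p·dv) + exp((1-p)·dv)) = σ((1-2p)·dv)
  w_f(p)  = 1 - w_ce(p)
  ```

The gate interpolates: a poorly classified sample (`p` near 0) is
penalised at near cross-entropy strength, a well-classified one at near
focal strength. Consequently `FL ≤ MFCE ≤ CE` pointwise for all `γ ≥ 0`,
`dv ≥ 0`, with equality of all three at `γ = 0`. At `p = 1/2` the gate is
exactly 1/2 by symmetry regardless of `dv`, giving the closed form
`MFCE(1/2) = -0.5 (1 + 0.5^γ) log(1/2)`. As `p → 0`, `MFCE/CE → 1`, and
the approach is monotone in `dv` — a sharper gate hands poorly classified
samples to the cross-entropy branch sooner.

**Gate convention.** The gate exponent could be read as `(1-p)·dv` or
`(1-p)/dv`. Only the multiplicative form makes a larger `dv` bring the
loss closer to cross-entropy for poorly classified samples, which is the
behaviour the loss is designed around, so it is the default; the divisive
form remains available via `LossParams(gate_convention="divisive")`.

**Parameters.** `γ` (focusing exponent, default 2) and `dv` (gate
sharpness, default 1) follow the conventional focal-loss setting; both are
unitless. `epsilon = 1e-7` floors probabilities before the log. The batch
reduction defaults to the mean.

**Numerics.** The gate is computed as a tanh-based logistic of
`(1-2p)·dv`, which cannot overflow at any `dv` and makes
`w_ce + w_f = 1` exact. Probabilities are clipped to `[1e-7, 1]` before
the log; the clip passes gradients only inside the range. Labels are
accepted one-hot or as integer indices.

## The classifier

The OAOM model is a ViT-style encoder:

1. the image is cut into non-overlapping `Ph x Pw` patches (`N =
   ⌊H'/Ph⌋·⌊W'/Pw⌋` after the boundary policy),
2. each flattened patch passes through one shared affine projection to
   width `D`, a learned positional-encoding vector indexed by patch
   position is added, and a learned CLS token is prepended,
3. the sequence runs through `L` pre-norm residual encoder blocks
   (`x + MHSA(LN(x))` then `y + FFN(LN(y))`, GELU feed-forward of width
   `mlp_size`, dropout after both sublayers),
4. the final CLS state feeds a GELU MLP head and a softmax over classes.

The reference configuration is 12 layers, `D = 790`, 12 heads,
`mlp_size = 3092`, 6x6 patches on a 70x70 image; tiny test
configurations run the identical code path.

Design points that the reference sizes force:

- 70 is not a multiple of 6, so a boundary policy is needed: `resize`
  (default) rescales to the nearest multiple (70 → 72, `N = 144`), `crop`
  drops the remainder (70 → 66, `N = 121`).
- 790 is not divisible by 12, so the per-head width is an independent
  parameter (default `⌊D/heads⌋ = 65`) and the head concatenation is
  projected back to `D`.
- Attention scales logits by `1/sqrt(head_dim)`; positional encodings are
  a learned table (one vector per patch position; the CLS token gets
  none); the head has one hidden layer of width 512 by default.

Training uses Adam (default learning rate `1e-3`) on the selected loss
applied to the softmax output. All randomness — initialisation
(`N(0, 0.02²)`), shuffling, dropout masks, validation carving — derives
from one integer seed, so runs reproduce exactly in single-threaded
numerics.

The network and its gradients are implemented on a small reverse-mode
tensor autodiff engine (`orchardvit.autodiff`) over numpy arrays; its
primitives are verified against central finite differences in the test
suite. `OAOMClassifier` exposes the whole thing through the scikit-learn
estimator API.

## The synthetic generator

Each image is an ellipse "fruit" (class hue, radial shading, low-frequency
skin speckle, random orientation/eccentricity) on a cluttered background,
plus one of six lesion operators applied over a target fraction of the
fruit area: `blotch` (irregular dark patches), `scab` (many small dark
dots), `powdery_mildew` (pale overlay), `rot`/`brown_rot` (one expanding
brown region), `cork_spot` (dimpled spots with dark rims). Per-image
severity jitters ±25% around the class severity.

Dataset designs pair a class list with per-class train/test counts. The
built-in presets emulate three collection layouts: 85 hue-separated
variety classes at 315/35 per class (29,750 images), fresh-vs-rotten at
1,044/116 per class (2,320), and seven disease phenotypes totalling
2,682 train / 294 test (2,976; train counts split 383x6 + 384, test 42
per class — the per-class split within the published totals is this
package's choice). Default image size is 96 px for desk-scale speed;
presets accept other sizes.

Determinism: per-image seeds derive from the master seed as
`SeedSequence([master_seed, class_index, split_index, image_index])`, so
any subset regenerates independently and byte-identically (PNG output is
lossless). A manifest-only mode emits counts and seeds without rendering,
which is how large design audits stay fast.

What the generator does **not** emulate: photographic texture, lighting,
occlusion, within-class shape diversity of real cultivars, background
semantics. A linear probe on mean color solves the easy 3-class setting
(the suite checks > 90%), which is by construction: passing tests show
the pipeline learns and evaluates correctly on controllable signal, not
that the model ranks well on real orchard photographs.

## Pipelines and experiment design

- **Splits.** The generator emits train/test; the pipeline carves
  validation out of train (`val/(train+val)`, so (0.8, 0.1, 0.1) takes
  1/9 of train). Checkpoint selection is by best validation accuracy,
  earliest epoch on ties; with no validation split the final weights are
  kept.
- **Cross-validation** pools train+test and uses stratified k-folds
  (imbalanced many-class designs make plain folds degenerate); per-fold
  reports are averaged.
- **Metrics** come from the confusion matrix with one-vs-rest TP/FP/FN/TN
  per class; zero denominators report 0 with a warning. Accuracy equals
  support-weighted recall by construction, which the suite fuzz-checks.
- **The imbalance experiment** generates one 95:5 two-class easy-mode
  dataset (152 majority / 8 minority training images at 24 px, balanced
  test split), then trains the same seeded initialisation under each loss
  for 5 paired seeds and compares minority-class recall. Training runs 60
  epochs — enough for runs to leave the all-majority plateau and
  converge; shorter schedules land mid-transition, where run-to-run
  variance is bimodal (minority recall 0 or 1) and the comparison is
  uninformative.

### Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: a 12-px, 3-class fixture for unit tests; a 24-px, 3x64-image
overfit run (tiny config: 2 layers, `D = 32`, 2 heads, `mlp 64`, 30
epochs); the 95:5 imbalance experiment above; and manifest-only audits of
the three full-size presets.

## Known limitations

- On this scaled-down fixture MFCE shows **no measurable minority-recall
  advantage** over cross-entropy: at convergence both losses typically
  reach recall 1.0 (the comparison holds as a tie), and on a minority of
  seeds MFCE stalls permanently in the all-majority plateau where
  cross-entropy escapes. The loss's motivating claim concerns large-scale
  training on real photographic data and is not reproduced — or refuted —
  at this scale.
- The autodiff engine is eager and unfused; the reference-size model
  constructs and runs but is not practical to train on a laptop CPU. All
  shipped experiments use tiny configurations.
- The generator's lesion operators are stylised; classes are separable by
  low-order color/texture statistics, which is intentional but means
  results do not transfer to photographic difficulty.
- `stride` must equal the patch size (non-overlapping tiling); overlapping
  patch grids are out of scope.
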