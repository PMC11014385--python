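# Methods

## The problem

Multi-label image classifiers for dietary monitoring are trained on
annotations listing which ingredients appear in each image. Annotation
campaigns produce *noisy multi-labels*: some of an image's labels are wrong
while others stay correct. Plain binary cross-entropy (BCE) training
eventually fits the wrong labels (the memorization effect), hurting
generalization.

## The method

**Attentive feature MixUp (AFM).** A group-to-attend (GA) module randomly
pairs samples within a batch. Each member's pooled feature vector passes
through its own linear projection; the concatenated projections feed a
single linear unit whose sigmoid output is the pair's attention weight
`a ∈ (0, 1)`. The pair is interpolated in feature space,

    x = a·x_i + (1−a)·x_j,        y = a·y_i + (1−a)·y_j,

and the virtual samples train a second ("mixed") classification head. The
total loss is `L = λ·L_mix + (1−λ)·L_org` with `λ = 0.75`, where `L_org` is
BCE of the original head on the batch's hard labels and `L_mix` is BCE of
the mixed head on the soft labels. Because the attention weights are
optimized jointly with the classifiers, pairs containing mislabeled samples
can be down-weighted.

**CAM-driven refinement (AFCM).** In the multi-label setting a single
scalar `a` is wrong for labels individually: an ingredient that lands on the
*background* of its mixing partner stays recognizable, one that lands on the
partner's *food* does not. For each positive label `n` of image `i`,
Grad-CAM++ produces an activation map from the last conv layer; maps are
min–max normalized and binarized at `T1 = 0.5` (strict `>`; a constant map
binarizes to all zeros). The overlap ratio

    r_in = Σ(M_in ∧ union(M_j)) / Σ M_in

measures how much of the ingredient's area falls inside the union of the
partner image's food masks, and the per-label weights are

    a_il = a + (1−a)·(1−r_in)·T2,      a_ir = (1−a) + a·(1−r_jm)·T2,

with `T2 = 0.8`. Soft labels are `y_c = a_il,c·y_i,c + a_ir,c·y_j,c`,
clamped to [0, 1] (the clamp matters only for classes positive in both
parents; clamping keeps BCE targets valid probabilities). Features are
always mixed with the unrefined scalar `a`. `T2 = 0` reduces the whole
pipeline — bit for bit — to scalar MixUp.

Degenerate cases: an ingredient whose own binarized map is empty gets
`r = 1` (no boost — localization failed, so be conservative); a partner
image whose union mask is empty gives `r = 0` for the other image's
ingredients (maximal boost — they mix with pure background).

**Post-hoc Laplace (PAFCM).** After training, the original head's weights
get a Gaussian posterior `N(θ_MAP, H⁻¹)`. The curvature is the generalized
Gauss–Newton of the last layer under the per-class Bernoulli likelihood,
Kronecker-factored as `N·(B ⊗ A)` with input factor `A = E[φφᵀ]`
(`φ = [features; 1]`) and output factor `B = E[diag(p(1−p))]`. A scalar
prior precision τ is added on the Kronecker eigenvalues and tuned by
maximizing the Laplace evidence over log τ (coarse grid, then bounded
golden-section refinement). Prediction draws `K = 10` weight samples —
shared across the inputs of an evaluation run — and averages the sigmoid
outputs. As τ → ∞ the predictive collapses onto the MAP model. An
MC-Dropout predictor (dropout active at inference, mean of `K` passes) is
provided for comparison; both are strictly post hoc.

## Numerical core

No deep-learning framework is used: the package carries a small NumPy
neural-network core (im2col convolutions through BLAS, explicit backward
passes, SGD with momentum 0.9 and weight decay 1e-4), in float32. Gradients
are verified against central finite differences in the test suite. Because
every head is linear on globally average-pooled features, the gradient of a
class logit with respect to the last-conv activations is available in
closed form (head weight / number of spatial positions), so Grad-CAM++ runs
without a second backward pass; maps are treated as constants within a
training iteration (no gradient flows through the refinement weights).
Grad-CAM++ channel weights use the standard first/second/third-order
gradient combination with ReLU on pixel gradients; positions with a
vanishing denominator contribute nothing. Upsampling to input resolution is
bilinear via precomputed interpolation operators.

The default backbone is a four-block CNN (3×3 conv + ReLU, 2×2 max-pool
after the first three blocks; channels 8/16/32/64), giving an 8×8 last-conv
grid and 64-dimensional pooled features on 64×64 input. The backbone is a
pluggable contract — anything exposing last-conv activations and the logit
gradient works. Inference uses the original-feature head with sigmoid
probabilities thresholded at 0.5 (training-time mixing modules are removed
at test time, the usual MixUp-family convention); the mixed head remains
accessible via `predict_multilabel(head="mixed")`.

## Synthetic scenes

The generator emulates tray-style images: a near-uniform gray background
carrying 1–3 disjoint flat-colored shapes, each class a fixed
(shape, color) identity with mild per-instance jitter in size, position,
orientation (±10°) and color. Polygonal shapes are deliberately
orientation-bearing so rotation perturbations genuinely shift the test
distribution. Ground-truth pixel masks let the CAM machinery be scored
against an oracle. Label noise substitutes `round(rate × total positive
instances)` instances, pooled over the whole set and sampled without
replacement; the substitute class is drawn uniformly among classes absent
from both the current and the clean annotation, so the labels-vs-clean diff
counts altered instances exactly. Drop and add modes are also provided.

What the generator does *not* emulate: photographic texture, lighting,
occlusion, class imbalance, and — crucially — the scarce-class regime of
real food datasets (dozens of classes with a handful of examples each).
Passing tests on these scenes demonstrate the correctness and direction of
the mechanisms, not real-data performance.

## Desk-scale benchmark and what it shows

The bundled benchmark trains each arm on 400 scenes (six classes, 64×64)
with 30% substituted labels for 30 epochs (batch 32, lr 0.1 dropped ×0.1 at
epochs 15 and 22, random horizontal flip only). The learning rate is hotter
than the recipe used for a pretrained large backbone because the small CNN
trains from scratch; 0.01 leaves every arm far from convergence at this
step count. Milestones keep the 50%/75% schedule shape.

Across seeds the CAM-driven arm consistently fits the corrupted training
labels *less* than the plain-BCE baseline (lower F1 against noisy labels on
the noisy training subset) — the memorization direction. The *benefit*
direction (higher clean-test F1 than the baseline) does not reproduce at
this scale: a ~65k-parameter CNN cannot memorize individual samples in ~390
SGD steps, so uniform label noise largely averages out for the baseline,
while the mixing arm's original head — weighted `1−λ = 0.25` in the loss —
is systematically undertrained at equal step count. In scarcer synthetic
regimes (≥14 classes), where noise does hurt the baseline, no arm learns at
all without a pretrained backbone. The acceptance tests assert both
directions; the benefit test documents this limitation by failing honestly
rather than being weakened.

## Parameter summary

| Parameter | Default | Meaning |
|---|---|---|
| `T1` | 0.5 | CAM binarization threshold on the min–max-normalized map |
| `T2` | 0.8 | cap on the per-label weight boost (0 = scalar MixUp) |
| `λ` | 0.75 | weight of the mixed-head loss term |
| `lr / momentum / weight decay` | 0.1 / 0.9 / 1e-4 | SGD recipe (desk scale) |
| milestones | 50%, 75% of epochs | lr ×0.1 drops |
| noise rate | 0.2 (benchmark: 0.3) | fraction of positive instances corrupted |
| `K` | 10 | Monte-Carlo samples for the Laplace / MC-Dropout predictive |
| dropout p | 0.1 (off by default) | per-block dropout for the MC-Dropout variant |

## Known limitations

- Grad-CAM++ on a GAP+linear head has spatially constant gradients, so the
  map is a ReLU'd nonnegative channel combination — coarse (8×8 before
  upsampling) but sufficient on these scenes.
- The clamp on doubly-present classes and the `r = 1` / `r = 0` empty-mask
  conventions are design choices; alternatives (renormalization, skipping
  the pair) were not explored.
- KFAC treats the output curvature as shared across classes; it is exact
  here only when `p(1−p)` is constant (the tests exploit that case).
- Runtime scales with the number of positive labels per image (one CAM per
  ground-truth label per batch member that joins a pair).
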