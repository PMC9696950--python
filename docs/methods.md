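# Methods

## Model

The framework is a selective-prediction ensemble for three-class
pigmented-lesion diagnosis. A 3-class CNN (`s3`) makes a first
prediction; its reliability for a given image is estimated by comparing
its top-class probability *p_i* against the "belongs to class *i*"
probability *p_i′* of a one-vs-all CNN specialised in that class:
`u = |p_i − p_i′|`. Small *u* means two independently trained players
agree. Predictions are then grouped by thresholds α₁ ≤ α₂ —
high (`u ≤ α₁`), medium (`α₁ < u ≤ α₂`), uncertain (`u > α₂`) — and
routed: high keeps the stage-1 decision; medium defers to the single
one-vs-one duel of the two most probable classes; uncertain defers to
Max-Win voting over all three duels (each duel votes for its preferred
class, most votes wins). Final probabilities are renormalised to sum
to one.

Underlying assumptions: the one-vs-all players are decent estimators of
class membership (otherwise *u* is noise); the duels are stronger than
`s3` on their own pair, which is what makes deferral profitable; and
errors concentrate near the stage-1 decision boundary, which is where
medium/uncertain confidence lands.

### Conventions the grouping rule needs

The grouping boundaries as usually written overlap at α₁ and α₂, and the
step-by-step procedure uses strict inequalities. We fix: high is the
closed interval `[0, α₁]`, medium `(α₁, α₂]`, uncertain `(α₂, 1]`, so the
three groups partition `[0, 1]` for every valid threshold pair (a
property test enforces this).

Ties anywhere (argmax, top-2 selection, duel winners, Max-Win) break by
the fixed priority **M > B > N**: the framework exists to minimise missed
melanomas, so melanoma wins ambiguity. A 1-1-1 circular Max-Win tie
breaks first by the probability mass each class received over its two
duels, then by priority. The priority is configurable.

Renormalisation inputs: on the medium route, *p_i* and *p_j* come from
the selected duel and *p_k* (the excluded class) is carried over from
stage 1 — the procedure never states where *p_k* originates, and
carrying the stage-1 value preserves whatever mass stage 1 assigned it.
On the uncertain route each class is scored by its summed probability
across its two duels before renormalising. Both choices are internal
conventions; the predicted class never depends on them, only the
reported final probabilities do.

One published worked example reports a "confidence score of 54 %"
alongside a stage-1 melanoma probability of 0.53; that number is not
`|p_i − p_i′|` for any plausible *p_i′* and we treat it as a display
quantity. The confidence function here is implemented literally.

## Training recipe

All seven players share one recipe: weighted cross-entropy
`L = −w_i log q_i` with inverse-sample-count class weights; Adam;
cyclical "triangular2" learning rate `1e-5 … 1e-3` with step size 2 000
iterations (the triangular wave's amplitude halves each cycle); early
stopping when validation balanced accuracy has not improved for 15
epochs, returning the best checkpoint; and partial-depth fine-tuning of
the deepest 64 % of parameterized layers.

Choices the recipe leaves open, fixed here:

* **Weight normalisation.** Inverse-count weights are rescaled to mean 1
  so loss magnitudes stay comparable across the seven tasks (the
  3-class, one-vs-all and one-vs-one datasets have very different
  sizes).
* **"64 % of the deeper layers".** Interpreted as freezing the first
  `floor(0.36 · L)` of the `L` parameterized layers in definition order;
  the fraction is configurable since layer-counting conventions differ
  between backbones.
* **Loss clamping.** `log q` is clamped at `q = 1e-12`.
* **Head initialisation.** New softmax heads (2 or 3 nodes) use Kaiming
  fan-in normal initialisation.
* **Adam moments.** β₁ = 0.9, β₂ = 0.999, ε = 1e-8 (the conventional
  defaults; the recipe does not specify them).

### The backbone and the optimizer

The backbone is pluggable (`backbone_factory`). The bundled desk-scale
backbone is a three-block CNN (3×3 convolutions, ReLU, two 2×2 max
pools, global average pooling, dense softmax head) implemented in
`dermroute.nn` with explicit forward/backward passes, alongside an Adam
optimizer. Writing the network layer-by-layer keeps activations and
exact gradients of any layer accessible, which the class-activation maps
require, and a finite-difference oracle in the test suite verifies the
gradients to 1e-3. An EfficientNet-class backbone can be adapted for
full-scale runs; nothing in the routing, recipe or evaluation depends on
the backbone.

## Preprocessing

Per class: a random 70/10/20 train/validation/test split, with
validation and test sizes rounded **half-to-even** and training taking
the remainder — the only rounding convention consistent with the
reference per-class split table (e.g. 6 705 × 0.1 = 670.5 → 670).
Training data is then augmented **offline** to fixed per-class targets
(2 000 / 2 000 / 5 000 at full scale) by randomly composing horizontal
flip, vertical flip, rotation and width/height shift of randomly chosen
originals. Magnitudes are not specified by the recipe; we use ±90°
rotation and ±10 % shifts, common for dermoscopy, both configurable.
Augmentation happens after splitting and only on the training split.
Images are color-corrected with the gray-world constancy algorithm
(each channel scaled by global-mean / channel-mean), then stretched —
not letterboxed — to a square input with bicubic interpolation
(456 px at full scale, 32 px in the desk-scale experiments), and scaled
to `[−0.5, 0.5]` floats.

## Grad-CAM

For class score *y_c* (the pre-softmax logit) and the K feature maps
*A_k* of the last convolutional stage, weights are the spatial means of
`∂y_c/∂A_k` and the map is `ReLU(Σ_k w_k A_k)`. The raw u×v map is kept
for quantitative use; display maps are bicubically upsampled to input
resolution (matching the resize choice elsewhere), min-max scaled and
blended with the image through a colormap. Rendering never mutates the
raw map.

## Evaluation

Balanced accuracy (BACC) is the unweighted mean of per-class
sensitivities, appropriate under the ~75 % nevus prevalence. AUROC is
one-vs-rest per class with midrank tie handling, plus the macro mean;
ROC curves are staircase curves whose trapezoidal area equals the AUROC
by construction (asserted on every input in tests). Repeated runs
aggregate as mean ± sample standard deviation (ddof = 1), reported at
two decimals.

The threshold grid search runs the full routed framework at every
(α₁, α₂) pair of a grid — default `{0.1, 0.2, 0.3} × {0.3, 0.4, 0.5}`
restricted to α₁ < α₂ — on the validation split and maximises either
framework BACC (default) or melanoma AUROC; both objectives appear in
the method's own description and we expose both rather than guess. Ties
prefer smaller α₁, then smaller α₂ (less deferral for equal accuracy).

## Synthetic data and mock players

The image generator renders class-coded lesions on a skin-toned
background with acquisition-like illumination gradients: nevi are
smooth, uniformly brown ellipses; melanomas have irregular star-like
borders, dual colouring (dark brown / blue-gray) and an off-center pale
regression region; keratoses are sharply bounded plaques with
keratin-plug speckle. These cues deliberately parallel the clinical
features dermatologists use, so heat-map localization tests are
meaningful. A `separability` dial in [0, 1] scales additive noise;
at 1.0 a 10-image nearest-centroid baseline exceeds 90 % accuracy
(tested), at 0 classes are indistinguishable. What the generator does
**not** emulate: hair and ruler artifacts, specular highlights, lesion
scale variation, camera color profiles, and the long-tailed difficulty
distribution of real dermoscopy — so passing desk-scale tests
demonstrates the machinery is correct, not that clinical performance
would transfer.

Mock players draw their outputs from per-true-class Dirichlet
distributions — the simplest family giving valid probability vectors
with tunable confusion and confidence — reproducibly per (seed, sample,
player). The "confusable" bundle engineers the structure the framework
targets: the 3-class player lands near the B/M boundary on melanomas and
keratoses, the one-vs-all players disagree with it there (pushing *u*
into the medium band), and the B/M duel is accurate; nevi are easy for
everyone. Under thresholds (0.1, 0.5) the framework then repairs most
stage-1 M↔B errors, and beats the 3-class player alone in ≥95 % of
random replicates (tested over 20 seeds).

## Study conditions of the desk-scale experiment

`run_desk_experiment` fixes the package's reference conditions: 100
images per class at 32 px, separability 0.8, 70/10/20 split, training
augmented to 150 per class, tiny-CNN backbone, batch 16, up to 25
epochs, CLR step 80 iterations, patience 8, grid search by BACC. These
sizes make the full seven-player pipeline reproducible in about 90
seconds on one CPU while leaving enough signal for high held-out
accuracy (framework BACC 0.97 at the reference seed; training draws at
other seeds can land lower, since 25 epochs on 60-image binary tasks
leaves real variance). All randomness (generation,
splitting, augmentation, initialisation, batching) derives from a single
seed through independent seed streams.

## Known limitations

* Full-scale results on real dermoscopy require a pretrained
  large-capacity backbone and the real dataset; this package ships the
  machinery and its desk-scale validation, not those results.
* The confidence function is a single absolute difference; it inherits
  any shared bias between `s3` and the one-vs-all players (both see the
  same training distribution), and can be overconfident when both are
  wrong together.
* Offline augmentation to fixed targets reflects the reference
  pipeline; online augmentation may behave differently at full scale.
* On the synthetic classes the 3-class player is often already
  near-ceiling, so the routed framework's advantage is demonstrated on
  engineered confusions rather than on the synthetic images themselves.
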