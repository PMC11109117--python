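# Methods

## Pipeline

An input photograph is analysed twice, independently:

- **Segmentation (cascade).** Stage 1 is a binary U-Net (lesion vs normal);
  stage 2 a seven-way U-Net over codes 0–6 (background plus the six lesion
  subcategories). Both stages see the full image; the stage-2 label map is
  then masked by the stage-1 lesion mask, so a pixel the binary stage calls
  normal is always code 0 in the final map. Running stage 2 on the full
  image (rather than on cropped lesion regions) preserves spatial context
  and keeps the composition a pure function of the two per-pixel maps;
  restricting the stage-2 *loss* to lesion pixels is available via
  `TrainConfig(lesion_pixels_only=True)` but full-image loss is the default.
- **Stratification.** A residual-block classifier (stem convolution, two
  residual stages, global average pooling, 4-way softmax head) produces the
  probability vector P over {normal, infection, ulcer, gangrene}. The name
  "necrosis" is accepted as an input alias of gangrene so both clinical
  vocabularies work.
- **Scoring.** With per-family areas S_i = S_i1 + S_i2 (shallow + deep
  pixels) from the final label map and probabilities P_i from the
  classifier:

      a_i = S_i / Σ S_i,
      X_i = W_i · P_i · (W_i1·S_i1 + W_i2·S_i2) / Σ S_i,
      V   = C · Σ X_i + ε.

  The score depends on area *shares*, not absolute pixel counts, so it is
  invariant to image resolution (homogeneity). With W_i = W_i1 = W_i2 = 1
  and P_i = 1 the inner terms telescope and V = C + ε, which pins the
  nominal scale.

### Scoring decisions where the design was open

- **P_i is the raw softmax probability** of the matching class. A variant
  that renormalizes P over the three lesion classes is available
  (`renormalize_probs=True`); it makes V independent of the normal-class
  probability mass, which can be preferable when lesion presence is already
  established, but the raw form is the default because the formula consumes
  the stratifier's output directly.
- **ε is a global constant** from the weight configuration, not adapted
  per image; no adaptation rule is defined, and a constant keeps the score
  a pure function of (areas, probabilities, weights).
- **V is not clamped** by default — scores above C are meaningful (large,
  confident, heavily weighted deep lesions); an optional `clamp=True`
  restricts to [0, C].
- **Lesion-free images** (Σ S_i = 0) are a valid class, not an error: the
  ratio-level functions raise `NoLesionError`, and `total_score` /
  `score_image` return V = ε with `no_lesion=True`.
- **Weight defaults** — W = (ulcer 1.0, infection 1.0, gangrene 1.5),
  W_i1 = 1.0, W_i2 = 2.0, C = 100, ε = 0 — encode the clinical severity
  ordering (gangrene worst, deep worse than shallow) on a 0–100 nominal
  scale. They are *not* calibrated against any clinical reference and are
  labelled non-canonical; every report carries a hash of the weight set
  used.

## Compute engine

No GPU framework is used: `scoredfu.nn` implements conv2d (im2col matmul),
ReLU, 2×2 max-pool, nearest-neighbour upsampling, global average pooling,
linear heads, softmax cross-entropy, soft-Dice loss and Adam in plain
float32 NumPy with hand-written backward passes (verified against finite
differences in the test suite). This keeps every run single-threaded
deterministic: the same seed gives byte-identical histories, checkpoints
and predictions. Grad-CAM falls out of the same machinery — the classifier
caches the last residual block's activations on the forward pass and their
gradient on the backward pass; channel weights are the spatially averaged
gradients, and the rectified weighted sum is max-normalized and upsampled
to image size.

Numerical conventions: per-pixel argmax breaks exact ties toward the lowest
code; input images are scaled to [0,1] and standardized with fixed constants
(mean 0.5, SD 0.25) recorded in the model config; He-normal initialization;
max-pool routes gradient to the first maximum on exact ties.

"Pretrained" backbones are implemented as warm starts: `pretrained=<path>`
copies the encoder (segmenter) or everything below the head (classifier)
from an existing checkpoint, e.g. reusing the binary-stage encoder for the
subcategory stage. Random initialization is the default.

## Synthetic scenes

The generator emulates the structure of clinical DFU photograph datasets:
a foot-shaped skin ellipse on a dark backdrop, 1–3 lesion blobs per
non-normal scene with irregular boundaries (random angular harmonics),
optional low-frequency skin shading, and additive Gaussian pixel noise
(σ = 6 RGB units). Each subcategory has a fixed mean colour; the minimum
pairwise distance between subcategory means is ≈57 RGB units, far above the
noise scale, so colour statistics alone separate the classes. Level-2
(deep/extensive) subcategories are darker and drawn with a larger radius
prior than level-1, encoding depth and extent in both appearance and size.
Blob overlap is resolved by list order (later wins). A scene's severity
label is the most severe family with nonzero *realized* area (gangrene >
ulcer > infection > normal), which keeps "normal ⇔ all areas zero" true
even when one blob fully occludes another. Dataset class counts follow
largest-remainder rounding of the requested mix.

What this does **not** emulate: photographic realism, camera angle and
distance variation, partial foot views, lighting changes, skin-tone
diversity, or lesions whose classes are distinguishable only by texture.
Models that pass the desk-scale tests have learned colour-separable
classes at 64×64; this validates the pipeline's mechanics and learning
machinery, not clinical performance.

## Evaluation

- Zero-denominator metrics (e.g. precision with no positive predictions)
  return 0.0 and emit a warning; the Dice of two empty masks is 1.0.
- Mean IoU excludes classes absent from both maps (their IoU is 0/0);
  when every class occurs the value equals the plain (k+1)-class mean.
- Multi-class summaries are macro-averaged by default; micro and
  support-weighted variants are reported alongside.
- The 7:2:1 stratified split assigns per-class counts by largest-remainder
  rounding; exact remainder ties are settled by the globally most
  under-allocated split, so per-class counts are within one item of their
  shares *and* overall totals sit on the 7:2:1 marks.
- Agreement uses Bland–Altman bias and 1.96·SD limits with a Wilcoxon
  signed-rank test (paired t-test behind a flag); significance bands are
  * p<0.05, ** p<0.01, *** p<0.001. All-zero differences give p = 1.
- ROC/AUC are one-vs-rest per class, delegated to scikit-learn.

## Desk-scale experiment sizes

`scoredfu.experiments` fixes the study conditions used by the tests and the
reproduction script: 64×64 scenes; segmentation on 200 scenes (binary and
seven-way U-Nets, width 8, depth 2, 8 epochs, Adam 3e-3, batch 8);
classification on 400 scenes (width 12, 15 epochs, Adam 1e-2 with a single
0.3× decay two-thirds through, batch 16); 7:2:1 train/validation/test
splits; three independent seeds for the stochastic learning measurements.
The classifier's width and one-step decay were chosen for stable
convergence of the small backbone; at width 8 or without decay, occasional
seeds stall below ceiling.

## Known limitations

- The synthetic domain is colour-dominated; texture-only distinctions are
  absent, so subcategory confusion there underestimates the clinical
  difficulty.
- The NumPy engine targets small models at small resolutions; it is not
  suitable for full-resolution clinical training (no GPU, no
  parallelism), though the architecture is config-scalable.
- Score weights are uncalibrated defaults; clinical use would require
  fitting W, C and ε against expert ratings.
- The cascade's two stages are trained independently; no joint fine-tuning.
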