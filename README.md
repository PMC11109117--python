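# scoredfu

Objective severity scoring of diabetic foot ulcer (DFU) photographs.

Clinical grading of DFU photographs is slow and varies between raters. This
package implements an automated assessment pipeline that turns an RGB
photograph of a foot into a single severity score with full provenance:

1. **Two-stage lesion segmentation** — a binary U-Net first separates lesion
   from normal skin; a second, seven-way U-Net then labels each lesion pixel
   as one of six subcategories (Ulcer1/2, Infection1/2, Gangrene1/2 — two
   depth levels per lesion family). The subcategory map is gated by the
   binary mask, and per-subcategory pixel areas are read off it.
2. **Four-class severity stratification** — a small residual-block classifier
   produces a probability vector P over {normal, infection, ulcer, gangrene}
   ("necrosis" is accepted as an alias of gangrene), with Grad-CAM saliency
   maps for inspection.
3. **Scoring** — areas and probabilities are fused into the score

   ```
   a_i = S_i / Σ_i S_i
   X_i = W_i · P_i · (W_i1·S_i1 + W_i2·S_i2) / Σ_i S_i
   V   = C · Σ_i X_i + ε
   ```

   where i ranges over the three lesion families, S_i1/S_i2 are the
   shallow/deep pixel areas of family i, W are configurable weights, C sets
   the scale and ε is an additive adjustment. With unit weights and unit
   probabilities, V = C for any lesion layout; a lesion-free image scores
   V = ε. The shipped weights (gangrene 1.5×, deep levels 2×, C = 100,
   ε = 0) respect severity ordering but are not clinically calibrated.

Because clinical DFU datasets are not redistributable, the package ships a
deterministic **synthetic scene generator** (`scoredfu.synth`) that renders
foot-like scenes with lesion blobs whose colour statistics separate the six
subcategories, together with pixel-exact label maps and severity labels. The
entire pipeline is trainable and verifiable end-to-end on these scenes.
All models run on a hand-written NumPy compute engine (`scoredfu.nn`) —
convolutions, U-Net skip connections, residual blocks, Adam — so training is
CPU-only and bit-reproducible for a fixed seed.

## Worked example

```python
from scoredfu.synth import SceneSpec, BlobSpec, generate_scene
from scoredfu.types import Subcategory, ClassProbabilities, ScoreWeights
from scoredfu.scoring import total_score

spec = SceneSpec(64, 64, blobs=(
    BlobSpec(Subcategory.ULCER2, (24, 22), 9, 0.2),
    BlobSpec(Subcategory.GANGRENE1, (40, 38), 7, 0.2),
), seed=5)
img, truth = generate_scene(spec)
print(truth.areas.as_dict())
# {'ulcer1': 0, 'ulcer2': 253, 'infection1': 0, 'infection2': 0,
#  'gangrene1': 154, 'gangrene2': 0}

probs = ClassProbabilities(0.02, 0.08, 0.30, 0.60)
bd = total_score(truth.areas, probs, ScoreWeights())
print(round(bd.a_ulcer, 4), round(bd.a_gangrene, 4), round(bd.v, 2))
# 0.6216 0.3784 71.35
```

The deep ulcer covers 253 of the 407 lesional pixels (a_ulcer = 0.62) and
the localized gangrene the remaining 154 (a_gangrene = 0.38). The gangrene
family contributes X = 0.34 despite its smaller area because its family
weight is 1.5 and the classifier is confident (P = 0.6); the total lands at
V = 71.4 on the nominal 0–100 scale.

The same pipeline is available from the shell:

```bash
scoredfu synth --n 200 --seed 7 --out data/
scoredfu train --which binary     --data data/ --out ckpt/binary.npz     --seed 7
scoredfu train --which multiclass --data data/ --out ckpt/multiclass.npz --seed 7
scoredfu train --which classifier --data data/ --out ckpt/classifier.npz --seed 7
scoredfu score data/scene_00000.png \
    --binary-ckpt ckpt/binary.npz --multiclass-ckpt ckpt/multiclass.npz \
    --classifier-ckpt ckpt/classifier.npz --out reports/
scoredfu evaluate --pred preds/ --truth truths/ --out report.json
```

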