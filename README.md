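# npcscreen

Two-stage deep-learning screening of nasopharyngeal biopsy whole-slide
images (WSIs), built as a reusable, tested framework and exercised end to
end on synthetic annotated slides.

Nonkeratinizing nasopharyngeal carcinoma (NPC) is difficult histology:
poorly differentiated tumor cells sit in dense lymphoid stroma, and benign
structures — germinal centers, surface epithelium — mimic tumor nests.
`npcscreen` implements the standard two-stage answer for pathologists'
workflows:

1. **Patch level.** 256×256 px patches are cropped dynamically from
   free-hand polygon annotations of tumor, benign tissue and background.
   Benign/background patches must lie 100 % inside the annotated union;
   tumor patches need ≥ 50 % tumor coverage.  A small residual CNN with a
   3-way softmax head is trained on balanced batches of 48 (16 per class)
   with SGD + Nesterov momentum (lr 0.0017, momentum 0.95) and a
   reduce-on-plateau schedule.
2. **Slide level.** Each slide is tiled without overlap; per-tile class
   probabilities are reassembled into a probability map (one pixel per
   tile, channels = P(NPC), P(benign), P(background)), stacked with a
   tile-aligned thumbnail, and fed to a free-input-size residual CNN
   (global average pooling before the 2-way head).  Training resizes each
   balanced batch of 8 (4 NPC + 4 benign) to one of six target shapes
   drawn at random; at test time the slide score is the mean NPC
   probability over all six shapes.

Around the two models the package provides: a synthetic H&E-like slide
generator with five annotatable region kinds and exported GeoJSON polygon
ground truth; Grad-CAM attribution for auditing which pixels drive a tumor
call; ROC/AUC evaluation with the repeated-inference two-model comparison
(per-run AUCs + two-tailed Welch t-test); and a CLI over the whole
pipeline.  Everything a formula could touch is tested against an
independent oracle (exhaustive pair enumeration for AUC, permutation test
for the t-test, pixel-center scanlines for geometry, float64 central
differences for the network gradients).

Who it is for: researchers who want a transparent, dependency-light
reference implementation of patch-based WSI classification — every stage
from annotation geometry to slide-level ROC is plain NumPy/SciPy/sklearn
and readable in an afternoon — and anyone who needs a controllable
synthetic benchmark for histology tooling.

## Worked example

```python
import numpy as np
from npcscreen import (SlideSpec, generate_slide, SlideDataset,
                       PatchClassifier, TrainingClass)
from npcscreen.slide_pipeline import build_probability_map

slides = [generate_slide(SlideSpec(width=1280, height=1024,
                                   tumor_fraction=0.18, seed=s, label="NPC"))
          for s in (0, 1, 2)]
slides += [generate_slide(SlideSpec(width=1280, height=1024, tumor_fraction=0.0,
                                    seed=s, label="BENIGN"))
           for s in (100, 101, 102)]
ds = SlideDataset.from_slides(slides)

est = PatchClassifier(max_steps=400, eval_interval=100, seed=1)
est.fit(ds)
print(est.curves_[["step", "train_loss", "val_loss", "val_auc"]].tail(2))

pmap = build_probability_map(est, slides[0].image)
print("map shape:", pmap.grid.shape)
print("NPC channel:\n", np.round(pmap.grid[:, :, 0], 2))
```

Output from this exact script:

```
   step  train_loss  val_loss  val_auc
2   300    0.030732  0.039063      1.0
3   400    0.011536  0.010290      1.0
map shape: (4, 5, 3)
NPC channel:
 [[0.   0.   0.   0.25 0.01]
 [0.   0.05 0.05 1.   0.89]
 [0.17 0.01 0.01 0.23 0.02]
 [0.01 0.01 0.01 0.   0.  ]]
```

The learning curve rows show the loss falling and the validation AUC
(tumor vs rest) saturating; the probability map is 4×5 because a
1280×1024 slide tiles into ceil(1024/256) × ceil(1280/256) windows, and
its NPC channel lights up only on tiles overlapping the simulated tumor
nests.

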