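# plaqueangle

Angle-wise (cross-sectional) prediction of lipid-rich and calcified
coronary plaque on CT angiography-like vessel images.

## The problem

On contrast-enhanced coronary CT, the Hounsfield-unit (HU) range of
lipid-rich plaque overlaps fibrotic tissue and surrounding myocardium,
and calcified plaque overlaps the contrast-filled lumen (the conventional
350 HU cut separating calcium from lumen fails whenever lumen intensity
is high).  Intravascular reference imaging (NIRS-IVUS) reports plaque as
*angles* — a chemogram gives, for every pullback position and every
degree around the vessel, the probability that lipid-rich plaque is
present — but carries no reliable depth.  `plaqueangle` implements a
pipeline that predicts this angular plaque distribution per
cross-sectional frame and evaluates it the same way:

- **Pie-shaped labels.**  A per-frame angular probability profile
  `p(α), α ∈ {0,…,359}` is thresholded at 0.6 and rasterized into a
  binary wedge mask radiating from the lumen center (no depth encoded).
- **Two predictors.**
  1. A two-branch dense encoder–decoder **segmenter** on Cartesian
     128×128×7 blocks (7 consecutive frames give longitudinal context),
     trained with a distance-weighted binary cross entropy
     `L = mean(w · BCE(ŷ, y)) + λ‖K‖²`, where the pixel weight `w` is
     inversely related to the distance from the lumen center and `‖K‖²`
     is the l2 norm of the convolution kernels.
  2. A polar-domain angle-interval **detector** on 45×360×7 polar blocks
     (radius 0–5.625 mm × angle 0–359°).  Anchor intervals tile the angle
     axis only; the four-term loss is
     `BCE(fg/bg) + L1(angle) + BCE(class) + L1(angle refined)` with
     angles normalized by 360.  There is no mask head.
- **Spread-out views.**  Per-frame profiles are stacked into a 360×N
  angle-by-frame matrix; element `(α, n)` is the probability of plaque at
  angle α on frame n.  Operating points: segmenter 0.6 for both classes,
  detector 0.3 (lipid) and 0.5 (calcified).
- **Lesion-level metrics.**  A lesion is a maximal run of frames with
  plaque burden ≥ 40%.  Accuracy and F1 are computed on the binarized
  spread-out views restricted to the lesion's columns.

Because clinical CTA + NIRS-IVUS data cannot be redistributed, the
package ships a **phantom generator**: synthetic vessel stacks in HU
(lumen 450, wall 60, lipid 30, calcium 800, Gaussian noise) with known
per-degree angular occupancy, 0.30 mm frame increments, and lesion tables
— every downstream stage is testable against exact ground truth.

Training runs on a small numpy reverse-mode autograd engine bundled with
the package (`plaqueangle.nn`), sized for CPU-scale phantom experiments.

## Worked example

```python
import numpy as np
from plaqueangle import evaluation, geometry, models, phantom, spreadout

# 1. Simulate a 200-frame vessel with randomized calcified/lipid lesions
config = phantom.synthetic_vessel_config(n_frames=200, seed=0)
stack, ground_truth, lesion_table = phantom.generate_stack(config)

# 2. Train the small two-branch dense U-Net (5 epochs, desk scale)
seg_cfg = models.SegModelConfig(base_channels=8, growth_rate=4, dense_block_layers=1)
train_cfg = models.TrainConfig(epochs=5, batch_size=2, learning_rate=3e-3, seed=0)
model, curve = models.train_segmenter(stack, ground_truth, seg_cfg, train_cfg)

# 3. Predict a held-out vessel, assemble spread-out views, evaluate lesions
ho_stack, ho_gt, ho_table = phantom.generate_stack(phantom.synthetic_vessel_config(60, seed=1))
profiles = {c: [] for c in phantom.PLAQUE_CLASSES}
for f in range(ho_stack.n_frames):
    pred = models.predict_segmenter(model, geometry.build_block(ho_stack, f, "cartesian"))
    for c in profiles:
        profiles[c].append(spreadout.segmentation_to_profile(
            pred, c, (63.5, 63.5), ho_stack.pixel_spacing_mm, (1.5, 3.0)))
preds = {c: spreadout.binarize_spreadout(
    spreadout.assemble_spreadout(profiles[c], 60, c), spreadout.SEGMENTER_THRESHOLDS[c])
    for c in profiles}
gts = {c: spreadout.binarize_spreadout(spreadout.ground_truth_spreadout(ho_gt, c, 60), 0.6)
       for c in profiles}
lesions = evaluation.extract_lesions(phantom.burden_per_frame(ho_table, 60))
result = evaluation.summarize(evaluation.evaluate_lesions(preds, gts, lesions, method="dense-unet"))
print(result.format_median_mean())
```

Output (about a minute on one CPU):

```
200 frames, 12 lesions, 0.09 mm/px, 0.3 mm/frame
loss: 0.772 -> 0.383
          dense-unet   calcified  accuracy  0.86 (0.86)
          dense-unet   calcified        f1  0.70 (0.69)
          dense-unet       lipid  accuracy  1.00 (1.00)
          dense-unet       lipid        f1  1.00 (1.00)
```

The `median (mean)` lines mirror the conventional reporting layout.  The
high-contrast calcified arcs (800 HU against a 60 HU wall) are learned
within five epochs; lipid scores on this held-out vessel are dominated by
lesions without lipid ground truth, where an empty prediction counts as a
perfect match.  A `plaqueangle` console command exposes the same pipeline
as `simulate | train | predict | evaluate | report` subcommands driven by
a YAML config (see `plaqueangle --help`).

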