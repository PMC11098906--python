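# Methods

This note documents the models, conventions, numerical choices and known
limitations of `plaqueangle`.  It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Angular conventions

All modules share one convention: angle 0° lies along the +x image axis
and increases counter-clockwise in standard display (y down on screen),
i.e. the mathematical angle of `(-Δy, Δx)`.  Degree bins are half-open
`[a, a+1)`; a pixel lands in bin `floor(angle)`.  The pixel exactly at
the lumen center has no defined angle and is assigned bin 0 — a
measure-zero tie-break.  Arcs are half-open `[start, end)` degree
intervals; `end < start` wraps through 0°, and the full circle is written
`(0, 360)`.  Rotation augmentation uses integer angles only so that the
matching label transformation is an exact circular roll of the 360-bin
profile — no fractional-bin label interpolation ever occurs.

## The phantom generator

The generator emulates the statistical and geometric structure of
contrast CTA cross-sections co-registered with chemogram-style angular
plaque labels:

| parameter | default | rationale |
|---|---|---|
| image size / spacing | 128 px, 0.09 mm/px | the 5.625 mm polar extent (62.5 px) fits the frame |
| frame increment / slice | 0.30 mm / 0.50 mm | clinical MPR reconstruction geometry |
| lumen HU | 450 | contrast-filled lumen, above the 350 HU calcium cut |
| wall / myocardium HU | 60 | soft-tissue attenuation |
| lipid HU | 30 | low attenuation, overlapping the fibrotic range |
| calcium HU | 800 | well above the 350 HU threshold |
| noise SD | 20 HU (15 in the cohort generator) | iterative-reconstruction-level noise |
| lumen radius / wall | 1.5 mm / 1.5 mm | mid-size epicardial vessel |

Plaque arcs are painted into the wall annulus only — the angular ground
truth says nothing about depth, so tissue depth is a free choice — while
ground-truth profiles record the requested per-degree probability
exactly.  Same-class overlapping arcs merge (per-bin maximum); where
lipid and calcified arcs overlap spatially, calcium wins the painted HU
(it dominates CT appearance).  `synthetic_vessel_config` builds a
randomized multi-lesion vessel: lesions of 8–14 frames separated by 4–8
normal frames, each with a 60–140° calcified arc (probability 0.9) and,
with probability 0.5, an opposite-side 50–110° lipid arc; burden 0.6.
Lesion sizes (2.4–4.2 mm) and arc widths were chosen once as plausible
for obstructive coronary disease.

What the phantom does **not** emulate: partial-volume and blooming
artifacts, eccentric remodeling, catheter/registration error beyond
optional center jitter, anatomical background structure, and the
real-data ambiguity between lipid and fibrotic tissue beyond simple HU
overlap.  Passing tests therefore demonstrate pipeline correctness and
learnability under separable contrast, not clinical performance.

## Labels

* **Pie masks**: profile thresholded at 0.6 (the chemogram operating
  point), then rasterized: a pixel is set iff its bin is occupied and its
  radius ≤ 5.625 mm.  The rasterizer is vectorized; tests compare it to a
  per-pixel `atan2` loop for exact equality.
* **Weight maps**: the sample weight is "inversely proportional to lumen
  distance" with no stated constant or functional form, so two bounded
  forms are offered: `inverse` (default) `w_max / (1 + d/d0)` with `d0`
  set to the lumen radius in pixels, and `linear-decay`
  `max(w_min, w_max(1 − d/d_max))`.  Both are radially symmetric, maximal
  at the center, non-increasing and strictly positive; `w_max = 10`.
* **Angle boxes**: maximal runs of above-threshold bins, merged across
  the 359→0 seam; the box score is the mean profile value over the run
  (ground-truth boxes are used with score 1 in training targets).
* **Frame filters**: segmentation training keeps every frame (normals are
  negatives); detection training drops frames with no plaque and frames
  where any present class occupies fewer than 10°.

## Models

Both predictors run on `plaqueangle.nn`, a small float32 reverse-mode
autograd engine written on numpy (stride-1 same-padding convolutions with
odd kernels, factor pooling/upsampling, dropout, Adam).  The engine was
written for this package so the full training loop is dependency-light
and reproducible on one CPU; its gradients are verified against central
finite differences and its convolution against an independent
correlation oracle.

**Segmenter** (dense U-Net): a full-resolution stem convolution, then
DenseNet-style blocks (each 3×3 convolution sees the concatenation of the
block input and all previous outputs) at 1/2, 1/4 and 1/8 resolution;
50% dropout on the bottleneck output (the final encoder layer); two
nearest-upsample + skip-concatenation decoder stages; a 1×1 head
upsampled to full resolution.  The two output channels (lipid,
calcified) are independent sigmoids, not a softmax, because the tissues
co-occur on mixed frames.  Keeping dense blocks off the 128² grid is what
makes CPU training practical; angular profile extraction is insensitive
to the resulting 2-px blockiness.  Loss: `mean(w · BCE) + λ‖K‖²` with
λ = 1e-5 by default.  Inputs are normalized as `(HU − 60)/400`.

**Detector**: a four-convolution backbone over the polar plane with
angle-axis pooling 360→45 and radius pooling 45→5, then a mean over the
radial axis — anchors carry no depth, so every proposal spans the full
radial extent by construction.  Anchors: 45 centers every 8°, widths
(20, 60, 120, 240, 360)°, 225 anchors per frame.  Two 1×1 heads: a
proposal head (foreground logit + 2 angle-regression outputs) and a
refinement head (2 class logits + 2 refined angle outputs); no mask head
exists anywhere in the network.  Regression targets are normalized:
(circular center offset /360, width offset /360) relative to the anchor.
Matching uses exact circular interval IoU with positive/negative
thresholds 0.5/0.3 and best-anchor forcing per target.  Decoding applies
per-class score thresholds (score = foreground × class probability) and
greedy circular NMS (ties: wider box, then lower start angle; boxes of
different classes never suppress each other).

**Training**: Adam, learning rate 1e-4, 50 epochs, batch 32 by default;
batches drawn class-balanced at lipid : calcified : mixed : normal =
3 : 1 : 1 : 5.  Since 32 is not divisible by the ratio sum, each batch
slot draws its class i.i.d. with ratio-proportional probabilities —
the simplest policy consistent with a per-batch ratio.  Ratios
renormalize (with a warning) when a class is absent.  Rotation
augmentation rotates all 7 block frames about the window center by a
random integer angle and rolls the label profiles identically.  A
non-finite loss aborts with diagnostics.

Smoke-scale runs use 200 phantom frames, batch 2, learning rate 3e-3
and a base width of 8 channels: small batches turn the short epoch
budget into enough optimizer steps to reach confident calcified
predictions.  The test suite trains 5 epochs (about half a minute on one
CPU); `scripts/acceptance.py` uses 12 epochs (about a minute), which
keeps the sigmoid confidence comfortably past the 0.6 operating point
across phantom seeds rather than only for the fixed test seed.

## Spread-out views and evaluation

Segmenter maps reduce to per-frame profiles by aggregating (max by
default; mean available) over pixels in a radial band about the lumen
center — default the phantom's wall band, 1.5–3.0 mm.  Max is robust to
thin plaques at any depth within the band.  One-degree bins that contain
no pixel center (possible in thin bands along the diagonals) inherit the
circularly nearest occupied bin.  Detector boxes paint their score over
their angular span; overlaps keep the maximum.  Binarization applies the
operating points (segmenter 0.6/0.6, detector 0.3/0.5); metrics are
computed on binarized views — the natural reading of threshold-based
reporting, stated here explicitly since the placement is otherwise
ambiguous.

Lesions are maximal runs of frames with burden ≥ 0.40.  Accuracy
`(TP+TN)/all` and `F1 = 2TP/(2TP+FP+FN)` are computed over the 360×length
grid of each lesion.  If a lesion's ground-truth view is empty, F1 is
defined as 1.0 for an empty prediction and 0.0 otherwise, keeping
per-lesion metrics total.  Summaries report median and mean per class
and method in `median (mean)` format, with violin + box figures (the
violin is omitted for degenerate all-identical distributions, where the
box plot alone is drawn).

## Numerical choices

* Bilinear interpolation for intensities, nearest for binary masks;
  samples outside the source image are edge-clamped by default, with an
  optional constant fill.  The polar→Cartesian direction pads the angle
  axis with its wrap-around neighbours so interpolation is seamless at
  0/360; radii beyond 5.625 mm take the fill value.
* 2.5D blocks replicate-pad the terminal frame so depth is always 7.
* The Cartesian 128-window is centered on the lumen center, making the
  network input vessel-centric and consistent with wedge labels.
* BCE probabilities are clipped to `[1e-6, 1 − 1e-6]` (engine precision
  is float32; the pure-numpy reference loss forms compute in float64).
* Angular IoU is computed exactly on continuous intervals, wrap-aware.

## Limitations

* The engine is single-threaded dense numpy; it is sized for phantom
  experiments, not clinical volumes.
* Lipid-rich arcs (30 HU vs 60 HU wall at 15–20 HU noise) are much
  harder than calcified arcs; the desk-scale smoke runs demonstrate
  learnability only for the calcified class, and held-out lipid scores
  are often dominated by the empty-ground-truth convention.
* Real-data ingestion stops at NIfTI/TIFF stacks with per-frame lumen
  centers; DICOM reading, centerline extraction and multi-planar
  reconstruction are out of scope, as are pullback co-registration and
  activation-map visualization.
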