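"""Label artifacts: pie-shaped masks, gradient weight maps, angle boxes.

Angular plaque probabilities (chemogram-style profiles) carry no depth
information, so training labels are *pie-shaped*: a pixel belongs to the
mask when its angular bin about the lumen center is occupied, regardless
of radius (up to a maximum radius).  The segmenter additionally uses a
pixel-wise sample-weight map whose value is inversely related to the
distance from the lumen center, concentrating the loss near the lumen
where plaque sits.  The detector consumes the same profiles as 1-D
angular boxes in the polar view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import angles
from .phantom import PLAQUE_CLASSES, AngularProfile, GroundTruth

CHEMOGRAM_THRESHOLD = 0.6  # chemogram probability above which tissue counts as plaque
MIN_PLAQUE_ANGLE_DEG = 10  # detector training drops frames with less total angle


@dataclass
class PieMask:
    """Binary pie-shaped label image for one frame and class."""

    values: np.ndarray
    plaque_class: str
    frame_index: int
    lumen_center: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("pie mask must be binary")


@dataclass
class WeightMap:
    """Pixel-wise sample weight, maximal at the lumen center and
    non-increasing with distance from it along any ray."""

    values: np.ndarray
    lumen_center: tuple[float, float]
    w_max: float
    form: str


@dataclass(frozen=True)
class AngleBox:
    """A class-labeled angular interval ``[start, end)`` with a score.

    ``end < start`` denotes a wrap through 0 degrees; the full circle is
    ``(0, 360)``.  This is the polar-domain detector's prediction unit:
    the box spans the full radial axis, only the angles carry information.
    """

    plaque_class: str
    start_angle_deg: float
    end_angle_deg: float
    score: float = 1.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.width_deg < 1.0:
            raise ValueError("angular width must be >= 1 degree")

    @property
    def width_deg(self) -> float:
        return angles.arc_width_deg(self.start_angle_deg, self.end_angle_deg)

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_angle_deg, self.end_angle_deg)


def profile_to_pie_mask(
    profile: AngularProfile,
    lumen_center: tuple[float, float],
    image_shape: tuple[int, int],
    pixel_spacing_mm: float,
    max_radius_mm: float,
    threshold: float = CHEMOGRAM_THRESHOLD,
) -> PieMask:
    """Rasterize a thresholded profile into a pie-shaped binary mask.

    A pixel is set iff its degree bin about ``lumen_center`` has profile
    value strictly above ``threshold`` and its radius is at most
    ``max_radius_mm``.  The profile is thresholded *before* rasterization.
    """
    h, w = image_shape
    cx, cy = lumen_center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("lumen_center out of image bounds")
    if cx in (0, w - 1) or cy in (0, h - 1):
        warnings.warn("lumen_center lies on the image border; pie mask is clipped", stacklevel=2)
    occupied = np.asarray(profile.values) > threshold
    bins = angles.pixel_angle_bins(image_shape, lumen_center)
    r_mm = angles.pixel_radii(image_shape, lumen_center) * pixel_spacing_mm
    mask = occupied[bins] & (r_mm <= max_radius_mm)
    return PieMask(mask.astype(np.uint8), profile.plaque_class, profile.frame_index, lumen_center)


def pie_mask_to_profile(mask: PieMask, pixel_spacing_mm: float | None = None) -> AngularProfile:
    """Binary angular occupancy of a pie mask: bin ``a`` is 1 iff any mask
    pixel falls in bin ``a`` about the mask's lumen center.

    Left inverse of :func:`profile_to_pie_mask` on thresholded profiles
    for arcs a few degrees wide (very thin arcs can miss pixel centers at
    small radii; the boundary-bin convention is floor-of-angle).
    """
    vals = np.zeros(angles.N_ANGLE_BINS)
    if mask.values.any():
        bins = angles.pixel_angle_bins(mask.values.shape, mask.lumen_center)
        hit = np.unique(bins[mask.values.astype(bool)])
        vals[hit] = 1.0
    return AngularProfile(vals, mask.frame_index, mask.plaque_class)


def gradient_weight_map(
    image_shape: tuple[int, int],
    lumen_center: tuple[float, float],
    w_max: float = 10.0,
    form: str = "inverse",
    d0_px: float = 16.0,
    w_min: float = 0.1,
    d_max_px: float | None = None,
) -> WeightMap:
    """Distance-graded sample-weight map about the lumen center.

    ``inverse`` (default): ``w_max / (1 + d / d0_px)`` — a bounded, smooth
    inverse-distance law with half-height at ``d0_px`` (a natural choice
    for ``d0_px`` is the lumen radius in pixels).  ``linear-decay``:
    ``max(w_min, w_max * (1 - d / d_max_px))``.  Both are radially
    symmetric, maximal (= ``w_max``) at the lumen center, non-increasing
    with distance, and strictly positive.
    """
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    d = angles.pixel_radii(image_shape, lumen_center)
    if form == "inverse":
        vals = w_max / (1.0 + d / float(d0_px))
    elif form == "linear-decay":
        if d_max_px is None:
            d_max_px = float(d.max()) or 1.0
        vals = np.maximum(w_min, w_max * (1.0 - d / float(d_max_px)))
    else:
        raise ValueError(f"unknown weight form {form!r}")
    return WeightMap(vals, lumen_center, w_max, form)


def profile_to_angle_boxes(
    profile: AngularProfile, threshold: float = CHEMOGRAM_THRESHOLD
) -> list[AngleBox]:
    """Maximal runs of above-threshold bins become angle boxes.

    Runs are merged across the 359 -> 0 wrap.  Each box scores the mean
    profile value over its run (ground-truth boxes in training targets
    are used with score 1).
    """
    vals = np.asarray(profile.values)
    above = vals > threshold
    if not above.any():
        return []
    if above.all():
        return [AngleBox(profile.plaque_class, 0.0, 360.0, float(vals.mean()), profile.frame_index)]
    # Rotate so the sequence starts at a below-threshold bin, find runs,
    # rotate starts back.
    start0 = int(np.argmin(above))
    rolled = np.roll(above, -start0)
    edges = np.flatnonzero(np.diff(rolled.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1 if len(edges) % 2 == 0 else np.append(edges[1::2] + 1, len(rolled))
    boxes = []
    for s, e in zip(starts, ends):
        bins = np.mod(np.arange(s, e) + start0, angles.N_ANGLE_BINS)
        boxes.append(
            AngleBox(
                profile.plaque_class,
                float(bins[0]),
                float((bins[-1] + 1) % 360),
                float(vals[bins].mean()),
                profile.frame_index,
            )
        )
    return sorted(boxes, key=lambda b: b.start_angle_deg)


def filter_training_frames(
    ground_truth: GroundTruth,
    mode: str = "segmentation",
    threshold: float = CHEMOGRAM_THRESHOLD,
    min_angle_deg: int = MIN_PLAQUE_ANGLE_DEG,
) -> set[int]:
    """Select frame indices eligible for training.

    ``segmentation`` mode keeps every frame (normal frames are negative
    examples).  ``detection`` mode drops frames with no lipid or calcified
    tissue and frames where any present class occupies fewer than
    ``min_angle_deg`` degrees above ``threshold``.
    """
    if mode not in ("segmentation", "detection"):
        raise ValueError(f"unknown mode {mode!r}")
    n_frames = len(next(iter(ground_truth.values())))
    if mode == "segmentation":
        return set(range(n_frames))
    keep: set[int] = set()
    for f in range(n_frames):
        occ = {
            cls: int((np.asarray(ground_truth[cls][f].values) > threshold).sum())
            for cls in PLAQUE_CLASSES
            if cls in ground_truth
        }
        present = {cls: n for cls, n in occ.items() if n > 0}
        if present and min(present.values()) >= min_angle_deg:
            keep.add(f)
    return keep


def frame_tissue_class(
    ground_truth: GroundTruth, frame_index: int, threshold: float = CHEMOGRAM_THRESHOLD
) -> str:
    """Batch-sampling category of a frame: ``lipid``, ``calcified``,
    ``mixed`` (both present) or ``normal`` (neither)."""
    has = {
        cls: bool((np.asarray(ground_truth[cls][frame_index].values) > threshold).any())
        for cls in PLAQUE_CLASSES
    }
    if has["lipid"] and has["calcified"]:
        return "mixed"
    if has["lipid"]:
        return "lipid"
    if has["calcified"]:
        return "calcified"
    return "normal"
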