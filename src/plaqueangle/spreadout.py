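"""Spread-out view assembly: angle x frame probability matrices.

The spread-out view unrolls a vessel: element ``(alpha, n)`` is the
probability that plaque of one class occupies angle ``alpha`` on frame
``n``.  Segmenter probability maps are reduced to per-frame angular
profiles (per-angle aggregation over a radial band about the lumen
center); detector boxes paint their score over their angular span.  The
assembled matrix is the substrate of all lesion-level evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import angles
from .labels import AngleBox
from .models import SegmentationPrediction
from .phantom import AngularProfile

SEGMENTER_THRESHOLDS = {"lipid": 0.6, "calcified": 0.6}
DETECTOR_THRESHOLDS = {"lipid": 0.3, "calcified": 0.5}


@dataclass
class SpreadOutView:
    """(360 angle bins x N frames) probability matrix for one class."""

    values: np.ndarray
    plaque_class: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != angles.N_ANGLE_BINS:
            raise ValueError(f"spread-out view must be (360, N), got {self.values.shape}")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("spread-out values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def segmentation_to_profile(
    pred: SegmentationPrediction,
    plaque_class: str,
    lumen_center: tuple[float, float],
    pixel_spacing_mm: float,
    radius_band_mm: tuple[float, float],
    aggregator: str = "max",
) -> AngularProfile:
    """Reduce a probability map to a 360-bin angular profile.

    Bin ``a`` aggregates (max by default, or mean) the predicted
    probabilities of pixels whose degree bin about ``lumen_center`` is
    ``a`` and whose radius lies within ``radius_band_mm``.  A thin band
    can leave a few one-degree bins without any pixel center; such bins
    take the value of the circularly nearest occupied bin so the profile
    has no spurious gaps.
    """
    lo, hi = radius_band_mm
    if hi <= lo:
        raise ValueError(f"empty radius band {radius_band_mm}")
    if aggregator not in ("max", "mean"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    pmap = pred.maps[plaque_class]
    bins = angles.pixel_angle_bins(pmap.shape, lumen_center)
    r_mm = angles.pixel_radii(pmap.shape, lumen_center) * pixel_spacing_mm
    band = (r_mm >= lo) & (r_mm <= hi)
    if not band.any():
        raise ValueError("radius band contains no pixels")
    vals = np.zeros(angles.N_ANGLE_BINS)
    sel_bins = bins[band]
    sel_p = pmap[band]
    counts = np.bincount(sel_bins, minlength=angles.N_ANGLE_BINS)
    if aggregator == "max":
        np.maximum.at(vals, sel_bins, sel_p)
    else:
        sums = np.bincount(sel_bins, weights=sel_p, minlength=angles.N_ANGLE_BINS)
        vals = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        occupied = np.flatnonzero(counts > 0)
        for a in empty:
            d = np.abs((occupied - a + 180) % 360 - 180)
            vals[a] = vals[occupied[int(d.argmin())]]
    return AngularProfile(np.clip(vals, 0.0, 1.0), pred.frame_index, plaque_class)


def boxes_to_profile(
    boxes: list[AngleBox], plaque_class: str, frame_index: int = 0
) -> AngularProfile:
    """Angular profile from detector boxes of one class: bin value is the
    max score over boxes covering the bin, zero where uncovered."""
    vals = np.zeros(angles.N_ANGLE_BINS)
    for b in boxes:
        if b.plaque_class != plaque_class:
            continue
        sel = angles.arc_mask(b.start_angle_deg, b.end_angle_deg)
        vals[sel] = np.maximum(vals[sel], b.score)
    return AngularProfile(vals, frame_index, plaque_class)


def assemble_spreadout(
    profiles: list[AngularProfile], n_frames: int, plaque_class: str | None = None
) -> SpreadOutView:
    """Stack per-frame profiles into the (360, n_frames) spread-out view.

    Frames without a profile become zero columns; a duplicated frame index
    is an error.
    """
    if plaque_class is None:
        if not profiles:
            raise ValueError("plaque_class required when profiles is empty")
        plaque_class = profiles[0].plaque_class
    mat = np.zeros((angles.N_ANGLE_BINS, n_frames))
    seen: set[int] = set()
    for p in profiles:
        if p.frame_index in seen:
            raise ValueError(f"duplicate frame index {p.frame_index}")
        if not 0 <= p.frame_index < n_frames:
            raise ValueError(f"frame index {p.frame_index} outside [0, {n_frames})")
        seen.add(p.frame_index)
        mat[:, p.frame_index] = p.values
    return SpreadOutView(mat, plaque_class)


def binarize_spreadout(view: SpreadOutView, threshold: float) -> SpreadOutView:
    """Element = 1 iff probability strictly exceeds ``threshold``.

    Default operating points: segmenter 0.6 for both classes; detector
    0.3 for lipid-rich and 0.5 for calcified plaque.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return SpreadOutView((view.values > threshold).astype(float), view.plaque_class)


def ground_truth_spreadout(ground_truth, plaque_class: str, n_frames: int) -> SpreadOutView:
    """Spread-out view of a phantom's ground-truth profiles."""
    return assemble_spreadout(ground_truth[plaque_class], n_frames, plaque_class)


def render_spreadout(view: SpreadOutView, path: str | Path, dpi: int = 100) -> Path:
    """Render the view as a heatmap PNG: frame on x, angle on y, fixed
    [0, 1] probability color scale."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(
        view.values, aspect="auto", origin="lower", vmin=0.0, vmax=1.0, cmap="inferno",
        interpolation="nearest",
    )
    ax.set_xlabel("frame index")
    ax.set_ylabel("plaque angle (deg)")
    ax.set_title(f"{view.plaque_class} plaque spread-out view")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label("plaque probability")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def write_spreadout_csv(view: SpreadOutView, path: str | Path) -> Path:
    """Serialize as CSV, one row per angle bin, one column per frame."""
    path = Path(path)
    np.savetxt(path, view.values, delimiter=",", fmt="%.6g")
    return path


def read_spreadout_csv(path: str | Path, plaque_class: str) -> SpreadOutView:
    vals = np.loadtxt(path, delimiter=",", ndmin=2)
    return SpreadOutView(vals, plaque_class)
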