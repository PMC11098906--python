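"""Synthetic vessel phantoms with known angular plaque occupancy.

Each phantom is a stack of square cross-sectional frames in Hounsfield
units (HU): a contrast-filled lumen disc (HU above the 350 HU
calcium/lumen threshold used by conventional CT plaque analysis), a
vessel-wall / myocardium band, and plaque arcs painted into the wall —
lipid-rich arcs at low HU overlapping the fibrotic range, calcified arcs
at high HU.  The generator records, per frame and per tissue class, the
per-degree plaque probability profile ("chemogram"-like ground truth) so
every downstream stage can be validated against known angular occupancy.

Frame geometry follows clinical multi-planar reformatted CTA: 0.30 mm
increments between frames at 0.50 mm slice thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import angles

PLAQUE_CLASSES = ("lipid", "calcified")

CALCIUM_HU_THRESHOLD = 350.0  # conventional lumen/calcium separation point


class StackParseError(ValueError):
    """Raised when a serialized phantom fails validation; the message
    names the offending field."""


@dataclass(frozen=True)
class LesionSpec:
    """A contiguous diseased segment of the vessel.

    Parameters
    ----------
    frame_range
        Half-open ``(start, stop)`` frame-index interval.
    arcs
        ``(plaque_class, start_angle_deg, end_angle_deg, probability)``
        tuples; wrap-around arcs have ``start > end``.  Probability is the
        chemogram-style per-angle plaque probability assigned to the arc.
    plaque_burden
        Fraction of the cross-section occupied by plaque, used by the
        lesion-level evaluation (lesions are defined by burden >= 0.40).
    """

    frame_range: tuple[int, int]
    arcs: Sequence[tuple[str, float, float, float]] = ()
    plaque_burden: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.frame_range
        if hi <= lo or lo < 0:
            raise ValueError(f"frame_range {self.frame_range} must be a nonempty half-open interval")
        if not 0.0 <= self.plaque_burden <= 1.0:
            raise ValueError(f"plaque_burden {self.plaque_burden} outside [0, 1]")
        for cls, start, end, prob in self.arcs:
            if cls not in PLAQUE_CLASSES:
                raise ValueError(f"unknown plaque class {cls!r}")
            if not (0.0 <= start < 360.0 and 0.0 <= end <= 360.0):
                raise ValueError(f"arc angles ({start}, {end}) outside [0, 360)")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"arc probability {prob} outside [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for a synthetic vessel stack.

    Default intensities emulate contrast CTA: lumen 450 HU (above the
    350 HU calcium threshold), wall/myocardium 60 HU, lipid 30 HU
    (overlapping fibrotic attenuation), calcium 800 HU.
    """

    n_frames: int = 40
    image_size: int = 128
    pixel_spacing_mm: float = 0.09
    frame_increment_mm: float = 0.30
    slice_thickness_mm: float = 0.50
    lumen_radius_mm: float | Sequence[float] = 1.5
    wall_thickness_mm: float = 1.5
    lumen_hu: float = 450.0
    wall_hu: float = 60.0
    lipid_hu: float = 30.0
    calcium_hu: float = 800.0
    noise_sd_hu: float = 20.0
    center_jitter_px: float = 0.0
    lesion_specs: Sequence[LesionSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (self.calcium_hu > CALCIUM_HU_THRESHOLD > self.lipid_hu):
            raise ValueError(
                f"calcium_hu ({self.calcium_hu}) must exceed {CALCIUM_HU_THRESHOLD} HU "
                f"and lipid_hu ({self.lipid_hu}) must sit below it"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        radii = np.atleast_1d(np.asarray(self.lumen_radius_mm, dtype=float))
        if radii.size not in (1, self.n_frames):
            raise ValueError("lumen_radius_mm must be scalar or length n_frames")
        for spec in self.lesion_specs:
            if spec.frame_range[1] > self.n_frames:
                raise ValueError(f"lesion frame_range {spec.frame_range} exceeds n_frames={self.n_frames}")
        spans = sorted(s.frame_range for s in self.lesion_specs)
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo < hi:
                raise ValueError("lesion frame_ranges overlap")

    def lumen_radii(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.lumen_radius_mm, dtype=float))
        return np.broadcast_to(r, (self.n_frames,)).copy() if r.size == 1 else r


@dataclass
class VesselStack:
    """Ordered cross-sectional frames with per-frame lumen centers.

    ``frames`` has shape ``(n_frames, height, width)`` in HU;
    ``lumen_centers`` holds per-frame ``(x, y)`` pixel coordinates.
    """

    frames: np.ndarray
    lumen_centers: np.ndarray
    pixel_spacing_mm: float
    frame_increment_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.lumen_centers = np.asarray(self.lumen_centers, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, h, w) array with n_frames >= 1")
        if self.lumen_centers.shape != (self.frames.shape[0], 2):
            raise ValueError("lumen_centers must be (n_frames, 2) (x, y) coordinates")
        h, w = self.frames.shape[1:]
        x, y = self.lumen_centers[:, 0], self.lumen_centers[:, 1]
        if (x < 0).any() or (x > w - 1).any() or (y < 0).any() or (y > h - 1).any():
            raise ValueError("lumen_centers must lie inside image bounds")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AngularProfile:
    """Per-degree plaque probability for one frame and one tissue class.

    ``values[a]`` is the probability that the angular bin ``[a, a+1)``
    about the lumen center contains plaque of ``plaque_class``.
    """

    values: np.ndarray
    frame_index: int
    plaque_class: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (angles.N_ANGLE_BINS,):
            raise ValueError(f"profile must have length {angles.N_ANGLE_BINS}, got {self.values.shape}")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("profile values must lie in [0, 1]")
        if self.plaque_class not in PLAQUE_CLASSES:
            raise ValueError(f"unknown plaque class {self.plaque_class!r}")


GroundTruth = dict[str, list[AngularProfile]]


def _merged_class_profiles(spec: LesionSpec) -> dict[str, np.ndarray]:
    """Per-class 360-length probability vectors for one lesion; arcs of
    the same class are merged by taking the per-bin maximum."""
    out: dict[str, np.ndarray] = {}
    for cls, start, end, prob in spec.arcs:
        vec = out.setdefault(cls, np.zeros(angles.N_ANGLE_BINS))
        sel = angles.arc_mask(start, end)
        vec[sel] = np.maximum(vec[sel], prob)
    return out


def generate_stack(config: PhantomConfig) -> tuple[VesselStack, GroundTruth, pd.DataFrame]:
    """Generate a synthetic vessel stack with its angular ground truth.

    Returns the stack, the per-class lists of per-frame
    :class:`AngularProfile` (zero outside lesions), and a lesion table
    with columns ``lesion_id, frame_start, frame_stop, plaque_burden``.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, size = config.n_frames, config.image_size
    center0 = (size - 1) / 2.0
    radii = config.lumen_radii()

    centers = np.full((n, 2), center0, dtype=float)
    if config.center_jitter_px > 0:
        centers += rng.normal(0.0, config.center_jitter_px, size=(n, 2))
        centers = np.clip(centers, 1.0, size - 2.0)

    lesion_of_frame: dict[int, LesionSpec] = {}
    for spec in config.lesion_specs:
        for f in range(*spec.frame_range):
            lesion_of_frame[f] = spec

    frames = np.empty((n, size, size), dtype=np.float32)
    gt: GroundTruth = {cls: [] for cls in PLAQUE_CLASSES}

    for f in range(n):
        cx, cy = centers[f]
        r_px = angles.pixel_radii((size, size), (cx, cy))
        r_mm = r_px * config.pixel_spacing_mm
        bins = angles.pixel_angle_bins((size, size), (cx, cy))

        img = np.full((size, size), config.wall_hu, dtype=np.float64)
        img[r_mm <= radii[f]] = config.lumen_hu
        wall_band = (r_mm > radii[f]) & (r_mm <= radii[f] + config.wall_thickness_mm)

        spec = lesion_of_frame.get(f)
        class_vecs = _merged_class_profiles(spec) if spec is not None else {}
        # Lipid first, then calcium: co-occurring classes overlap in angle
        # and calcium dominates the CT appearance where both are painted.
        for cls, hu in (("lipid", config.lipid_hu), ("calcified", config.calcium_hu)):
            vec = class_vecs.get(cls)
            if vec is None:
                continue
            occupied = vec[bins] > 0
            img[wall_band & occupied] = hu

        for cls in PLAQUE_CLASSES:
            vec = class_vecs.get(cls, np.zeros(angles.N_ANGLE_BINS))
            gt[cls].append(AngularProfile(vec.copy(), frame_index=f, plaque_class=cls))

        frames[f] = img

    if config.noise_sd_hu > 0:
        frames += rng.normal(0.0, config.noise_sd_hu, size=frames.shape).astype(np.float32)

    stack = VesselStack(
        frames=frames,
        lumen_centers=centers,
        pixel_spacing_mm=config.pixel_spacing_mm,
        frame_increment_mm=config.frame_increment_mm,
    )
    lesion_table = pd.DataFrame(
        [
            {
                "lesion_id": i,
                "frame_start": s.frame_range[0],
                "frame_stop": s.frame_range[1],
                "plaque_burden": s.plaque_burden,
            }
            for i, s in enumerate(config.lesion_specs)
        ],
        columns=["lesion_id", "frame_start", "frame_stop", "plaque_burden"],
    )
    return stack, gt, lesion_table


def synthetic_vessel_config(
    n_frames: int,
    seed: int,
    noise_sd_hu: float = 15.0,
    lipid_probability: float = 0.5,
) -> PhantomConfig:
    """A randomized multi-lesion vessel emulating the study's lesion
    statistics at phantom scale.

    Lesions span 8--14 frames (2.4--4.2 mm at 0.30 mm frame increments)
    and are separated by 4--8 disease-free frames.  Every lesion carries a
    calcified arc of 60--140 degrees at chemogram probability 0.9; with
    probability ``lipid_probability`` it also carries a lipid-rich arc of
    50--110 degrees on the opposite side of the wall (mixed-plaque
    frames).  Arc placement is uniform over the circle, so wrap-around
    lesions occur naturally.  Plaque burden is 0.6, above the 0.40 lesion
    threshold.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed + 100)
    lesions = []
    f = 4
    while f < n_frames - 12:
        length = int(rng.integers(8, 14))
        start = float(rng.integers(0, 360))
        width = float(rng.integers(60, 140))
        arcs = [("calcified", start, (start + width) % 360.0, 0.9)]
        if rng.random() < lipid_probability:
            s2 = (start + 180.0) % 360.0
            w2 = float(rng.integers(50, 110))
            arcs.append(("lipid", s2, (s2 + w2) % 360.0, 0.9))
        lesions.append(LesionSpec((f, f + length), arcs, plaque_burden=0.6))
        f += length + int(rng.integers(4, 9))
    return PhantomConfig(
        n_frames=n_frames, noise_sd_hu=noise_sd_hu, lesion_specs=tuple(lesions), seed=seed
    )


def burden_per_frame(lesion_table: pd.DataFrame, n_frames: int) -> np.ndarray:
    """Per-frame plaque-burden vector implied by a lesion table (zero
    outside every lesion)."""
    burden = np.zeros(n_frames)
    for _, row in lesion_table.iterrows():
        burden[int(row.frame_start) : int(row.frame_stop)] = row.plaque_burden
    return burden


# ---------------------------------------------------------------------------
# Serialization: NIfTI (or multi-page TIFF) image stack + JSON label sidecar.
# ---------------------------------------------------------------------------


def write_stack(
    stack: VesselStack,
    ground_truth: GroundTruth,
    path: str | Path,
    lesion_table: pd.DataFrame | None = None,
    image_format: str = "nifti",
) -> dict[str, Path]:
    """Write a stack and its labels under directory ``path``.

    The image stack goes to ``stack.nii.gz`` (voxel spacing header set to
    ``(pixel_spacing, pixel_spacing, frame_increment)``) or ``stack.tiff``;
    lumen centers, per-class profiles and the lesion table go to
    ``labels.json``.  Intensities round-trip losslessly as float32.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if image_format == "nifti":
        img_path = path / "stack.nii.gz"
        data = np.ascontiguousarray(stack.frames.transpose(2, 1, 0))  # (x, y, frame)
        affine = np.diag([stack.pixel_spacing_mm, stack.pixel_spacing_mm, stack.frame_increment_mm, 1.0])
        img = nib.Nifti1Image(data.astype(np.float32), affine)
        img.header.set_zooms((stack.pixel_spacing_mm, stack.pixel_spacing_mm, stack.frame_increment_mm))
        nib.save(img, img_path)
    elif image_format == "tiff":
        import tifffile

        img_path = path / "stack.tiff"
        tifffile.imwrite(img_path, stack.frames.astype(np.float32))
    else:
        raise ValueError(f"unknown image_format {image_format!r}")

    labels = {
        "pixel_spacing_mm": stack.pixel_spacing_mm,
        "frame_increment_mm": stack.frame_increment_mm,
        "lumen_centers": stack.lumen_centers.tolist(),
        "profiles": {
            cls: [p.values.tolist() for p in sorted(profs, key=lambda p: p.frame_index)]
            for cls, profs in ground_truth.items()
        },
        "lesions": [] if lesion_table is None else lesion_table.to_dict(orient="records"),
    }
    label_path = path / "labels.json"
    label_path.write_text(json.dumps(labels))
    return {"image": img_path, "labels": label_path}


def read_stack(path: str | Path) -> tuple[VesselStack, GroundTruth, pd.DataFrame]:
    """Read a stack written by :func:`write_stack`; validates every field
    and raises :class:`StackParseError` naming the first offending one."""
    path = Path(path)
    nii = path / "stack.nii.gz"
    tiff = path / "stack.tiff"
    if nii.exists():
        img = nib.load(nii)
        frames = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    elif tiff.exists():
        import tifffile

        frames = tifffile.imread(tiff).astype(np.float32)
    else:
        raise StackParseError(f"no stack.nii.gz or stack.tiff under {path}")

    label_path = path / "labels.json"
    if not label_path.exists():
        raise StackParseError(f"missing labels.json under {path}")
    raw = json.loads(label_path.read_text())

    for key in ("pixel_spacing_mm", "frame_increment_mm", "lumen_centers", "profiles"):
        if key not in raw:
            raise StackParseError(f"labels.json missing field {key!r}")
    centers = np.asarray(raw["lumen_centers"], dtype=float)
    if centers.shape != (frames.shape[0], 2):
        raise StackParseError(
            f"lumen_centers: expected shape {(frames.shape[0], 2)}, got {centers.shape}"
        )

    gt: GroundTruth = {}
    for cls in PLAQUE_CLASSES:
        rows = raw["profiles"].get(cls)
        if rows is None:
            raise StackParseError(f"profiles missing class {cls!r}")
        if len(rows) != frames.shape[0]:
            raise StackParseError(f"profiles[{cls!r}]: expected {frames.shape[0]} frames, got {len(rows)}")
        gt[cls] = []
        for f, vals in enumerate(rows):
            if len(vals) != angles.N_ANGLE_BINS:
                raise StackParseError(
                    f"profiles[{cls!r}][{f}]: expected length {angles.N_ANGLE_BINS}, got {len(vals)}"
                )
            try:
                gt[cls].append(AngularProfile(np.asarray(vals), frame_index=f, plaque_class=cls))
            except ValueError as exc:
                raise StackParseError(f"profiles[{cls!r}][{f}]: {exc}") from exc

    try:
        stack = VesselStack(
            frames=frames,
            lumen_centers=centers,
            pixel_spacing_mm=float(raw["pixel_spacing_mm"]),
            frame_increment_mm=float(raw["frame_increment_mm"]),
        )
    except ValueError as exc:
        raise StackParseError(str(exc)) from exc

    lesion_table = pd.DataFrame(
        raw.get("lesions", []), columns=["lesion_id", "frame_start", "frame_stop", "plaque_burden"]
    )
    return stack, gt, lesion_table
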