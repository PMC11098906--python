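"""Cartesian/polar resampling about the lumen center and 2.5D blocks.

The polar view resamples a cross-sectional frame onto a fixed
``(radius, angle)`` grid of 45 radial bins spanning 0--5.625 mm (0.125 mm
bin width) by 360 one-degree angular bins.  2.5D blocks stack 7
consecutive frames around a target frame so the networks see longitudinal
context: 128 x 128 x 7 in the Cartesian domain, 45 x 360 x 7 in polar.

Intensities are interpolated bilinearly; binary masks use nearest
neighbour.  Samples falling outside the source image are edge-clamped by
default (or filled with a constant).  Rotation augmentation uses integer
angles only, so the matching label shift is an exact circular bin roll.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import angles
from .phantom import AngularProfile, VesselStack

DEFAULT_N_RADIUS = 45
DEFAULT_N_ANGLE = 360
DEFAULT_RADIAL_EXTENT_MM = 5.625
CART_BLOCK_SIZE = 128
BLOCK_DEPTH = 7


@dataclass
class PolarImage:
    """A frame resampled to ``(radius_bins, angle_bins)`` about the lumen
    center; row ``r`` holds the circle at radius ``(r + 0.5) * bin_width``."""

    values: np.ndarray
    radial_extent_mm: float = DEFAULT_RADIAL_EXTENT_MM
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("polar values must be 2-D (radius, angle)")

    @property
    def radial_bin_mm(self) -> float:
        return self.radial_extent_mm / self.values.shape[0]


@dataclass
class Block25D:
    """Seven consecutive frames centered on a target frame.

    ``values`` is ``(h, w, 7)``: ``(128, 128, 7)`` in the Cartesian domain
    (lumen-centered window) or ``(45, 360, 7)`` in polar.
    """

    values: np.ndarray
    center_frame_index: int
    domain: str  # "cartesian" | "polar"
    lumen_center: tuple[float, float] | None = None  # window-local, cartesian only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[2] != BLOCK_DEPTH:
            raise ValueError(f"block must be (h, w, {BLOCK_DEPTH})")
        if self.domain not in ("cartesian", "polar"):
            raise ValueError(f"unknown domain {self.domain!r}")


def _sample(frame: np.ndarray, xs: np.ndarray, ys: np.ndarray, order: int, fill: float | None) -> np.ndarray:
    mode = "nearest" if fill is None else "constant"
    cval = 0.0 if fill is None else fill
    return ndimage.map_coordinates(
        np.asarray(frame, dtype=float), [ys, xs], order=order, mode=mode, cval=cval
    )


def cart_to_polar(
    frame: np.ndarray,
    lumen_center: tuple[float, float],
    pixel_spacing_mm: float,
    n_radius: int = DEFAULT_N_RADIUS,
    n_angle: int = DEFAULT_N_ANGLE,
    radial_extent_mm: float = DEFAULT_RADIAL_EXTENT_MM,
    order: int = 1,
    fill: float | None = None,
    frame_index: int = 0,
) -> PolarImage:
    """Resample a frame onto a polar grid about ``lumen_center``.

    Element ``(r, a)`` is the interpolated intensity at the center of
    radial bin ``r`` and angular bin ``a``.  ``fill=None`` edge-clamps
    samples outside the image; a float fills with that constant.
    """
    cx, cy = lumen_center
    r_mm = (np.arange(n_radius) + 0.5) * (radial_extent_mm / n_radius)
    theta = np.deg2rad((np.arange(n_angle) + 0.5) * (360.0 / n_angle))
    r_px = (r_mm / pixel_spacing_mm)[:, None]
    xs = cx + r_px * np.cos(theta)[None, :]
    ys = cy - r_px * np.sin(theta)[None, :]
    vals = _sample(frame, xs, ys, order=order, fill=fill)
    return PolarImage(vals, radial_extent_mm=radial_extent_mm, frame_index=frame_index)


def polar_to_cart(
    polar: PolarImage,
    lumen_center: tuple[float, float],
    out_shape: tuple[int, int],
    pixel_spacing_mm: float,
    order: int = 1,
    fill: float = 0.0,
) -> np.ndarray:
    """Inverse resampling of a polar image back to a Cartesian frame.

    Pixels beyond the radial extent receive ``fill``.  The angle axis is
    periodic, so interpolation wraps across the 359->0 degree seam.
    """
    n_radius, n_angle = polar.values.shape
    h, w = out_shape
    cx, cy = lumen_center
    ang = angles.pixel_angles_deg(out_shape, (cx, cy))
    r_mm = angles.pixel_radii(out_shape, (cx, cy)) * pixel_spacing_mm

    rbin = r_mm / polar.radial_bin_mm - 0.5
    abin = ang / (360.0 / n_angle) - 0.5
    # Pad the angle axis with its wrap-around neighbour so bilinear
    # interpolation is seamless at 0/360.
    padded = np.concatenate([polar.values[:, -1:], polar.values, polar.values[:, :1]], axis=1)
    out = ndimage.map_coordinates(
        np.asarray(padded, dtype=float), [rbin, abin + 1.0], order=order, mode="nearest"
    )
    out = np.where(r_mm <= polar.radial_extent_mm, out, fill)
    return out


def build_block(
    stack: VesselStack,
    frame_index: int,
    domain: str = "cartesian",
    block_size: int = CART_BLOCK_SIZE,
    n_radius: int = DEFAULT_N_RADIUS,
    n_angle: int = DEFAULT_N_ANGLE,
    radial_extent_mm: float = DEFAULT_RADIAL_EXTENT_MM,
) -> Block25D:
    """Assemble the 7-frame 2.5D block centered on ``frame_index``.

    Frames beyond either end of the stack are replicate-padded with the
    terminal frame.  Cartesian blocks are a ``block_size`` pixel window
    centered on the *center frame's* lumen center (edge-clamped); polar
    blocks resample each frame about its own lumen center.
    """
    if not 0 <= frame_index < stack.n_frames:
        raise IndexError(f"frame_index {frame_index} out of range")
    half = BLOCK_DEPTH // 2
    idx = np.clip(np.arange(frame_index - half, frame_index + half + 1), 0, stack.n_frames - 1)

    if domain == "cartesian":
        cx, cy = stack.lumen_centers[frame_index]
        off = np.arange(block_size) - (block_size - 1) / 2.0
        xs = cx + off[None, :].repeat(block_size, axis=0)
        ys = cy + off[:, None].repeat(block_size, axis=1)
        planes = [_sample(stack.frames[i], xs, ys, order=1, fill=None) for i in idx]
        vals = np.stack(planes, axis=-1)
        local_center = ((block_size - 1) / 2.0, (block_size - 1) / 2.0)
        return Block25D(vals, center_frame_index=frame_index, domain="cartesian", lumen_center=local_center)
    if domain == "polar":
        planes = [
            cart_to_polar(
                stack.frames[i],
                tuple(stack.lumen_centers[i]),
                stack.pixel_spacing_mm,
                n_radius=n_radius,
                n_angle=n_angle,
                radial_extent_mm=radial_extent_mm,
                frame_index=int(i),
            ).values
            for i in idx
        ]
        return Block25D(np.stack(planes, axis=-1), center_frame_index=frame_index, domain="polar")
    raise ValueError(f"unknown domain {domain!r}")


def rotate_frame(frame: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate a frame counter-clockwise (display convention) about the
    image center, bilinear by default, edge-clamped."""
    h, w = frame.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    y, x = np.mgrid[0:h, 0:w]
    u, v = x - cx, -(y - cy)  # math coords, y up
    a = np.deg2rad(angle_deg)
    # Source point = output point rotated by -angle.
    us = np.cos(a) * u + np.sin(a) * v
    vs = -np.sin(a) * u + np.cos(a) * v
    return _sample(frame, cx + us, cy - vs, order=order, fill=None)


def rotate_augment(
    block: Block25D,
    profiles: dict[str, AngularProfile] | list[AngularProfile],
    angle_deg: int,
) -> tuple[Block25D, dict[str, AngularProfile] | list[AngularProfile]]:
    """Rotate a Cartesian block by an integer angle and shift its angular
    ground truth by the same amount.

    All 7 frames rotate about the window center; every profile rolls by
    ``angle_deg`` bins exactly (bin ``a`` moves to ``(a + angle) % 360``),
    so labels stay consistent with the rotated image.  Polar blocks are
    rejected: in the polar domain a rotation is a column roll and is not
    an augmentation of this kind.
    """
    if block.domain != "cartesian":
        raise ValueError("rotate_augment applies to Cartesian blocks only")
    angle = int(angle_deg) % 360
    if angle == 0:
        rot = Block25D(block.values.copy(), block.center_frame_index, "cartesian", block.lumen_center)
    else:
        planes = [rotate_frame(block.values[:, :, k], angle) for k in range(BLOCK_DEPTH)]
        rot = Block25D(np.stack(planes, axis=-1), block.center_frame_index, "cartesian", block.lumen_center)

    def shift(p: AngularProfile) -> AngularProfile:
        return AngularProfile(np.roll(p.values, angle), p.frame_index, p.plaque_class)

    if isinstance(profiles, dict):
        return rot, {k: shift(p) for k, p in profiles.items()}
    return rot, [shift(p) for p in profiles]
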