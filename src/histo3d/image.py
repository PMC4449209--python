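"""Section image representation, I/O, intensity mappings and the MSE metric.

Brightfield serial-section scans are 8-bit RGB rasters on an isotropic pixel
grid (0.25 μm/pixel in the scans this package was designed around) with a
known physical section thickness (5 μm).  All intensity conventions live
here: percentages such as "green below 80%" are fractions of 255, grayscale
conversion is the unweighted RGB mean, and the window/level contrast mapping
follows the radiology convention (window = full ramp width, level = ramp
centre).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .geometry import AffineTransform2D, warp_raster

__all__ = [
    "SectionImage",
    "EmptyOverlapError",
    "read_section_series",
    "downsample",
    "downsampled_shape",
    "to_grayscale",
    "window_level",
    "mse",
    "resample_image",
    "round_half_up",
]

WHITE = 255.0


class EmptyOverlapError(ValueError):
    """No overlapping pixels are available for an image comparison."""


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class SectionImage:
    """An RGB section raster plus its physical metadata.

    Attributes
    ----------
    pixels : (H, W, 3) uint8
    spacing : float
        Isotropic in-plane pixel spacing in μm/pixel.
    index : int
        1-based section number within the stack.
    thickness : float
        Physical section thickness in μm.
    """

    pixels: np.ndarray
    spacing: float
    index: int = 1
    thickness: float = 5.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got shape {px.shape}")
        if px.size == 0:
            raise ValueError("zero-size image")
        if px.dtype != np.uint8:
            px = np.asarray(round_half_up(np.clip(px, 0, 255)), dtype=np.uint8)
        self.pixels = px
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not self.thickness > 0:
            raise ValueError("thickness must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    @property
    def extent_um(self) -> tuple:
        """Physical extent (height, width) in μm (pixel count × spacing)."""
        h, w = self.shape
        return (h * self.spacing, w * self.spacing)

    @property
    def physical_center(self) -> np.ndarray:
        """Centre of the pixel grid in μm, ordered (x, y)."""
        h, w = self.shape
        return np.array([(w - 1) / 2.0 * self.spacing, (h - 1) / 2.0 * self.spacing])

    def green(self) -> np.ndarray:
        return self.pixels[:, :, 1].astype(float)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(str(path))
    return iio.imread(str(path))


def _to_rgb8(arr: np.ndarray, path) -> np.ndarray:
    """Coerce an arbitrary raster to 8-bit RGB.

    Grayscale inputs are replicated to 3 channels; >8-bit integer or float
    inputs are rescaled to 0–255 by max-value normalisation per file.
    """
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"unsupported image dimensionality {arr.shape} in {path}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"expected 1, 3 or 4 channels in {path}, got {arr.shape[2]}")
    if arr.dtype != np.uint8:
        top = float(arr.max())
        if top <= 0:
            arr = np.zeros(arr.shape, dtype=np.uint8)
        else:
            arr = np.asarray(round_half_up(arr.astype(float) / top * 255.0), dtype=np.uint8)
    return arr


def read_section_series(
    paths: Sequence, spacing: float, thickness: float = 5.0
) -> list:
    """Read an ordered series of section images, numbering them 1..N.

    Raises a ``ValueError`` naming the offending path for unreadable or
    zero-size files, and for an empty path list.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("empty section series")
    sections = []
    for k, p in enumerate(paths, start=1):
        p = Path(p)
        try:
            raw = _read_raster(p)
        except Exception as exc:  # noqa: BLE001 - re-raise with path context
            raise ValueError(f"cannot read section image {p}: {exc}") from exc
        sections.append(
            SectionImage(_to_rgb8(raw, p), spacing=spacing, index=k, thickness=thickness)
        )
    return sections


def write_section(image: SectionImage, path) -> None:
    tifffile.imwrite(str(path), image.pixels, photometric="rgb")


# ----------------------------------------------------------------------
# Resolution and intensity mappings
# ----------------------------------------------------------------------

def downsampled_shape(shape_px: tuple, spacing: float, target_spacing: float) -> tuple:
    """Output extents for a downsample: ceil(physical extent / target spacing)."""
    return tuple(int(math.ceil(n * spacing / target_spacing)) for n in shape_px[:2])


def downsample(image: SectionImage, target_spacing: float) -> SectionImage:
    """Resample a section to a coarser isotropic grid by bilinear interpolation.

    ``target_spacing`` must not be finer than the source spacing (there is no
    upsampling path).
    """
    if target_spacing < image.spacing:
        raise ValueError(
            f"target spacing {target_spacing} μm finer than source {image.spacing} μm"
        )
    if target_spacing == image.spacing:
        return replace(image, pixels=image.pixels.copy())
    out_h, out_w = downsampled_shape(image.shape, image.spacing, target_spacing)
    ratio = target_spacing / image.spacing
    rows = np.arange(out_h) * ratio
    cols = np.arange(out_w) * ratio
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.vstack([rr.ravel(), cc.ravel()])
    out = np.empty((out_h, out_w, 3), dtype=np.uint8)
    for ch in range(3):
        vals = ndimage.map_coordinates(
            image.pixels[:, :, ch].astype(float), coords, order=1, mode="nearest"
        )
        out[:, :, ch] = round_half_up(vals).reshape(out_h, out_w).astype(np.uint8)
    return SectionImage(out, spacing=target_spacing, index=image.index, thickness=image.thickness)


def to_grayscale(image: SectionImage | np.ndarray) -> np.ndarray:
    """Unweighted per-pixel mean of the R, G, B channels (float raster)."""
    px = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("grayscale conversion requires an RGB raster")
    return px.astype(float).mean(axis=2)


def window_level(channel: np.ndarray, window: float, level: float) -> np.ndarray:
    """Linear contrast ramp mapping [level - window/2, level + window/2] to
    [0, 255], clamped outside, rounded half-up.

    With window 14 and level 235 this stretches the near-white band where the
    glass slide and pale tissue live, enhancing tissue-background contrast.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    ch = np.asarray(channel, dtype=float)
    lo = level - window / 2.0
    out = (ch - lo) * (255.0 / window)
    return round_half_up(np.clip(out, 0.0, 255.0))


def mse(a: np.ndarray, b: np.ndarray, overlap_mask: np.ndarray | None = None) -> float:
    """Mean of squared intensity differences over overlapping (or masked)
    pixels.  The ideal value is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    d = a - b
    if overlap_mask is not None:
        overlap_mask = np.asarray(overlap_mask, dtype=bool)
        if overlap_mask.shape != a.shape:
            raise ValueError("mask geometry mismatch")
        if not overlap_mask.any():
            raise EmptyOverlapError("no overlapping pixels to compare")
        d = d[overlap_mask]
    elif d.size == 0:
        raise EmptyOverlapError("no overlapping pixels to compare")
    return float(np.mean(d * d))


# ----------------------------------------------------------------------
# Resampling through a transform
# ----------------------------------------------------------------------

def resample_image(
    image: SectionImage,
    t: AffineTransform2D,
    *,
    out_spacing: float | None = None,
    out_shape: tuple | None = None,
    out_origin: Sequence[float] = (0.0, 0.0),
    fill: float = WHITE,
) -> SectionImage:
    """Backward-warp a section through ``t`` (bilinear; out-of-domain filled
    with slide-background white)."""
    out_spacing = image.spacing if out_spacing is None else out_spacing
    out_shape = image.shape if out_shape is None else out_shape
    out = np.empty((*out_shape, 3), dtype=np.uint8)
    for ch in range(3):
        w = warp_raster(
            image.pixels[:, :, ch],
            t,
            in_spacing=image.spacing,
            out_spacing=out_spacing,
            out_shape=out_shape,
            out_origin=out_origin,
            fill=fill,
        )
        out[:, :, ch] = round_half_up(np.clip(w, 0, 255)).astype(np.uint8)
    return SectionImage(out, spacing=out_spacing, index=image.index, thickness=image.thickness)
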