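"""Reading, writing and normalizing volumes and 2D images.

Conventions fixed here and relied on throughout the package:

* ``Volume3D.voxels`` is indexed ``[z, y, x]`` (0-based); ``spacing`` and
  ``origin`` are world-ordered ``(x, y, z)`` in millimetres, so the world
  position of voxel ``(ix, iy, iz)`` is ``origin + (ix*sx, iy*sy, iz*sz)``.
* ``Image2D.pixels`` is indexed ``[row, col]``; ``spacing`` is
  ``(row_spacing, col_spacing)`` in millimetres.

MetaImage and NIfTI volumes are read and written through SimpleITK, whose
array convention matches the one above; PNG/TIFF rasters go through
imageio.  Raster formats carry no reliable physical pixel size, so 2D
spacing is supplied by the caller (default 1.0 mm).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

_VOLUME_EXTENSIONS = (".mhd", ".mha", ".nii", ".nii.gz")


@dataclass
class Volume3D:
    """A 3D scalar image with physical metadata.

    voxels : float array, indexed [z, y, x]
    spacing : (sx, sy, sz) voxel size in mm, all > 0
    origin : world position of voxel (0, 0, 0) in mm, (x, y, z) order
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError(f"all volume dimensions must be >= 2, got {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_center(self) -> np.ndarray:
        """World coordinates (x, y, z) of the volume's physical center, mm."""
        nz, ny, nx = self.voxels.shape
        half = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
        return np.asarray(self.origin) + half * np.asarray(self.spacing)


@dataclass
class Image2D:
    """A 2D scalar image; pixels indexed [row, col], spacing (row, col) in mm."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if np.isscalar(self.spacing) or np.ndim(self.spacing) == 0:
            self.spacing = (float(self.spacing), float(self.spacing))
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if any(n < 2 for n in self.pixels.shape):
            raise ValueError(f"image dimensions must be >= 2, got {self.pixels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _check_volume_extension(path: str) -> None:
    if not str(path).lower().endswith(_VOLUME_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path!r}; expected one of {_VOLUME_EXTENSIONS}"
        )


def load_volume(path: str) -> Volume3D:
    """Load a MetaImage (.mhd/.mha) or NIfTI (.nii/.nii.gz) volume."""
    _check_volume_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img).astype(np.float64)  # [z, y, x]
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path!r}, got {voxels.ndim}D")
    if not np.all(np.isfinite(voxels)):
        raise ValueError(f"volume {path!r} contains non-finite voxels")
    return Volume3D(voxels=voxels, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def save_volume(vol: Volume3D, path: str) -> None:
    """Write a volume in MetaImage or NIfTI format; reloadable by load_volume."""
    _check_volume_extension(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise IOError(f"cannot write volume: directory not writable: {parent}")
    img = sitk.GetImageFromArray(vol.voxels)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def load_image2d(path: str, spacing: float | tuple[float, float] = 1.0) -> Image2D:
    """Load a PNG or TIFF image as grayscale.

    `spacing` (mm) must be supplied by the caller — raster headers do not
    carry it portably.  RGB inputs with unequal channels are converted to
    luminance with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (np.allclose(rgb[..., 0], rgb[..., 1]) and np.allclose(rgb[..., 1], rgb[..., 2])):
            logger.warning("RGB image %s has unequal channels; converting to luminance", path)
        arr = rgb @ np.array([0.2126, 0.7152, 0.0722])
    return Image2D(pixels=arr, spacing=spacing)


def save_image2d(img: Image2D, path: str, bit_depth: int = 16) -> None:
    """Write a grayscale PNG/TIFF, min-max scaled to the full bit-depth range.

    A constant image is written as all zeros (its range is empty).
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    maxval = 2**bit_depth - 1
    if hi > lo:
        scaled = np.round((px - lo) / (hi - lo) * maxval)
    else:
        scaled = np.zeros_like(px)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(path, scaled.astype(dtype))


def normalize_intensity(img: Image2D) -> Image2D:
    """Linearly rescale pixel values to [0, 1]; a constant image maps to 0."""
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        out = (px - lo) / (hi - lo)
    else:
        out = np.zeros_like(px)
    return Image2D(pixels=out, spacing=img.spacing)
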