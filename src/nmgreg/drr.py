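"""Digitally reconstructed radiograph (DRR) rendering.

The DRR is the simulated X-ray projection of the posed 3D volume that the
registration compares against the fixed 2D image at every iteration.  Each
detector pixel value is the line integral of volume intensity along its
ray, computed by fixed-step ray marching with trilinear interpolation
(voxels outside the volume contribute zero), multiplied by the step
length.  Intensities are integrated directly — no Beer-Lambert
exponentiation — which keeps the projector linear and analytically
testable; the similarity metrics used downstream are robust to monotone
intensity maps.

Geometry convention: before the pose is applied, the detector normal is
the world +Y axis.  Detector columns run along world +X, detector rows
along world +Z, and the detector is centered laterally on the volume
center.  In perspective mode the point source sits at
``center - (0, source_to_iso, 0)`` and the detector plane at
``center + (0, iso_to_detector, 0)``; rays fan from the source through
the detector pixels.  In parallel mode all rays run along +Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._raycast import march
from .geometry import RigidTransform6, to_matrix, invert_matrix
from .volume_io import Image2D, Volume3D


@dataclass
class ProjectionGeometry:
    """Detector and ray-sampling description for DRR rendering.

    mode : "parallel" or "perspective"
    source_to_iso : source-to-isocenter distance, mm (perspective only)
    iso_to_detector : isocenter-to-detector distance, mm
    detector_rows, detector_cols : detector size in pixels
    detector_spacing : pixel pitch, mm
    ray_step : sampling step along each ray, mm (must not exceed the
        smallest voxel spacing of the volume being projected)
    """

    mode: str = "parallel"
    source_to_iso: float = 1000.0
    iso_to_detector: float = 200.0
    detector_rows: int = 128
    detector_cols: int = 128
    detector_spacing: float = 1.0
    ray_step: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "perspective"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if self.detector_rows < 2 or self.detector_cols < 2:
            raise ValueError("detector must be at least 2x2 pixels")
        for name in ("source_to_iso", "iso_to_detector", "detector_spacing", "ray_step"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite length, got {v}")

    def scaled(self, factor: int) -> "ProjectionGeometry":
        """Geometry for a pyramid level downsampled by `factor` (>=1).

        Detector resolution shrinks and pixel pitch grows by the same
        factor, preserving the physical field of view.
        """
        return ProjectionGeometry(
            mode=self.mode,
            source_to_iso=self.source_to_iso,
            iso_to_detector=self.iso_to_detector,
            detector_rows=int(np.ceil(self.detector_rows / factor)),
            detector_cols=int(np.ceil(self.detector_cols / factor)),
            detector_spacing=self.detector_spacing * factor,
            ray_step=self.ray_step,
        )


def _ray_box_range(origins, dirs, lo, hi):
    """Entry/exit ray parameters for an axis-aligned box (slab method).

    Returns (t0, t1) arrays; rays that miss have t1 <= t0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        ta = (lo - origins) * inv
        tb = (hi - origins) * inv
    # Axes with zero direction: inside the slab -> (-inf, inf), outside -> miss
    zero = dirs == 0.0
    if np.any(zero):
        inside = (origins >= lo) & (origins <= hi)
        ta = np.where(zero, np.where(inside, -np.inf, np.inf), ta)
        tb = np.where(zero, np.where(inside, np.inf, -np.inf), tb)
    tmin = np.minimum(ta, tb).max(axis=-1)
    tmax = np.maximum(ta, tb).min(axis=-1)
    return tmin, tmax


def project(
    vol: Volume3D,
    pose: RigidTransform6,
    geom: ProjectionGeometry,
    normalize: bool = False,
) -> Image2D:
    """Render the DRR of `vol` posed by `pose` onto the detector of `geom`."""
    if geom.ray_step > min(vol.spacing) + 1e-12:
        raise ValueError(
            f"ray_step {geom.ray_step} exceeds min voxel spacing {min(vol.spacing)}"
        )
    center = vol.world_center()
    m = to_matrix(pose)
    minv = invert_matrix(m)

    rows, cols = geom.detector_rows, geom.detector_cols
    us = (np.arange(cols) - (cols - 1) / 2) * geom.detector_spacing  # along +X
    vs = (np.arange(rows) - (rows - 1) / 2) * geom.detector_spacing  # along +Z
    det_y = center[1] + geom.iso_to_detector
    px, pz = np.meshgrid(us + center[0], vs + center[2])  # (rows, cols)
    det_pts = np.stack([px, np.full_like(px, det_y), pz], axis=-1)

    if geom.mode == "parallel":
        origins = det_pts.copy()
        origins[..., 1] = center[1] - geom.source_to_iso  # start well before the volume
        dirs = np.zeros_like(origins)
        dirs[..., 1] = 1.0
    else:
        source = center - np.array([0.0, geom.source_to_iso, 0.0])
        dirs = det_pts - source
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        origins = np.broadcast_to(source, det_pts.shape).copy()

    # Move rays into the volume frame: q(t) = Minv (o + t d)
    o2 = origins @ minv[:3, :3].T + minv[:3, 3]
    d2 = dirs @ minv[:3, :3].T

    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    nz, ny, nx = vol.voxels.shape
    # Pad the clip box by one voxel so boundary interpolation is not cut off.
    lo = origin - spacing
    hi = origin + spacing * np.array([nx, ny, nz])
    t0, t1 = _ray_box_range(o2, d2, lo, hi)
    hit = t1 > t0
    if not np.any(hit):
        img = np.zeros((rows, cols))
        return Image2D(pixels=img, spacing=geom.detector_spacing)
    t0 = np.where(hit, t0, 0.0)
    span = float((np.where(hit, t1 - t0, 0.0)).max())
    n_steps = max(1, int(np.ceil(span / geom.ray_step)))
    img = march(vol.voxels, o2, d2, t0, hit, n_steps, geom.ray_step, origin, spacing)

    if normalize:
        lo_, hi_ = img.min(), img.max()
        img = (img - lo_) / (hi_ - lo_) if hi_ > lo_ else np.zeros_like(img)
    return Image2D(pixels=img, spacing=geom.detector_spacing)


def default_geometry(vol: Volume3D, rows: int = 128, cols: int = 128) -> ProjectionGeometry:
    """Parallel geometry whose detector covers the volume with >=5% margin.

    The detector is centered on the volume; pixel pitch is chosen from the
    volume's projected bounding box, and the ray step is half the smallest
    voxel spacing.
    """
    if rows < 2 or cols < 2:
        raise ValueError("detector must be at least 2x2 pixels")
    nz, ny, nx = vol.voxels.shape
    ext_x = nx * vol.spacing[0]
    ext_z = nz * vol.spacing[2]
    ext_y = ny * vol.spacing[1]
    spacing = 1.1 * max(ext_x / cols, ext_z / rows)
    return ProjectionGeometry(
        mode="parallel",
        source_to_iso=ext_y,  # parallel rays start this far before the volume
        iso_to_detector=ext_y,
        detector_rows=rows,
        detector_cols=cols,
        detector_spacing=spacing,
        ray_step=0.5 * min(vol.spacing),
    )
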