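"""Seeded synthetic vessel phantoms and ground-truth pose benchmarks.

Real paired CTA/angiogram data cannot ship with the package, so every
pipeline stage is exercised on synthetic volumes that emulate what the
similarity metric actually depends on: sparse, bright, curvilinear
(vessel-like) structure on a dark background.  Each phantom is a set of
smooth random-walk tubes with antialiased (partial-volume) rasterization
and optional additive Gaussian noise.  Randomness comes from numpy's
default PCG64 generator seeded explicitly, so identical seeds give
bit-identical volumes on any platform.

A benchmark case packages a phantom together with a reference DRR
rendered at a known all-zero ground-truth pose under a perspective
geometry (source-to-isocenter 1000 mm, isocenter-to-detector 200 mm) and
a displaced initial pose, so pose-recovery accuracy can be scored
exactly.  The canonical initial displacement is (0, 0, 0, 10, -50, -70)
(deg, mm) scaled by phantom extent / 256 mm, so that the standard
clinical-scale offset keeps its shape at desk scale; perspective
geometry is used because a parallel beam is blind to translation along
the ray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drr import ProjectionGeometry, project
from .geometry import RigidTransform6
from .volume_io import Image2D, Volume3D

BENCHMARK_INIT_OFFSETS = (0.0, 0.0, 0.0, 10.0, -50.0, -70.0)  # deg, mm at 256 mm extent
BENCHMARK_TRIAL_STEP = 20.0  # per-trial increment at 256 mm extent


@dataclass
class PhantomConfig:
    size: int = 64  # voxels per axis
    spacing: float = 1.0  # mm, isotropic
    n_branches: int = 4
    tube_radius: tuple[float, float] = (1.5, 3.0)  # mm
    tube_intensity: float = 1.0
    background: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"size must be >= 32, got {self.size}")
        if not (0 < self.tube_radius[0] <= self.tube_radius[1]):
            raise ValueError(f"invalid tube radius range {self.tube_radius}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")


class PhantomGenerationError(RuntimeError):
    pass


def _random_centerline(rng, size: int, margin: float, n_pts: int = 120):
    """Smooth random-walk polyline staying inside [margin, size-1-margin]^3.

    Returns None if the walk leaves the bounds (caller retries).
    """
    lo, hi = margin, size - 1 - margin
    p = rng.uniform(size * 0.3, size * 0.7, size=3)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    step = size / 90.0
    pts = [p.copy()]
    for _ in range(n_pts - 1):
        d = d + 0.25 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        p = p + step * d
        if np.any(p < lo) or np.any(p > hi):
            return None
        pts.append(p.copy())
    return np.asarray(pts)


def make_vessel_phantom(cfg: PhantomConfig) -> Volume3D:
    """Render a seeded tubular-vessel volume per the configuration."""
    rng = np.random.default_rng(cfg.seed)
    size = cfg.size
    vox = np.full((size, size, size), float(cfg.background))
    tube = np.zeros_like(vox)
    r_lo, r_hi = (r / cfg.spacing for r in cfg.tube_radius)  # radii in voxels
    margin = r_hi + 1.5

    for _ in range(cfg.n_branches):
        line = None
        for _attempt in range(100):
            line = _random_centerline(rng, size, margin)
            if line is not None:
                break
        if line is None:
            raise PhantomGenerationError(
                f"could not place a tube inside bounds after 100 attempts (size={size})"
            )
        # Radius varies smoothly along the branch.
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(1.0, 3.0)
        ts = np.linspace(0, 1, len(line))
        radii = r_lo + (r_hi - r_lo) * 0.5 * (1 + np.sin(2 * np.pi * freq * ts + phase))
        # Stamp antialiased balls along the (already half-voxel-spaced) centerline.
        for c, r in zip(line, radii):
            w = int(np.ceil(r + 1))
            zlo = max(int(np.floor(c[2])) - w, 0)
            ylo = max(int(np.floor(c[1])) - w, 0)
            xlo = max(int(np.floor(c[0])) - w, 0)
            zhi = min(int(np.floor(c[2])) + w + 1, size)
            yhi = min(int(np.floor(c[1])) + w + 1, size)
            xhi = min(int(np.floor(c[0])) + w + 1, size)
            zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
            dist = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
            prof = np.clip(r - dist + 0.5, 0.0, 1.0)  # partial-volume edge
            region = tube[zlo:zhi, ylo:yhi, xlo:xhi]
            np.maximum(region, prof, out=region)

    vox += cfg.tube_intensity * tube
    if cfg.noise_sigma > 0:
        vox += rng.normal(0.0, cfg.noise_sigma, size=vox.shape)
    return Volume3D(voxels=vox, spacing=(cfg.spacing,) * 3)


def benchmark_geometry(vol: Volume3D, rows: int = 128, cols: int = 128) -> ProjectionGeometry:
    """Perspective geometry used by the pose-recovery benchmark."""
    nz, ny, nx = vol.voxels.shape
    extent = max(nx * vol.spacing[0], nz * vol.spacing[2])
    src, det = 1000.0, 200.0
    magnification = (src + det) / src
    spacing = 1.4 * magnification * extent / min(rows, cols)
    return ProjectionGeometry(
        mode="perspective",
        source_to_iso=src,
        iso_to_detector=det,
        detector_rows=rows,
        detector_cols=cols,
        detector_spacing=spacing,
        ray_step=0.5 * min(vol.spacing),
    )


def make_benchmark_case(
    seed: int,
    scale: float = 64.0,
    trial: int = 0,
    cfg: PhantomConfig | None = None,
):
    """One ground-truth pose-recovery case.

    Returns (volume, fixed DRR, truth pose, init pose, geometry).  The
    truth pose is all zeros; the fixed image is the phantom's own DRR at
    truth; the initial pose is the canonical offset scaled by
    ``scale/256``, with `trial` adding ``20*scale/256`` to each
    translation per the five-trial perturbation protocol.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    cfg = cfg or PhantomConfig(size=int(round(scale)), spacing=1.0, seed=seed)
    vol = make_vessel_phantom(cfg)
    geom = benchmark_geometry(vol)
    center = tuple(vol.world_center())
    truth = RigidTransform6(center=center)
    fixed = project(vol, truth, geom, normalize=False)
    f = scale / 256.0
    off = np.asarray(BENCHMARK_INIT_OFFSETS) * f
    off[3:] += trial * BENCHMARK_TRIAL_STEP * f * np.sign(np.where(off[3:] == 0, 1.0, off[3:]))
    init = RigidTransform6.from_params(off, center=center)
    return vol, fixed, truth, init, geom
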