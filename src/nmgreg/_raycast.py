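"""Trilinear ray-marching kernel for DRR rendering.

The volume is treated as a trilinearly interpolated field that falls
linearly to zero over one voxel beyond the boundary voxel centers
(zero padding participates in the interpolation), so the field's spatial
integral equals sum(voxels) * voxel volume and parallel-beam projections
conserve mass.  Compiled with numba for throughput; the pure-Python
fallback keeps the package importable if JIT compilation is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _march_kernel(vox, o2, d2, t0, hit, n_steps, step, origin, inv_spacing, out):
    rows, cols = out.shape
    nz, ny, nx = vox.shape
    for r in range(rows):
        for c in range(cols):
            if not hit[r, c]:
                out[r, c] = 0.0
                continue
            ox = (o2[r, c, 0] - origin[0]) * inv_spacing[0]
            oy = (o2[r, c, 1] - origin[1]) * inv_spacing[1]
            oz = (o2[r, c, 2] - origin[2]) * inv_spacing[2]
            dx = d2[r, c, 0] * inv_spacing[0]
            dy = d2[r, c, 1] * inv_spacing[1]
            dz = d2[r, c, 2] * inv_spacing[2]
            acc = 0.0
            t = t0[r, c] + 0.5 * step
            for _ in range(n_steps):
                fx = ox + t * dx
                fy = oy + t * dy
                fz = oz + t * dz
                t += step
                if fx <= -1.0 or fx >= nx or fy <= -1.0 or fy >= ny or fz <= -1.0 or fz >= nz:
                    continue
                x0 = int(np.floor(fx))
                y0 = int(np.floor(fy))
                z0 = int(np.floor(fz))
                wx = fx - x0
                wy = fy - y0
                wz = fz - z0
                for dzi in range(2):
                    zi = z0 + dzi
                    if zi < 0 or zi >= nz:
                        continue
                    wz_ = wz if dzi == 1 else 1.0 - wz
                    for dyi in range(2):
                        yi = y0 + dyi
                        if yi < 0 or yi >= ny:
                            continue
                        wy_ = wy if dyi == 1 else 1.0 - wy
                        for dxi in range(2):
                            xi = x0 + dxi
                            if xi < 0 or xi >= nx:
                                continue
                            wx_ = wx if dxi == 1 else 1.0 - wx
                            acc += wz_ * wy_ * wx_ * vox[zi, yi, xi]
            out[r, c] = acc * step


def march(vox, o2, d2, t0, hit, n_steps, step, origin, spacing):
    """Integrate the volume along each ray; returns a (rows, cols) image."""
    rows, cols = t0.shape
    out = np.empty((rows, cols), dtype=np.float64)
    inv_spacing = 1.0 / np.asarray(spacing, dtype=np.float64)
    _march_kernel(
        np.ascontiguousarray(vox),
        np.ascontiguousarray(o2),
        np.ascontiguousarray(d2),
        np.ascontiguousarray(t0),
        np.ascontiguousarray(hit),
        n_steps,
        float(step),
        np.asarray(origin, dtype=np.float64),
        inv_spacing,
        out,
    )
    return out
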