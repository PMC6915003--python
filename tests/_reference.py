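"""Independent brute-force oracles used only by the tests.

The line-integral oracle computes, for one parallel-beam ray, the exact
intersection length of the ray with every pixel rectangle by Liang–Barsky
slab clipping — an O(n_pixels) per-ray algorithm that shares no code or
construction with the production projector.
"""

from __future__ import annotations

import numpy as np

from acval.image import centered_origin


def ray_integral_exact(values: np.ndarray, spacing, theta: float, s: float) -> float:
    """Exact line integral of a pixel image along one ray (value * mm).

    The ray at angle ``theta`` with radial offset ``s`` passes through
    ``s * (cos t, sin t)`` with direction ``(-sin t, cos t)`` in (x, y).
    """
    ny, nx = values.shape
    dy, dx = spacing
    origin = centered_origin(values.shape, spacing)
    ct, st = np.cos(theta), np.sin(theta)
    px, py = s * ct, s * st
    ux, uy = -st, ct
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    x_lo = origin[1] - dx / 2.0 + jj * dx
    y_lo = origin[0] - dy / 2.0 + ii * dy
    tmin = np.full(values.shape, -np.inf)
    tmax = np.full(values.shape, np.inf)
    eps = 1e-14
    for lo, hi, p, u in ((x_lo, x_lo + dx, px, ux), (y_lo, y_lo + dy, py, uy)):
        if abs(u) > eps:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            tmin = np.maximum(tmin, np.minimum(t1, t2))
            tmax = np.minimum(tmax, np.maximum(t1, t2))
        else:
            outside = (p < lo) | (p > hi)
            tmin = np.where(outside, np.inf, tmin)
    lengths = np.clip(tmax - tmin, 0.0, None)
    lengths[~np.isfinite(lengths)] = 0.0
    return float((values * lengths).sum())


def sinogram_exact(values: np.ndarray, spacing, geom) -> np.ndarray:
    """Brute-force sinogram: the per-ray oracle over the full geometry."""
    out = np.zeros((geom.n_angles, geom.n_radial))
    for a, th in enumerate(geom.angles):
        for r, s in enumerate(geom.offsets):
            out[a, r] = ray_integral_exact(values, spacing, th, s)
    return out
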