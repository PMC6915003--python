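"""Parallel-beam projection and attenuated emission simulation.

The forward model is a 2-D parallel-beam Radon transform with exact
pixel-intersection lengths (Siddon's gridline-crossing construction),
materialised once per (grid, geometry) as a sparse matrix and cached.  The
backprojector is the exact transpose, so the projector/backprojector pair
satisfies the adjoint identity to machine precision — a property the
expectation-maximisation reconstruction relies on.

Emission data are simulated as attenuated line integrals of the activity
image (Beer–Lambert factors ``exp(-integral of mu)`` from a true mu-map),
rescaled to a target total count and Poisson-sampled with a seeded
generator.  Attenuation is the only physics effect modelled: scatter,
randoms, normalisation, decay and dead time are deliberately absent so
that reconstructions under different AC mu-maps differ only through
attenuation correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .image import VoxelImage, centered_origin
from .phantoms import GeometryError

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "Projector",
    "get_projector",
    "line_integrals",
    "attenuation_factors",
    "simulate_emission",
    "default_geometry",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam geometry: angles over [0, pi), radial bins about the centre.

    Radial offsets are ``(k - (n_radial - 1)/2) * bin_width_mm``; with an
    even ``n_radial`` they fall at half-integer multiples of the bin width,
    which keeps rays off the pixel-edge lines at the axis-aligned angles.
    """

    n_angles: int = 180
    n_radial: int = 384
    bin_width_mm: float = 2.4

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.n_radial < 1:
            raise ValueError("n_radial must be >= 1")
        if self.bin_width_mm <= 0:
            raise ValueError("bin_width_mm must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def offsets(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.bin_width_mm

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_radial)

    def covers(self, shape: tuple[int, int], spacing: tuple[float, float]) -> bool:
        """True if the radial extent covers the image circumcircle."""
        half_diag = 0.5 * float(np.hypot(shape[0] * spacing[0], shape[1] * spacing[1]))
        radial_extent = float(np.abs(self.offsets).max()) + self.bin_width_mm / 2.0
        return radial_extent >= half_diag


def default_geometry(
    shape: tuple[int, int] = (256, 256),
    spacing: tuple[float, float] = (2.4, 2.4),
    n_angles: int = 180,
) -> ProjectionGeometry:
    """Geometry with bin width equal to the voxel size covering the diagonal."""
    bw = float(min(spacing))
    half_diag = 0.5 * float(np.hypot(shape[0] * spacing[0], shape[1] * spacing[1]))
    n_radial = int(np.ceil(2 * half_diag / bw)) + 2
    n_radial += n_radial % 2  # even: offsets at half-integer bin widths
    return ProjectionGeometry(n_angles=n_angles, n_radial=n_radial, bin_width_mm=bw)


@dataclass
class Sinogram:
    """Projection-domain data with per-bin attenuation factors.

    ``counts`` holds observed (or noiseless expected) counts; ``scale`` is
    the factor applied to the raw attenuated line integrals to reach the
    requested total counts, so dividing a reconstruction by it restores
    activity units.
    """

    counts: np.ndarray
    geometry: ProjectionGeometry
    attenuation_factors: np.ndarray | None = None
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.geometry.shape:
            raise ValueError("counts shape does not match the geometry")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.attenuation_factors is not None:
            af = np.asarray(self.attenuation_factors, dtype=float)
            if af.shape != self.geometry.shape:
                raise ValueError("attenuation factors shape mismatch")
            if np.any(af <= 0) or np.any(af > 1):
                raise ValueError("attenuation factors must lie in (0, 1]")
            self.attenuation_factors = af


# -- exact Siddon sparse projector ------------------------------------------

_PROJECTOR_CACHE: dict[tuple, "Projector"] = {}


def _siddon_matrix(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    geom: ProjectionGeometry,
) -> sparse.csr_matrix:
    """Sparse (n_angles*n_radial, ny*nx) matrix of exact intersection lengths."""
    ny, nx = shape
    dy, dx = spacing
    origin = centered_origin(shape, spacing)
    # pixel edge coordinates
    x_edges = origin[1] - dx / 2.0 + np.arange(nx + 1) * dx
    y_edges = origin[0] - dy / 2.0 + np.arange(ny + 1) * dy
    x_lo, x_hi = x_edges[0], x_edges[-1]
    y_lo, y_hi = y_edges[0], y_edges[-1]
    offsets = geom.offsets
    rows, cols, vals = [], [], []
    eps = 1e-12
    for a, th in enumerate(geom.angles):
        ct, st = np.cos(th), np.sin(th)
        ux, uy = -st, ct  # ray direction, unit
        for r, s in enumerate(offsets):
            px, py = s * ct, s * st  # a point on the ray
            # slab clipping against the grid bounding box
            tmin, tmax = -np.inf, np.inf
            if abs(ux) > eps:
                t1, t2 = (x_lo - px) / ux, (x_hi - px) / ux
                tmin, tmax = max(tmin, min(t1, t2)), min(tmax, max(t1, t2))
            elif not (x_lo <= px <= x_hi):
                continue
            if abs(uy) > eps:
                t1, t2 = (y_lo - py) / uy, (y_hi - py) / uy
                tmin, tmax = max(tmin, min(t1, t2)), min(tmax, max(t1, t2))
            elif not (y_lo <= py <= y_hi):
                continue
            if tmax <= tmin:
                continue
            ts = [np.array([tmin, tmax])]
            if abs(ux) > eps:
                tx = (x_edges - px) / ux
                ts.append(tx[(tx > tmin) & (tx < tmax)])
            if abs(uy) > eps:
                ty = (y_edges - py) / uy
                ts.append(ty[(ty > tmin) & (ty < tmax)])
            t = np.sort(np.concatenate(ts))
            seg = np.diff(t)
            keep = seg > 1e-9
            if not np.any(keep):
                continue
            tm = 0.5 * (t[:-1] + t[1:])[keep]
            seg = seg[keep]
            ix = np.floor((px + tm * ux - x_lo) / dx).astype(np.intp)
            iy = np.floor((py + tm * uy - y_lo) / dy).astype(np.intp)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            if not np.any(ok):
                continue
            cols.append(iy[ok] * nx + ix[ok])
            vals.append(seg[ok])
            rows.append(np.full(ok.sum(), a * geom.n_radial + r, dtype=np.intp))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    mat = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(geom.n_angles * geom.n_radial, ny * nx)
    )
    return mat.tocsr()


class Projector:
    """Matched projector/backprojector pair for one (grid, geometry)."""

    def __init__(self, shape, spacing, geom: ProjectionGeometry):
        self.shape = tuple(shape)
        self.spacing = tuple(float(s) for s in spacing)
        self.geom = geom
        self.P = _siddon_matrix(self.shape, self.spacing, geom)
        self.PT = self.P.T.tocsr()
        self._subset_cache: dict[int, list] = {}

    def forward(self, image: np.ndarray) -> np.ndarray:
        return (self.P @ np.asarray(image, dtype=float).ravel()).reshape(self.geom.shape)

    def back(self, sino: np.ndarray) -> np.ndarray:
        return (self.PT @ np.asarray(sino, dtype=float).ravel()).reshape(self.shape)

    def subset_operators(self, n_subsets: int) -> list[tuple[np.ndarray, sparse.csr_matrix, sparse.csr_matrix]]:
        """Per-subset (sinogram flat indices, P_s, P_s^T); angles by stride."""
        if n_subsets < 1 or n_subsets > self.geom.n_angles:
            raise ValueError("n_subsets must be between 1 and n_angles")
        if n_subsets not in self._subset_cache:
            ops = []
            nr = self.geom.n_radial
            for s in range(n_subsets):
                angles = np.arange(s, self.geom.n_angles, n_subsets)
                rows = (angles[:, None] * nr + np.arange(nr)[None, :]).ravel()
                Ps = self.P[rows]
                ops.append((rows, Ps, Ps.T.tocsr()))
            self._subset_cache[n_subsets] = ops
        return self._subset_cache[n_subsets]


def get_projector(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    geom: ProjectionGeometry,
) -> Projector:
    key = (tuple(shape), tuple(float(s) for s in spacing), geom.n_angles, geom.n_radial,
           float(geom.bin_width_mm))
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = Projector(shape, spacing, geom)
    return _PROJECTOR_CACHE[key]


def line_integrals(image: VoxelImage, geom: ProjectionGeometry) -> np.ndarray:
    """Radon transform: entry (theta, s) in value*mm; linear in the image."""
    if image.ndim != 2:
        raise ValueError("line_integrals operates on 2-D images")
    if not geom.covers(image.shape, image.spacing):
        raise GeometryError("projection geometry does not cover the image diagonal")
    return get_projector(image.shape, image.spacing, geom).forward(image.values)


def attenuation_factors(mu: VoxelImage, geom: ProjectionGeometry) -> np.ndarray:
    """Beer–Lambert survival factors exp(-integral mu) per LOR, in (0, 1]."""
    if np.any(mu.values < 0):
        raise ValueError("mu-map must be nonnegative")
    return np.exp(-line_integrals(mu, geom))


def simulate_emission(
    activity: VoxelImage,
    mu_true: VoxelImage,
    geom: ProjectionGeometry,
    total_counts: float = 5e6,
    seed: int | None = 0,
    poisson: bool = True,
) -> Sinogram:
    """Attenuated emission sinogram at a target total count level.

    The expected sinogram is ``line_integrals(activity) * exp(-integral mu)``
    rescaled so its sum equals ``total_counts``; observed counts are Poisson
    with the given seed (or the expectation itself with ``poisson=False``).
    The attenuation factors are retained for the reconstructor.
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    if not activity.same_grid(mu_true):
        raise ValueError("activity and mu-map must share one grid")
    proj = line_integrals(activity, geom)
    af = attenuation_factors(mu_true, geom)
    expected_raw = proj * af
    total_raw = expected_raw.sum()
    if total_raw <= 0:
        raise ValueError("activity projects to zero counts; nothing to simulate")
    scale = float(total_counts / total_raw)
    expected = expected_raw * scale
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return Sinogram(counts, geom, attenuation_factors=af, scale=scale,
                    meta={"seed": seed, "total_counts": float(total_counts),
                          "poisson": bool(poisson)})
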