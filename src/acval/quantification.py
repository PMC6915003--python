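"""SUV-style quantification: ROI means, 50% isocontour VOIs, and uniformity.

ROI membership is by voxel-centre-in-circle (no partial-volume weighting).
The uniformity statistic follows the QC convention for a uniform cylinder:
on each analysed slice, four 60 mm circles (B1..B4, placed on an axial
cross at +/-45 mm from the centre) and one central 120 mm circle (A1) are
averaged, the slice uniformity is the larger magnitude of
``(max(B) - A1)/A1`` and ``(min(B) - A1)/A1``, and the whole-image
uniformity is the maximum slice uniformity over the five slices at
0 / +/-30 / +/-60 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VoxelImage

__all__ = [
    "RoiSpec",
    "UniformityLayout",
    "UniformityResult",
    "roi_mean",
    "roi_mask",
    "slice_uniformity",
    "image_uniformity",
    "voi_isocontour",
    "suv_scale",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: physical centre (y, x) in mm and diameter in mm."""

    center: tuple[float, float]
    diameter_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")


def roi_mask(image: VoxelImage, roi: RoiSpec) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the circle."""
    if image.ndim != 2:
        raise ValueError("roi_mask operates on 2-D slices")
    Y, X = image.coord_grids()
    cy, cx = roi.center
    r = roi.diameter_mm / 2.0
    return (Y - cy) ** 2 + (X - cx) ** 2 <= r**2


def roi_mean(image: VoxelImage, roi: RoiSpec) -> float:
    """Mean over voxels whose centres fall inside the circular ROI."""
    m = roi_mask(image, roi)
    if not np.any(m):
        raise ValueError("ROI contains no voxel centres")
    return float(image.values[m].mean())


def slice_uniformity(B: tuple[float, float, float, float], A1: float) -> float:
    """Largest relative deviation of the peripheral means from the central mean.

    ``max(|max(B) - A1|, |min(B) - A1|) / A1``; both signed branches are
    evaluated and the larger magnitude is reported, so a large negative
    deviation counts against uniformity just as a positive one does.
    """
    if A1 <= 0:
        raise ValueError("central ROI mean A1 must be positive")
    b = np.asarray(B, dtype=float)
    if b.size != 4:
        raise ValueError("expected four peripheral ROI means")
    return float(max(abs(b.max() - A1), abs(b.min() - A1)) / A1)


@dataclass(frozen=True)
class UniformityLayout:
    """Slice offsets and circle layout for the uniformity statistic."""

    slice_offsets_mm: tuple[float, ...] = (-60.0, -30.0, 0.0, 30.0, 60.0)
    b_offset_mm: float = 45.0
    b_diameter_mm: float = 60.0
    a_diameter_mm: float = 120.0
    phantom_radius_mm: float = 100.0

    def b_centers(self) -> tuple[tuple[float, float], ...]:
        d = self.b_offset_mm
        return ((d, 0.0), (-d, 0.0), (0.0, d), (0.0, -d))

    def validate(self) -> None:
        if self.b_offset_mm + self.b_diameter_mm / 2.0 > self.phantom_radius_mm:
            raise ValueError("peripheral circles exceed the phantom support")
        if self.a_diameter_mm / 2.0 > self.phantom_radius_mm:
            raise ValueError("central circle exceeds the phantom support")


@dataclass
class UniformityResult:
    """Per-slice ROI means and uniformities plus the whole-image maximum."""

    per_slice: pd.DataFrame  # columns: offset_mm, B1..B4, A1, slice_uniformity
    whole_image_uniformity: float
    layout: UniformityLayout = field(default_factory=UniformityLayout)


def _volume_slices(volume: VoxelImage, layout: UniformityLayout):
    """(offset, 2-D slice) pairs nearest the layout's axial offsets."""
    if volume.ndim == 2:
        yield 0.0, volume
        return
    z = volume.axis_coords(0)
    dz = volume.spacing[0]
    for off in layout.slice_offsets_mm:
        k = int(np.argmin(np.abs(z - off)))
        if abs(z[k] - off) > dz / 2.0 + 1e-9:
            raise ValueError(
                f"volume axial extent does not cover the slice offset {off} mm"
            )
        yield float(off), VoxelImage(volume.values[k], volume.spacing[1:],
                                     volume.origin[1:])


def image_uniformity(
    volume: VoxelImage,
    layout: UniformityLayout | None = None,
) -> UniformityResult:
    """Whole-image uniformity over the five-slice, five-circle layout.

    Accepts a 3-D volume covering the axial offsets (slices nearest
    0 / +/-30 / +/-60 mm are analysed) or a single 2-D slice as a fallback,
    in which case the whole-image value equals that slice's uniformity.
    """
    layout = layout or UniformityLayout()
    layout.validate()
    rows = []
    for off, sl in _volume_slices(volume, layout):
        A1 = roi_mean(sl, RoiSpec((0.0, 0.0), layout.a_diameter_mm))
        B = tuple(roi_mean(sl, RoiSpec(c, layout.b_diameter_mm)) for c in layout.b_centers())
        rows.append({"offset_mm": off, "B1": B[0], "B2": B[1], "B3": B[2], "B4": B[3],
                     "A1": A1, "slice_uniformity": slice_uniformity(B, A1)})
    frame = pd.DataFrame(rows)
    return UniformityResult(frame, float(frame["slice_uniformity"].max()), layout)


def voi_isocontour(
    image: VoxelImage,
    search_region: np.ndarray | RoiSpec,
    fraction: float = 0.5,
) -> np.ndarray:
    """Isocontour VOI: voxels >= fraction * regional max, connected to the max.

    The threshold is inclusive; of the thresholded voxels only the
    connected component containing the regional maximum is retained.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    region = roi_mask(image, search_region) if isinstance(search_region, RoiSpec) \
        else np.asarray(search_region, dtype=bool)
    if region.shape != image.shape:
        raise ValueError("search region grid mismatch")
    vals = image.values
    if not np.any(region & (vals > 0)):
        raise ValueError("search region contains no positive voxel")
    vmax = vals[region].max()
    thresholded = region & (vals >= fraction * vmax)
    lab, _ = ndimage.label(thresholded)
    argmax_flat = np.flatnonzero(region.ravel() & (vals.ravel() == vmax))[0]
    comp = lab.ravel()[argmax_flat]
    return lab == comp


def suv_scale(image: VoxelImage, injected_dose: float, body_weight: float) -> VoxelImage:
    """Standardised-uptake scaling: values * body_weight / injected_dose.

    With the simulation convention dose = weight the reconstructed activity
    is already in SUV units and this is the identity.
    """
    if injected_dose <= 0 or body_weight <= 0:
        raise ValueError("dose and weight must be positive")
    return image.copy_with(image.values * (body_weight / injected_dose))
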