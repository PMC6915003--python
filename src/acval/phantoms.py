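"""Digital phantoms: a uniform cylinder QC phantom and a body-slice phantom.

Two phantoms drive the validation studies:

* a 20 cm uniform cylinder (a Ge-68 QC phantom analog) with optional rigid
  "hardware" attenuators in the field of view — the patient-bed track, the
  bed itself, a spine-coil shell and a head-coil shell — which carry linear
  attenuation but no activity;
* a transaxial body slice with air, lung, fat, soft tissue, liver, bone and
  FDG-avid lesions (one in soft tissue, one in/around a vertebra analog),
  standing in for a patient thorax/abdomen section.

Phantom generation is a pure function of (spec, grid): a fixed seed gives a
bitwise-identical phantom.  Geometry is 2-D (one transaxial slice); axial
stacks for the multi-slice uniformity layout are built by the study drivers
from independent noise realisations of the same slice.

All coordinates are physical mm in (y, x) order, matching array axes, with
the origin at the grid centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import VoxelImage, centered_origin

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "TissueLabelMap",
    "HARDWARE_CONFIGS",
    "PAPER_HARDWARE_CONFIGS",
    "TRUE_LAC_MM",
    "DEFAULT_UPTAKE",
    "make_cylinder_phantom",
    "make_body_phantom",
    "add_hardware",
]


class GeometryError(ValueError):
    """A phantom structure does not fit the requested grid."""


# Integer label codes shared by every phantom.
LABEL_CODES: dict[str, int] = {
    "air": 0,
    "lung": 1,
    "fat": 2,
    "soft": 3,
    "bone": 4,
    "liver": 5,
    "lesion_soft": 6,
    "lesion_bone": 7,
    "hardware_track": 8,
    "hardware_bed": 9,
    "hardware_spine": 10,
    "hardware_head": 11,
}

# Ground-truth linear attenuation coefficients at 511 keV, mm^-1.
# Soft tissue/liver are water-equivalent; fat sits just under the water
# value; bone is the segmented-CT bone value; hardware slabs are
# aluminium-like and coil shells lighter composite shells.
TRUE_LAC_MM: dict[str, float] = {
    "air": 0.0,
    "lung": 0.0032,
    "fat": 0.0088,
    "soft": 0.0096,
    "liver": 0.0096,
    "bone": 0.0161,
    "lesion_soft": 0.0096,
    "lesion_bone": 0.0161,
    "hardware_track": 0.020,
    "hardware_bed": 0.020,
    "hardware_spine": 0.012,
    "hardware_head": 0.012,
}

# Relative activity concentrations (soft tissue = 1); lesion uptake is
# randomised per phantom around 4x background.
DEFAULT_UPTAKE: dict[str, float] = {
    "air": 0.0,
    "lung": 0.3,
    "fat": 0.4,
    "soft": 1.0,
    "bone": 0.6,
    "liver": 1.2,
    "lesion_soft": 4.0,
    "lesion_bone": 4.0,
    "hardware_track": 0.0,
    "hardware_bed": 0.0,
    "hardware_spine": 0.0,
    "hardware_head": 0.0,
}

_HARDWARE_NAMES = ("hardware_track", "hardware_bed", "hardware_spine", "hardware_head")

# Cumulative hardware configurations: each entry is a superset of the one
# before it.  The scanner study sweeps the four PAPER_HARDWARE_CONFIGS.
HARDWARE_CONFIGS: dict[str, tuple[str, ...]] = {
    "none": (),
    "track": ("track",),
    "track+bed": ("track", "bed"),
    "track+bed+spine": ("track", "bed", "spine"),
    "track+bed+spine+head_base": ("track", "bed", "spine", "head_base"),
    "track+bed+spine+head_full": ("track", "bed", "spine", "head_full"),
}

PAPER_HARDWARE_CONFIGS: tuple[str, ...] = (
    "track",
    "track+bed+spine",
    "track+bed+spine+head_base",
    "track+bed+spine+head_full",
)


@dataclass
class TissueLabelMap:
    """Per-voxel tissue class with ground-truth LAC and uptake lookups."""

    labels: np.ndarray  # integer codes per LABEL_CODES
    spacing: tuple[float, ...]
    origin: tuple[float, ...]
    lac_true: dict[str, float] = field(default_factory=lambda: dict(TRUE_LAC_MM))
    uptake: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UPTAKE))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        present = {name for name, code in LABEL_CODES.items() if np.any(self.labels == code)}
        for name in present:
            if name not in self.lac_true or name not in self.uptake:
                raise ValueError(f"label {name!r} missing from lac_true/uptake lookup")
        if self.lac_true.get("air", 0.0) != 0.0:
            raise ValueError("air must have zero LAC")

    def mask(self, *names: str) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        for name in names:
            m |= self.labels == LABEL_CODES[name]
        return m

    def _lookup_image(self, table: dict[str, float]) -> VoxelImage:
        out = np.zeros(self.labels.shape, dtype=float)
        for name, code in LABEL_CODES.items():
            if name in table:
                out[self.labels == code] = table[name]
        return VoxelImage(out, self.spacing, self.origin)

    def lac_image(self) -> VoxelImage:
        """Ground-truth LAC map (mm^-1), hardware included."""
        return self._lookup_image(self.lac_true)

    def hardware_lac_image(self) -> VoxelImage:
        """LAC map of the hardware structures alone (mm^-1)."""
        table = {k: (self.lac_true[k] if k in _HARDWARE_NAMES else 0.0) for k in self.lac_true}
        return self._lookup_image(table)

    def activity_image(self) -> VoxelImage:
        """Relative activity-concentration map; zero in air and hardware."""
        return self._lookup_image(self.uptake)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom realisation.

    ``kind`` selects the cylinder QC phantom or the body slice.  For the
    body slice the seed drives lesion placement/size/uptake jitter; the
    cylinder is fully deterministic apart from the hardware configuration.
    """

    kind: str = "cylinder"
    cylinder_diameter_mm: float = 200.0
    activity: float = 1.0
    hardware_config: str = "none"
    seed: int = 0
    lesion_uptake_range: tuple[float, float] = (3.0, 5.0)
    soft_lesion_radius_range: tuple[float, float] = (6.0, 10.0)
    bone_lesion_radius_range: tuple[float, float] = (4.0, 6.0)

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "body_slice"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.hardware_config not in HARDWARE_CONFIGS:
            raise ValueError(f"unknown hardware config {self.hardware_config!r}")
        if self.cylinder_diameter_mm < 0:
            raise ValueError("cylinder diameter must be >= 0")


def _grid_coords(shape: tuple[int, int], spacing: tuple[float, float]):
    origin = centered_origin(shape, spacing)
    y = origin[0] + np.arange(shape[0]) * spacing[0]
    x = origin[1] + np.arange(shape[1]) * spacing[1]
    Y, X = np.meshgrid(y, x, indexing="ij")
    return Y, X, origin


def make_cylinder_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int] = (256, 256),
    spacing: tuple[float, float] = (2.4, 2.4),
) -> tuple[VoxelImage, TissueLabelMap]:
    """Uniform 20 cm cylinder: constant activity inside, air outside.

    Hardware attenuators from ``spec.hardware_config`` are stamped into the
    label map with zero activity.  Raises :class:`GeometryError` if the
    cylinder does not fit the grid.
    """
    if spec.kind != "cylinder":
        raise ValueError("spec.kind must be 'cylinder'")
    Y, X, origin = _grid_coords(shape, spacing)
    r = spec.cylinder_diameter_mm / 2.0
    half_extent = min((shape[0] - 1) / 2 * spacing[0], (shape[1] - 1) / 2 * spacing[1])
    if r > half_extent:
        raise GeometryError(
            f"cylinder radius {r} mm exceeds grid half-extent {half_extent:.1f} mm"
        )
    inside = (Y**2 + X**2) <= r**2
    labels = np.where(inside, LABEL_CODES["soft"], LABEL_CODES["air"]).astype(np.int16)
    lmap = TissueLabelMap(labels, spacing, origin, meta={"cylinder_radius_mm": r})
    lmap = add_hardware(lmap, spec.hardware_config)
    activity = np.where(inside, float(spec.activity), 0.0)
    return VoxelImage(activity, spacing, origin), lmap


# -- body-slice phantom -----------------------------------------------------

# Fixed anatomy (mm, (y, x) centres).  Fits a 307 mm grid (128 @ 2.4 mm).
_BODY = {
    "body_semi": (95.0, 140.0),      # outer ellipse (fat boundary)
    "inner_semi": (85.0, 130.0),     # soft-tissue interior; rim between is fat
    "lung_semi": (42.0, 32.0),
    "lung_centers": ((20.0, -55.0), (20.0, 55.0)),
    "liver_center": (-45.0, 50.0),
    "liver_semi": (18.0, 28.0),
    "vertebra_center": (-50.0, 0.0),
    "vertebra_radius": 14.0,
    "sternum_center": (60.0, 0.0),   # second bone structure, hosts the organ ROI
    "sternum_radius": 12.0,
    "soft_lesion_base": (-50.0, -55.0),
    "soft_lesion_jitter": 6.0,
    "bone_lesion_jitter": 4.0,
}

# Organ ROI centres (y, x) used by the comparison study (20 mm circles).
BODY_ORGAN_ROIS: dict[str, tuple[float, float]] = {
    "bone": _BODY["sternum_center"],
    "liver": _BODY["liver_center"],
    "lung": (20.0, 55.0),
}


def _ellipse(Y, X, center, semi) -> np.ndarray:
    cy, cx = center
    sy, sx = semi
    return ((Y - cy) / sy) ** 2 + ((X - cx) / sx) ** 2 <= 1.0


def _disk(Y, X, center, radius) -> np.ndarray:
    cy, cx = center
    return (Y - cy) ** 2 + (X - cx) ** 2 <= radius**2


def make_body_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int] = (256, 256),
    spacing: tuple[float, float] = (2.4, 2.4),
) -> tuple[VoxelImage, TissueLabelMap]:
    """Body-slice phantom with lungs, fat rim, liver, bone and two lesions.

    The seed jitters lesion centres, radii and uptake (uptake uniform in
    ``spec.lesion_uptake_range``, i.e. well above 2x local background); the
    surrounding anatomy is fixed.  Lesion metadata (centres, radii, uptake)
    is recorded in ``labels.meta`` for ROI/VOI placement downstream.
    """
    if spec.kind != "body_slice":
        raise ValueError("spec.kind must be 'body_slice'")
    Y, X, origin = _grid_coords(shape, spacing)
    by, bx = _BODY["body_semi"]
    half_y = (shape[0] - 1) / 2 * spacing[0]
    half_x = (shape[1] - 1) / 2 * spacing[1]
    if by > half_y or bx > half_x:
        raise GeometryError("body outline exceeds grid extent")

    rng = np.random.default_rng(spec.seed)
    jy, jx = rng.uniform(-_BODY["soft_lesion_jitter"], _BODY["soft_lesion_jitter"], 2)
    soft_center = (_BODY["soft_lesion_base"][0] + jy, _BODY["soft_lesion_base"][1] + jx)
    soft_radius = rng.uniform(*spec.soft_lesion_radius_range)
    soft_uptake = rng.uniform(*spec.lesion_uptake_range)
    ky, kx = rng.uniform(-_BODY["bone_lesion_jitter"], _BODY["bone_lesion_jitter"], 2)
    bone_center = (_BODY["vertebra_center"][0] + ky, _BODY["vertebra_center"][1] + kx)
    bone_radius = rng.uniform(*spec.bone_lesion_radius_range)
    bone_uptake = rng.uniform(*spec.lesion_uptake_range)

    labels = np.full(shape, LABEL_CODES["air"], dtype=np.int16)
    labels[_ellipse(Y, X, (0.0, 0.0), _BODY["body_semi"])] = LABEL_CODES["fat"]
    labels[_ellipse(Y, X, (0.0, 0.0), _BODY["inner_semi"])] = LABEL_CODES["soft"]
    for lc in _BODY["lung_centers"]:
        labels[_ellipse(Y, X, lc, _BODY["lung_semi"])] = LABEL_CODES["lung"]
    labels[_ellipse(Y, X, _BODY["liver_center"], _BODY["liver_semi"])] = LABEL_CODES["liver"]
    labels[_disk(Y, X, _BODY["vertebra_center"], _BODY["vertebra_radius"])] = LABEL_CODES["bone"]
    labels[_disk(Y, X, _BODY["sternum_center"], _BODY["sternum_radius"])] = LABEL_CODES["bone"]

    soft_mask = _disk(Y, X, soft_center, soft_radius)
    bone_mask = _disk(Y, X, bone_center, bone_radius)
    if np.any(soft_mask & bone_mask):
        raise ValueError("soft-tissue and bone lesions overlap with incompatible labels")
    labels[soft_mask] = LABEL_CODES["lesion_soft"]
    labels[bone_mask] = LABEL_CODES["lesion_bone"]

    uptake = dict(DEFAULT_UPTAKE)
    uptake["lesion_soft"] = float(soft_uptake)
    uptake["lesion_bone"] = float(bone_uptake)
    meta = {
        "lesion_soft": {"center": tuple(map(float, soft_center)), "radius": float(soft_radius),
                        "uptake": float(soft_uptake)},
        "lesion_bone": {"center": tuple(map(float, bone_center)), "radius": float(bone_radius),
                        "uptake": float(bone_uptake)},
        "organ_rois": dict(BODY_ORGAN_ROIS),
    }
    lmap = TissueLabelMap(labels, spacing, origin, uptake=uptake, meta=meta)
    lmap = add_hardware(lmap, spec.hardware_config)
    return lmap.activity_image(), lmap


# -- hardware attenuators ---------------------------------------------------

def _hardware_part_mask(part: str, Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, str]:
    """Boolean mask and label name of one rigid attenuator (2-D slice)."""
    R = np.hypot(Y, X)
    if part == "track":
        return (Y >= -140.0) & (Y <= -132.0) & (np.abs(X) <= 200.0), "hardware_track"
    if part == "bed":
        return (Y >= -130.0) & (Y <= -118.0) & (np.abs(X) <= 180.0), "hardware_bed"
    if part == "spine":
        # arc shell under the phantom, +/-60 degrees about straight down
        ang = np.arctan2(X, -Y)  # 0 pointing straight down
        return (R >= 104.0) & (R <= 112.0) & (np.abs(ang) <= np.deg2rad(60)), "hardware_spine"
    if part == "head_base":
        return (R >= 115.0) & (R <= 121.0) & (Y < 0), "hardware_head"
    if part == "head_full":
        return (R >= 115.0) & (R <= 121.0), "hardware_head"
    raise ValueError(f"unknown hardware part {part!r}")


def add_hardware(labels: TissueLabelMap, config: str) -> TissueLabelMap:
    """Stamp the rigid attenuators of ``config`` into air regions.

    Configurations are cumulative (each is a superset of the previous one);
    hardware voxels carry LAC but zero activity.  ``config='none'`` returns
    the input unchanged.
    """
    parts = HARDWARE_CONFIGS[config]
    if not parts:
        return labels
    out = labels.labels.copy()
    origin = labels.origin
    y = origin[0] + np.arange(out.shape[0]) * labels.spacing[0]
    x = origin[1] + np.arange(out.shape[1]) * labels.spacing[1]
    Y, X = np.meshgrid(y, x, indexing="ij")
    for part in parts:
        mask, name = _hardware_part_mask(part, Y, X)
        out[mask & (labels.labels == LABEL_CODES["air"])] = LABEL_CODES[name]
    meta = dict(labels.meta)
    meta["hardware_config"] = config
    return replace(labels, labels=out, meta=meta)
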