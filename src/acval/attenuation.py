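"""Attenuation-map construction: continuous CT, segmented CT, and MRAC.

Three 511 keV mu-maps are compared throughout the package:

``ct_continuous``
    Bilinear Hounsfield-to-LAC conversion of a CT image.  A single linear
    segment cannot hit air, water and bone simultaneously, so the standard
    two-segment form is used: below 0 HU the map interpolates air to water,
    above 0 HU a shallower bone slope applies.

``ct_segmented``
    The continuous map quantised to five discrete LACs (air / fat / water /
    bone, plus a lung override) by thresholds on LAC.

``mrac``
    A four-class segmentation (air, lung, fat, soft tissue) as produced by
    Dixon-based MR attenuation correction.  Bone is *not* a class: bony
    voxels receive the soft-tissue LAC, which is the central MRAC
    limitation this package quantifies.  Rigid hardware attenuation maps
    (known to the scanner from CT) may be composited in.

The canonical internal unit is mm^-1; scanner class tables quoted in cm^-1
(0.096, 0.080, 0.032, 0) are converted once at the class-table boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import VoxelImage
from .phantoms import LABEL_CODES, TissueLabelMap

__all__ = [
    "MuMap",
    "LacSegmentationRule",
    "MracClassTable",
    "hu_to_lac",
    "synth_ct_from_labels",
    "segment_ct_lac",
    "mrac_mumap",
    "WATER_LAC_MM",
    "BONE_SLOPE_PER_HU",
]

# Water LAC at 511 keV (mm^-1) and the bone-branch slope of the bilinear
# HU -> LAC conversion.
WATER_LAC_MM = 0.0096
BONE_SLOPE_PER_HU = 5.1e-6
MU_SANITY_BOUND = 0.05  # mm^-1, > 2x cortical bone


class MuMap(VoxelImage):
    """A 511 keV LAC image (mm^-1) with a provenance tag."""

    PROVENANCES = ("truth", "ct_continuous", "ct_segmented", "mrac", "mrac_no_hardware", "custom")

    def __init__(self, values, spacing, origin=None, provenance: str = "custom"):
        super().__init__(values, spacing, origin)
        if provenance not in self.PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        self.provenance = provenance
        if np.any(self.values < 0):
            raise ValueError("LAC values must be nonnegative")
        if np.any(self.values > MU_SANITY_BOUND):
            raise ValueError(f"LAC values exceed sanity bound {MU_SANITY_BOUND} mm^-1")

    @classmethod
    def from_image(cls, image: VoxelImage, provenance: str = "custom") -> "MuMap":
        return cls(image.values, image.spacing, image.origin, provenance)


@dataclass(frozen=True)
class LacSegmentationRule:
    """Thresholds (on LAC, mm^-1) and assigned values for segmented CT.

    Half-open bins [lo, hi) with the bone bin unbounded above; the lung
    value cannot be produced by the bins (it falls inside the fat bin), so
    lung voxels are overridden by a mask after binning.
    """

    t_air: float = 0.003
    t_fat: float = 0.009
    t_water: float = 0.011
    v_air: float = 0.0
    v_fat: float = 0.008
    v_water: float = 0.0096
    v_bone: float = 0.0161
    v_lung: float = 0.0032

    def __post_init__(self) -> None:
        if not (self.t_air < self.t_fat < self.t_water):
            raise ValueError("thresholds must be strictly increasing")
        # idempotence support: each assigned non-lung value lies in its own bin
        if not (self.v_air < self.t_air):
            raise ValueError("air value must fall in the air bin")
        if not (self.t_air <= self.v_fat < self.t_fat):
            raise ValueError("fat value must fall in the fat bin")
        if not (self.t_fat <= self.v_water < self.t_water):
            raise ValueError("water value must fall in the water bin")
        if not (self.v_bone >= self.t_water):
            raise ValueError("bone value must fall in the bone bin")


@dataclass(frozen=True)
class MracClassTable:
    """Four-class MRAC LACs, stored in mm^-1.

    The scanner specifies soft tissue 0.096, fat 0.080, lung 0.032 and air
    0 cm^-1; there is deliberately no bone entry.
    """

    soft: float = 0.0096
    fat: float = 0.0080
    lung: float = 0.0032
    air: float = 0.0


def hu_to_lac(ct_hu: VoxelImage) -> MuMap:
    """Bilinear HU -> 511 keV LAC conversion (continuous CT mu-map).

    HU <= 0 maps linearly from air (-1000 HU -> 0) to water (0 HU ->
    0.0096 mm^-1), floored at zero; HU > 0 follows the bone branch
    0.0096 + 5.1e-6 * HU.  Monotone nondecreasing in HU.
    """
    hu = ct_hu.values
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    if np.any(hu < -1024):
        raise ValueError("HU values below -1024 are not supported")
    lac = np.where(
        hu <= 0,
        np.maximum(WATER_LAC_MM * (1.0 + hu / 1000.0), 0.0),
        WATER_LAC_MM + BONE_SLOPE_PER_HU * hu,
    )
    return MuMap(lac, ct_hu.spacing, ct_hu.origin, provenance="ct_continuous")


def synth_ct_from_labels(
    labels: TissueLabelMap,
    noise_sd_hu: float = 0.0,
    seed: int | None = None,
) -> VoxelImage:
    """Synthesise a CT image (HU) whose bilinear conversion reproduces lac_true.

    Inverts :func:`hu_to_lac` class-wise: LAC <= water inverts the soft
    branch, LAC > water the bone branch.  Optional seeded additive Gaussian
    HU noise models CT measurement noise.
    """
    hu = np.zeros(labels.labels.shape, dtype=float)
    max_lac = WATER_LAC_MM + BONE_SLOPE_PER_HU * 30000.0
    for name, code in LABEL_CODES.items():
        m = labels.labels == code
        if not np.any(m):
            continue
        lac = labels.lac_true[name]
        if lac > max_lac:
            raise ValueError(f"LAC {lac} mm^-1 for {name!r} exceeds the representable HU range")
        if lac <= WATER_LAC_MM:
            hu[m] = 1000.0 * (lac / WATER_LAC_MM - 1.0)
        else:
            hu[m] = (lac - WATER_LAC_MM) / BONE_SLOPE_PER_HU
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = np.maximum(hu + rng.normal(0.0, noise_sd_hu, hu.shape), -1000.0)
    return VoxelImage(hu, labels.spacing, labels.origin)


def segment_ct_lac(
    mu_ct: MuMap | VoxelImage,
    lung_mask: np.ndarray,
    rule: LacSegmentationRule | None = None,
) -> MuMap:
    """Quantise a continuous CT mu-map to the five segmented-CT LACs.

    Bin assignment on LAC (mm^-1): [0, t_air) -> air, [t_air, t_fat) -> fat,
    [t_fat, t_water) -> water, [t_water, inf) -> bone; lung-mask voxels are
    overridden to the lung LAC last, regardless of bin.  Idempotent for a
    fixed lung mask.
    """
    rule = rule or LacSegmentationRule()
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != mu_ct.shape:
        raise ValueError("lung mask grid does not match the mu-map grid")
    x = mu_ct.values
    out = np.full(x.shape, rule.v_bone, dtype=float)
    out[x < rule.t_water] = rule.v_water
    out[x < rule.t_fat] = rule.v_fat
    out[x < rule.t_air] = rule.v_air
    out[lung_mask] = rule.v_lung
    return MuMap(out, mu_ct.spacing, mu_ct.origin, provenance="ct_segmented")


def mrac_mumap(
    labels: TissueLabelMap,
    include_hardware: bool = False,
    hardware_mu: VoxelImage | None = None,
    table: MracClassTable | None = None,
) -> MuMap:
    """Four-class MRAC mu-map from the tissue labels.

    Soft tissue, liver, bone and lesions all receive the soft-tissue LAC —
    bone is not distinguished, so bony regions are under-attenuated.  Fat
    and lung receive their class LACs; air and hardware receive zero.  With
    ``include_hardware`` the known hardware mu-map (the scanner hardcodes
    CT-derived maps of the track/bed/coils) is composited in by voxelwise
    maximum.
    """
    table = table or MracClassTable()
    class_lac = {
        "air": table.air,
        "lung": table.lung,
        "fat": table.fat,
        "soft": table.soft,
        "liver": table.soft,
        "bone": table.soft,
        "lesion_soft": table.soft,
        "lesion_bone": table.soft,
        "hardware_track": 0.0,
        "hardware_bed": 0.0,
        "hardware_spine": 0.0,
        "hardware_head": 0.0,
    }
    out = np.zeros(labels.labels.shape, dtype=float)
    for name, code in LABEL_CODES.items():
        out[labels.labels == code] = class_lac[name]
    provenance = "mrac_no_hardware"
    if include_hardware:
        if hardware_mu is None:
            raise ValueError("include_hardware=True requires a hardware mu-map")
        if hardware_mu.shape != out.shape:
            raise ValueError("hardware mu-map grid does not match the label grid")
        out = np.maximum(out, hardware_mu.values)
        provenance = "mrac"
    return MuMap(out, labels.spacing, labels.origin, provenance=provenance)
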