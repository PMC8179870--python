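"""Per-case morphology covariates: ellipsoid volume and zone contrast.

Two covariates drive the variability analysis: the clinical ellipsoid
estimate of prostate volume (``length x width x height x 0.52``, dimensions
in cm) and the squared transition-zone to peripheral-zone signal-intensity
contrast ``((SI_TZ - SI_PZ) / (SI_TZ + SI_PZ))^2``, a scale-invariant index
of how well the two zones can be told apart on T2-weighted images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask_io import IntensityVolume, LabelVolume

ELLIPSOID_FACTOR = 0.52


@dataclass
class CaseFeatures:
    case_id: str
    volume_cm3_per_rater: list[float]
    volume_cm3_mean: float
    volume_cm3_median: float
    si_tz: float
    si_pz: float
    squared_contrast: float
    lesion_flag: bool | None = None
    median_lobe_flag: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.squared_contrast <= 1.0):
            raise ValueError(
                f"squared contrast out of [0,1]: {self.squared_contrast}"
            )
        if any(v <= 0 for v in self.volume_cm3_per_rater):
            raise ValueError("volumes must be positive")


def ellipsoid_volume(length_cm: float, width_cm: float, height_cm: float) -> float:
    """Clinical prostate volume estimate: length x width x height x 0.52 (cm³)."""
    dims = (length_cm, width_cm, height_cm)
    if any(not np.isfinite(d) or d <= 0 for d in dims):
        raise ValueError(f"ellipsoid dimensions must be positive, got {dims}")
    return float(length_cm * width_cm * height_cm * ELLIPSOID_FACTOR)


def squared_contrast(si_tz: float, si_pz: float) -> float:
    """Squared TZ-to-PZ signal contrast ((SI_TZ - SI_PZ)/(SI_TZ + SI_PZ))².

    Symmetric in its arguments and invariant to rescaling both signals.
    """
    if si_tz < 0 or si_pz < 0:
        raise ValueError("signal intensities must be nonnegative")
    total = si_tz + si_pz
    if total <= 0:
        raise ValueError("squared contrast undefined: SI_TZ + SI_PZ is zero")
    return float(((si_tz - si_pz) / total) ** 2)


def roi_signal(
    intensity: IntensityVolume,
    roi_center: tuple[int, int, int],
    roi_radius_mm: float,
) -> float:
    """Mean intensity over a spherical ROI (radius in mm, physical space).

    A radius smaller than the voxel size degenerates to the centre voxel.
    The ROI must lie fully inside the volume.
    """
    if roi_radius_mm < 0:
        raise ValueError("ROI radius must be nonnegative")
    spacing = np.asarray(intensity.spacing)
    center = np.asarray(roi_center, dtype=int)
    half = np.floor(roi_radius_mm / spacing).astype(int)
    lo = center - half
    hi = center + half
    shape = np.asarray(intensity.shape)
    if (lo < 0).any() or (hi >= shape).any():
        raise ValueError(
            f"ROI (center {tuple(center)}, radius {roi_radius_mm} mm) "
            "extends outside the volume"
        )
    grids = np.ogrid[
        lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
    ]
    dist2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing)
    )
    block = intensity.voxels[
        lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
    ]
    inside = dist2 <= roi_radius_mm**2
    if not inside.any():  # radius below voxel size -> centre voxel only
        return float(intensity.voxels[tuple(center)])
    return float(block[inside].mean())


def mask_ellipsoid_dims(mask: LabelVolume) -> tuple[float, float, float]:
    """Axis-aligned bounding-box extents of a mask in cm.

    Convenience for feeding :func:`ellipsoid_volume` from a segmentation
    rather than from caliper-style measurements; the bounding-box diameters
    stand in for the length/width/height a reader would measure.
    """
    if mask.n_foreground == 0:
        raise ValueError("cannot measure an empty mask")
    dims = []
    for axis in range(3):
        other = tuple(k for k in range(3) if k != axis)
        idx = np.flatnonzero(mask.voxels.any(axis=other))
        extent_mm = (idx[-1] - idx[0] + 1) * mask.spacing[axis]
        dims.append(extent_mm / 10.0)
    return tuple(dims)
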