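"""Overlap and surface-distance metrics between binary masks.

Dice score (DSC), Hausdorff distance (HD) and average Hausdorff distance
(AHD) in 3D, plus per-axial-slice (2D) DSC/HD averaged over slices.

Conventions
-----------
* A *boundary* voxel is a foreground voxel with at least one background
  6-neighbour; voxels outside the array count as background.
* ``units="voxels"`` computes Euclidean distances on integer index
  coordinates, ignoring spacing even on anisotropic grids (the convention in
  which clinical HD tables in voxels are reported); ``units="mm"`` scales
  each axis by its spacing.
* HD is the exact (100th percentile) symmetric Hausdorff distance by
  default; a percentile (e.g. 95) is available via ``percentile``.
* AHD follows the convention of the VISCERAL EvaluateSegmentation tool:
  the **max** of the two directed mean boundary distances.  The
  symmetric-mean variant is available via ``variant="mean"``.
* ``distance_support="boundary"`` (default) measures between boundary
  voxels; ``"all"`` measures from every foreground voxel to the other
  mask's nearest foreground voxel.

Distances are computed with exact Euclidean distance transforms
(``scipy.ndimage.distance_transform_edt``), which agree with the brute-force
all-pairs definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .mask_io import LabelVolume, require_same_geometry

Units = Literal["voxels", "mm"]

REGIONS = ("whole", "base", "mid", "apex")
METRICS = ("DSC", "HD", "AHD")


class EmptyMaskError(ValueError):
    """A metric was requested on (an) empty mask(s) where it is undefined."""


@dataclass
class MetricRecord:
    """One measurement: a (case, structure, region, frame, metric) cell."""

    case_id: str
    structure: str
    region: str
    frame: str  # "pairwise(r1,r2)" or "consensus(r)"
    metric: str  # DSC | HD | AHD
    value: float
    units: str  # dimensionless | voxels | mm
    mode: str = "3D"  # 3D | slicewise
    rater_a: str = ""
    rater_b: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.metric == "DSC":
            if not (0.0 <= self.value <= 1.0):
                raise ValueError(f"DSC out of [0,1]: {self.value}")
            if self.units != "dimensionless":
                raise ValueError("DSC is dimensionless")
        elif self.value < 0:
            raise ValueError(f"{self.metric} must be nonnegative: {self.value}")


# ---------------------------------------------------------------------------
# Core computations (operate on boolean arrays; nD so slices reuse them)
# ---------------------------------------------------------------------------


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >=1 background face-neighbour (6-conn in 3D)."""
    mask = np.asarray(mask, dtype=bool)
    struct = ndi.generate_binary_structure(mask.ndim, 1)
    eroded = ndi.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise EmptyMaskError("DSC undefined: both masks empty")
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def _directed_distances(
    src: np.ndarray,
    dst: np.ndarray,
    sampling: tuple[float, ...],
    distance_support: str,
) -> np.ndarray:
    """Distances from each support voxel of ``src`` to nearest of ``dst``."""
    if distance_support == "boundary":
        src_support = boundary_voxels(src)
        dst_support = boundary_voxels(dst)
    elif distance_support == "all":
        src_support, dst_support = src, dst
    else:
        raise ValueError(f"unknown distance_support {distance_support!r}")
    dt = ndi.distance_transform_edt(~dst_support, sampling=sampling)
    return dt[src_support]


def _crop_to_union(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Crop both arrays to the union bounding box plus one voxel.

    Exact for surface distances: every support voxel of either mask lies
    inside the crop.
    """
    union = a | b
    slices = ndi.find_objects(union.astype(np.int8), max_label=1)[0]
    padded = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(slices, union.shape)
    )
    return a[padded], b[padded]


def _distance_pair(
    a: np.ndarray,
    b: np.ndarray,
    sampling: tuple[float, ...],
    distance_support: str,
) -> tuple[np.ndarray, np.ndarray]:
    if not a.any() or not b.any():
        raise EmptyMaskError("surface distance undefined on an empty mask")
    a, b = _crop_to_union(a, b)
    return (
        _directed_distances(a, b, sampling, distance_support),
        _directed_distances(b, a, sampling, distance_support),
    )


def _sampling(
    volume: LabelVolume | None, units: Units, ndim: int
) -> tuple[float, ...]:
    if units == "voxels":
        return (1.0,) * ndim
    if units == "mm":
        if volume is None:
            raise ValueError("mm units require a LabelVolume with spacing")
        return tuple(volume.spacing[:ndim])
    raise ValueError(f"unknown units {units!r}")


# ---------------------------------------------------------------------------
# Public metric operations
# ---------------------------------------------------------------------------


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); errors if both masks are empty."""
    require_same_geometry(a, b)
    return _dice_arrays(a.voxels, b.voxels)


def hausdorff(
    a: LabelVolume,
    b: LabelVolume,
    units: Units = "voxels",
    percentile: float = 100.0,
    distance_support: str = "boundary",
) -> float:
    """Symmetric Hausdorff distance between mask surfaces.

    ``max(h(A,B), h(B,A))`` where ``h`` takes the ``percentile``-th
    percentile (default max) of the minimal distances from one surface
    to the other.
    """
    require_same_geometry(a, b)
    sampling = _sampling(a, units, 3)
    dab, dba = _distance_pair(a.voxels, b.voxels, sampling, distance_support)
    if percentile >= 100.0:
        return float(max(dab.max(), dba.max()))
    return float(
        max(np.percentile(dab, percentile), np.percentile(dba, percentile))
    )


def average_hausdorff(
    a: LabelVolume,
    b: LabelVolume,
    units: Units = "voxels",
    variant: Literal["max", "mean"] = "max",
    distance_support: str = "boundary",
) -> float:
    """Average Hausdorff distance.

    Default ``variant="max"``: the maximum of the two directed mean surface
    distances; ``"mean"`` averages the two directions instead.
    """
    require_same_geometry(a, b)
    sampling = _sampling(a, units, 3)
    dab, dba = _distance_pair(a.voxels, b.voxels, sampling, distance_support)
    if variant == "max":
        return float(max(dab.mean(), dba.mean()))
    if variant == "mean":
        return float((dab.mean() + dba.mean()) / 2.0)
    raise ValueError(f"unknown AHD variant {variant!r}")


def pair_surface_metrics(
    a: LabelVolume,
    b: LabelVolume,
    units: Units = "voxels",
    percentile: float = 100.0,
    ahd_variant: Literal["max", "mean"] = "max",
    distance_support: str = "boundary",
) -> dict[str, float]:
    """HD and AHD from a single pair of directed distance computations."""
    require_same_geometry(a, b)
    sampling = _sampling(a, units, 3)
    dab, dba = _distance_pair(a.voxels, b.voxels, sampling, distance_support)
    if percentile >= 100.0:
        hd = float(max(dab.max(), dba.max()))
    else:
        hd = float(
            max(np.percentile(dab, percentile), np.percentile(dba, percentile))
        )
    if ahd_variant == "max":
        ahd = float(max(dab.mean(), dba.mean()))
    else:
        ahd = float((dab.mean() + dba.mean()) / 2.0)
    return {"HD": hd, "AHD": ahd}


def slicewise_metric(
    a: LabelVolume,
    b: LabelVolume,
    metric: Literal["DSC", "HD"],
    units: Units = "voxels",
    distance_support: str = "boundary",
) -> float:
    """2D metric per axial slice, averaged over informative slices.

    DSC: slices where both masks are empty are excluded; slices where
    exactly one is empty contribute 0.  HD: only slices where both are
    nonempty contribute.  Errors if no slice has both masks nonempty.
    """
    require_same_geometry(a, b)
    sampling = _sampling(a, units, 2)
    values: list[float] = []
    n_both = 0
    for k in range(a.shape[2]):
        sa, sb = a.voxels[:, :, k], b.voxels[:, :, k]
        ea, eb = not sa.any(), not sb.any()
        if ea and eb:
            continue
        if ea or eb:
            if metric == "DSC":
                values.append(0.0)
            continue
        n_both += 1
        if metric == "DSC":
            values.append(_dice_arrays(sa, sb))
        elif metric == "HD":
            dab, dba = _distance_pair(sa, sb, sampling, distance_support)
            values.append(float(max(dab.max(), dba.max())))
        else:
            raise ValueError(f"slicewise metric must be DSC or HD, got {metric}")
    if n_both == 0:
        raise EmptyMaskError("no axial slice has both masks nonempty")
    return float(np.mean(values))
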