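"""Cranio-caudal base / mid-gland / apex decomposition of mask comparisons.

The comparison extent along the slice axis (axis 2, apex -> base) is the
span of slices containing foreground — of the union of the compared pair
(pairwise frame) or of the consensus mask (STAPLE frame).  An extent of
``L`` slices splits into thirds of ``floor(L/3)`` (apex), ``L - 2
floor(L/3)`` (mid-gland, which absorbs the remainder), and ``floor(L/3)``
(base); base is the most cranial third.  All intervals are half-open
0-based slice ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mask_io import LabelVolume, require_same_geometry
from .metrics import (
    EmptyMaskError,
    MetricRecord,
    dice,
    hausdorff,
    slicewise_metric,
)

logger = logging.getLogger("raterlab")

REGION_ORDER = ("apex", "mid", "base")  # caudal -> cranial along axis 2


class DecompositionError(ValueError):
    """The cranio-caudal extent cannot be split into three regions."""


@dataclass
class RegionalDecomposition:
    """Slice intervals of the three regions for one comparison frame."""

    limits_source: str  # "pairwise-union" | "pairwise-intersection" | "consensus"
    extent: tuple[int, int]  # half-open [lo, hi)
    ranges: dict[str, tuple[int, int]]  # region -> half-open slice interval

    def __post_init__(self) -> None:
        lo, hi = self.extent
        spans = [self.ranges[r] for r in REGION_ORDER]
        if spans[0][0] != lo or spans[-1][1] != hi:
            raise DecompositionError("regions do not cover the extent")
        for (_, a_hi), (b_lo, _) in zip(spans, spans[1:]):
            if a_hi != b_lo:
                raise DecompositionError("regions are not contiguous")

    def region_of_slice(self, k: int) -> str | None:
        for region, (lo, hi) in self.ranges.items():
            if lo <= k < hi:
                return region
        return None


def region_submask(mask: LabelVolume, span: tuple[int, int]) -> LabelVolume:
    """Mask restricted to a slice interval (zeros elsewhere, same shape)."""
    lo, hi = span
    vox = np.zeros_like(mask.voxels)
    vox[:, :, lo:hi] = mask.voxels[:, :, lo:hi]
    return LabelVolume(vox, mask.spacing)


def decompose(
    masks: list[LabelVolume],
    limits_source: str = "pairwise-union",
    reference: LabelVolume | None = None,
) -> RegionalDecomposition:
    """Split the cranio-caudal extent of a comparison into thirds.

    ``limits_source="pairwise-union"`` (default) takes the extent of the
    union of the compared masks; ``"pairwise-intersection"`` the extent of
    their intersection; ``"consensus"`` the extent of ``reference`` (the
    STAPLE mask), which must then be provided.
    """
    if limits_source == "consensus":
        if reference is None:
            raise ValueError("consensus limits require a reference mask")
        fg = reference.voxels
    else:
        if not masks:
            raise ValueError("no masks given")
        require_same_geometry(*masks)
        stack = np.stack([m.voxels for m in masks])
        if limits_source == "pairwise-union":
            fg = stack.any(axis=0)
        elif limits_source == "pairwise-intersection":
            fg = stack.all(axis=0)
        else:
            raise ValueError(f"unknown limits_source {limits_source!r}")
    zs = np.flatnonzero(fg.any(axis=(0, 1)))
    if zs.size == 0:
        raise DecompositionError("no foreground slice in the limits source")
    lo, hi = int(zs[0]), int(zs[-1]) + 1
    length = hi - lo
    if length < 3:
        raise DecompositionError(
            f"cranio-caudal extent of {length} slice(s) is too short to "
            "split into thirds"
        )
    third = length // 3
    ranges = {
        "apex": (lo, lo + third),
        "mid": (lo + third, hi - third),
        "base": (hi - third, hi),
    }
    return RegionalDecomposition(
        limits_source=limits_source, extent=(lo, hi), ranges=ranges
    )


def regional_metrics(
    a: LabelVolume,
    b: LabelVolume,
    decomposition: RegionalDecomposition,
    metric: str = "DSC",
    units: str = "voxels",
    mode: str = "3D",
    case_id: str = "",
    structure: str = "",
    frame: str = "",
    rater_a: str = "",
    rater_b: str = "",
    group: str = "",
    **metric_kwargs,
) -> list[MetricRecord]:
    """One MetricRecord per region for a pair of masks.

    Empty-region policy: when both sub-masks are empty the region is
    skipped (with a log line); when exactly one is empty, DSC is recorded
    as 0 and distance metrics are skipped.
    """
    require_same_geometry(a, b)
    records: list[MetricRecord] = []
    for region in REGION_ORDER:
        span = decomposition.ranges[region]
        sub_a = region_submask(a, span)
        sub_b = region_submask(b, span)
        ea, eb = sub_a.n_foreground == 0, sub_b.n_foreground == 0
        if ea and eb:
            logger.info(
                "skipping %s/%s region %s: both sub-masks empty",
                case_id, structure, region,
            )
            continue
        if ea or eb:
            if metric == "DSC":
                value = 0.0
            else:
                logger.info(
                    "skipping %s %s/%s region %s: one sub-mask empty",
                    metric, case_id, structure, region,
                )
                continue
        else:
            if mode == "slicewise":
                try:
                    value = slicewise_metric(
                        sub_a, sub_b, metric, units=units, **metric_kwargs
                    )
                except EmptyMaskError:
                    logger.info(
                        "skipping slicewise %s %s/%s region %s: no common slice",
                        metric, case_id, structure, region,
                    )
                    continue
            elif metric == "DSC":
                value = dice(sub_a, sub_b)
            elif metric == "HD":
                value = hausdorff(sub_a, sub_b, units=units, **metric_kwargs)
            else:
                raise ValueError(f"unsupported regional metric {metric!r}")
        records.append(
            MetricRecord(
                case_id=case_id,
                structure=structure,
                region=region,
                frame=frame,
                metric=metric,
                value=value,
                units="dimensionless" if metric == "DSC" else units,
                mode=mode,
                rater_a=rater_a,
                rater_b=rater_b,
                group=group,
            )
        )
    return records
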