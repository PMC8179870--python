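"""Reading and writing of label/intensity volumes and cohort manifests.

Supported image formats: NIfTI-1 (``.nii``/``.nii.gz``) via nibabel, and
NRRD (``.nrrd``) / MetaImage (``.mha``/``.mhd``) via SimpleITK.

All volumes are held in a canonical axis order ``(x, y, z)`` with the third
axis cranio-caudal: the slice index increases from the apex (caudal) towards
the base (cranial).  NIfTI files are reoriented to the closest canonical
(RAS) orientation on read; NRRD/MetaImage files must carry an axis-aligned
direction matrix (permutation with signs), which is undone so that the third
array axis points cranially.  Oblique direction matrices raise an error —
resampling is out of scope.

Voxel indexing is 0-based throughout and slice ranges are half-open
``[lo, hi)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger("raterlab")

EXPERIENCE_GROUPS = ("expert", "senior", "junior")
STRUCTURES = ("WG", "TZ")
SEQUENCE_TYPES = ("3D_T2W", "2D_T2W")

MANIFEST_COLUMNS = [
    "case_id",
    "rater_id",
    "experience_group",
    "structure",
    "sequence_type",
    "path",
]


class MaskIOError(ValueError):
    """Raised for unreadable files, bad headers, or invalid mask content."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LabelVolume:
    """A 3D binary mask with physical voxel spacing.

    Parameters
    ----------
    voxels
        Boolean array of shape ``(nx, ny, nz)``; axis 2 is cranio-caudal
        (index increases apex -> base).
    spacing
        Physical voxel size ``(sx, sy, sz)`` in millimetres, all positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MaskIOError(f"label volume must be 3D, got shape {vox.shape}")
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.isin(uniq, (0, 1)).all():
                raise MaskIOError(
                    f"label volume values must be binary, found {uniq[:10]}"
                )
            vox = vox.astype(bool)
        self.voxels = vox
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in spacing
        ):
            raise MaskIOError(f"spacing must be 3 positive reals, got {spacing}")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_foreground * self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "LabelVolume | IntensityVolume") -> bool:
        return self.shape == other.voxels.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class IntensityVolume:
    """A 3D scalar image sharing geometry with a case's label volumes."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise MaskIOError(f"intensity volume must be 3D, got {vox.shape}")
        if not np.isfinite(vox).all():
            raise MaskIOError("intensity volume contains non-finite values")
        self.voxels = vox
        spacing = tuple(float(s) for s in self.spacing)
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise MaskIOError(f"spacing must be positive, got {spacing}")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def require_same_geometry(*volumes: LabelVolume | IntensityVolume) -> None:
    ref = volumes[0]
    for v in volumes[1:]:
        if v.voxels.shape != ref.voxels.shape or not np.allclose(
            v.spacing, ref.spacing
        ):
            raise MaskIOError(
                "geometry mismatch: "
                f"{ref.voxels.shape}@{ref.spacing} vs {v.voxels.shape}@{v.spacing}"
            )


# ---------------------------------------------------------------------------
# Image readers / writers
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_SITK_SUFFIXES = (".nrrd", ".mha", ".mhd")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _read_array_any(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read any supported format into canonical (x, y, z) order + spacing."""
    suf = _suffix(path)
    if suf in _NIFTI_SUFFIXES:
        return _read_nifti(path)
    if suf in _SITK_SUFFIXES:
        return _read_sitk(path)
    raise MaskIOError(f"unsupported image format: {path}")


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise MaskIOError(f"cannot read NIfTI {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # RAS: axis 2 -> superior (cranial)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskIOError(f"{path}: expected 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z is None or not np.isfinite(z) or z <= 0 for z in zooms):
        raise MaskIOError(f"{path}: missing or invalid voxel spacing {zooms}")
    return np.asarray(data), tuple(float(z) for z in zooms)


def _read_sitk(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise MaskIOError(f"cannot read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise MaskIOError(f"{path}: expected 3D image")
    spacing = img.GetSpacing()  # (sx, sy, sz) in image axis order
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise MaskIOError(f"{path}: missing or invalid voxel spacing {spacing}")
    # sitk arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    data, spacing = _canonicalize_direction(data, spacing, direction, path)
    return data, spacing


def _canonicalize_direction(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    direction: np.ndarray,
    path: Path,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Undo an axis-aligned direction matrix so axis 2 points cranially.

    ITK physical space is LPS; its third physical axis is superior, so a
    positive entry in row 2 means the image axis already runs caudal->cranial.
    """
    rounded = np.round(direction)
    is_signed_perm = (
        np.allclose(direction, rounded, atol=1e-4)
        and (np.abs(rounded).sum(axis=0) == 1).all()
        and (np.abs(rounded).sum(axis=1) == 1).all()
    )
    if not is_signed_perm:
        raise MaskIOError(f"{path}: oblique direction matrix not supported")
    # image axis j maps to physical axis perm[j] with sign signs[j]
    perm = np.argmax(np.abs(rounded), axis=0)
    signs = rounded[perm, np.arange(3)]
    order = np.argsort(perm)  # image axes sorted by physical axis
    data = np.transpose(data, order)
    spacing_arr = np.asarray(spacing, dtype=float)[order]
    for phys_axis in range(3):
        if signs[order[phys_axis]] < 0:
            data = np.flip(data, axis=phys_axis)
    return np.ascontiguousarray(data), tuple(spacing_arr)


def _binarize(data: np.ndarray, path: Path) -> np.ndarray:
    if not np.allclose(data, np.round(data), atol=1e-6):
        raise MaskIOError(f"{path}: label volume has non-integer values")
    data = np.round(data).astype(np.int64)
    nonzero = np.unique(data[data != 0])
    if nonzero.size > 1:
        warnings.warn(
            f"{path}: {nonzero.size} distinct nonzero labels {nonzero[:5]}; "
            "binarizing nonzero -> 1",
            stacklevel=3,
        )
    return data != 0


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a binary mask; any nonzero voxel value becomes foreground."""
    path = Path(path)
    data, spacing = _read_array_any(path)
    return LabelVolume(_binarize(data, path), spacing)


def read_intensity_volume(path: str | Path) -> IntensityVolume:
    path = Path(path)
    data, spacing = _read_array_any(path)
    return IntensityVolume(data.astype(float), spacing)


def write_volume(
    path: str | Path, volume: LabelVolume | IntensityVolume
) -> Path:
    """Write a volume with identity orientation in the file's native frame."""
    path = Path(path)
    suf = _suffix(path)
    if isinstance(volume, LabelVolume):
        arr = volume.voxels.astype(np.uint8)
    else:
        arr = volume.voxels.astype(np.float32)
    if suf in _NIFTI_SUFFIXES:
        affine = np.diag(list(volume.spacing) + [1.0])
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    elif suf in _SITK_SUFFIXES:
        img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
        img.SetSpacing(tuple(volume.spacing))
        sitk.WriteImage(img, str(path))
    else:
        raise MaskIOError(f"unsupported image format: {path}")
    return path


# ---------------------------------------------------------------------------
# PZ derivation
# ---------------------------------------------------------------------------


def derive_pz(
    wg: LabelVolume, tz: LabelVolume, tolerance_fraction: float = 0.0
) -> LabelVolume:
    """Peripheral zone as the set difference WG \\ TZ.

    The central zone is folded into the PZ and the anterior fibromuscular
    stroma into the TZ, so the whole gland partitions exactly into TZ and PZ.

    Parameters
    ----------
    tolerance_fraction
        Largest tolerated fraction of TZ voxels lying outside the WG
        (default 0: strict nesting).
    """
    require_same_geometry(wg, tz)
    outside = int((tz.voxels & ~wg.voxels).sum())
    n_tz = tz.n_foreground
    if n_tz and outside / n_tz > tolerance_fraction:
        raise MaskIOError(
            f"TZ is not nested in WG: {outside} of {n_tz} TZ voxels "
            "lie outside the whole gland"
        )
    return LabelVolume(wg.voxels & ~tz.voxels, wg.spacing)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------


@dataclass
class RaterCohort:
    """A fully validated case x rater x structure collection of masks.

    ``manifest`` keeps one row per mask file; ``volumes`` caches loaded
    masks keyed ``(case_id, rater_id, structure)``.
    """

    manifest: pd.DataFrame
    volumes: dict[tuple[str, str, str], LabelVolume] = field(default_factory=dict)
    intensities: dict[str, IntensityVolume] = field(default_factory=dict)

    @property
    def case_ids(self) -> list[str]:
        return sorted(self.manifest["case_id"].unique())

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.manifest["rater_id"].unique())

    def group_of(self, rater_id: str) -> str:
        groups = self.manifest.loc[
            self.manifest["rater_id"] == rater_id, "experience_group"
        ].unique()
        return str(groups[0])

    @property
    def groups(self) -> dict[str, str]:
        return {r: self.group_of(r) for r in self.rater_ids}

    def mask(self, case_id: str, rater_id: str, structure: str) -> LabelVolume:
        return self.volumes[(case_id, rater_id, structure)]

    def masks(self, case_id: str, structure: str) -> dict[str, LabelVolume]:
        return {
            r: self.volumes[(case_id, r, structure)] for r in self.rater_ids
        }


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MaskIOError(f"manifest missing columns: {missing}")
    df = df.astype({c: str for c in MANIFEST_COLUMNS})
    bad_group = set(df["experience_group"]) - set(EXPERIENCE_GROUPS)
    if bad_group:
        raise MaskIOError(f"unknown experience groups: {sorted(bad_group)}")
    bad_struct = set(df["structure"]) - set(STRUCTURES)
    if bad_struct:
        raise MaskIOError(f"unknown structures: {sorted(bad_struct)}")
    # experience group constant per rater
    per_rater = df.groupby("rater_id")["experience_group"].nunique()
    if (per_rater > 1).any():
        raise MaskIOError(
            "experience_group differs within rater(s): "
            f"{per_rater[per_rater > 1].index.tolist()}"
        )
    # every (case, rater) must carry both WG and TZ
    for (case, rater), sub in df.groupby(["case_id", "rater_id"]):
        have = set(sub["structure"])
        for structure in STRUCTURES:
            if structure not in have:
                raise MaskIOError(
                    f"manifest incomplete: case {case}, rater {rater} "
                    f"is missing structure {structure}"
                )
    return df


def load_cohort(manifest_path: str | Path) -> RaterCohort:
    """Load and validate a cohort manifest (CSV or JSON) plus all masks.

    Raises on schema violations, missing structures, unreadable paths, or
    shape mismatches between raters of the same case.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(manifest_path.read_text()))
    else:
        df = pd.read_csv(manifest_path)
    df = _validate_manifest(df)

    root = manifest_path.parent
    cohort = RaterCohort(manifest=df.reset_index(drop=True))
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        if not p.exists():
            raise MaskIOError(
                f"manifest path not resolvable for case {row.case_id}, "
                f"rater {row.rater_id}, {row.structure}: {p}"
            )
        cohort.volumes[(row.case_id, row.rater_id, row.structure)] = (
            read_label_volume(p)
        )
    for case_id in cohort.case_ids:
        vols = [
            v for (c, _, _), v in cohort.volumes.items() if c == case_id
        ]
        require_same_geometry(*vols)
    counts = df.groupby("experience_group")["rater_id"].nunique()
    logger.info(
        "loaded cohort: %d cases, %d raters (%s)",
        len(cohort.case_ids),
        len(cohort.rater_ids),
        ", ".join(f"{g}={n}" for g, n in counts.items()),
    )
    return cohort
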