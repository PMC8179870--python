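"""Synthetic multi-rater prostate segmentation cohorts.

Emulates the statistical structure of a reader study in which seven
radiologists (3 experts, 2 seniors, 2 juniors) each contour the whole
gland (WG) and transition zone (TZ) on ~40 axial T2-weighted MRI volumes:

* ground-truth WG: an ellipsoidal blob with a smooth low-frequency radial
  perturbation, volume sampled log-uniformly over the clinical range
  (15–199 cm³);
* ground-truth TZ: a concentric blob nested in the WG at a sampled volume
  fraction;
* intensity image: two-level zonal signal plus Gaussian noise, with the
  TZ level chosen so the noiseless image hits a target squared TZ-to-PZ
  contrast exactly;
* rater masks: the true boundary displaced by a smooth (band-limited)
  random radial field with a given RMS amplitude in mm, plus a constant
  inward/outward bias; the displacement amplitude is inflated on the
  apical and basal thirds of the structure's cranio-caudal extent, and
  optionally coupled to the case's zone contrast (low contrast -> noisier
  contours).  The simulated TZ is clipped to the simulated WG.

Noise is *absolute* (mm), not volume-proportional, so the clinical
volume-vs-agreement relationship emerges rather than being assumed.  The
whole cohort is a pure function of ``(CohortSpec, seed)``; randomness is
expanded with counter-based ``numpy.random.SeedSequence`` spawn keys per
(case, rater, structure), so adding cases never perturbs earlier ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .mask_io import (
    IntensityVolume,
    LabelVolume,
    MANIFEST_COLUMNS,
    write_volume,
)

logger = logging.getLogger("raterlab")

# Surface roughness of the true anatomy (relative radial RMS) and the
# physical correlation length of both anatomy and rater noise fields.
_TRUTH_PERTURB_RMS = 0.04
_TZ_PERTURB_RMS = 0.03
_ASPECT = (1.0, 0.88, 1.12)  # x (LR), y (AP), z (CC) semi-axis ratios
_BACKGROUND_SI = 100.0


@dataclass(frozen=True)
class RaterSpec:
    """One simulated reader: id, experience group, and contouring noise."""

    rater_id: str
    group: str  # expert | senior | junior
    boundary_noise_mm: float
    bias_mm: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.boundary_noise_mm) or self.boundary_noise_mm < 0:
            raise ValueError("boundary_noise_mm must be finite and >= 0")
        if not np.isfinite(self.bias_mm):
            raise ValueError("bias_mm must be finite")


def default_raters() -> tuple[RaterSpec, ...]:
    """Seven readers in three experience groups (3/2/2).

    Group noise levels (expert 1.0, senior 1.2, junior 1.3 mm RMS) give
    near-equal group agreement, mirroring reader studies in which
    expertise barely moves the Dice score.
    """
    return (
        RaterSpec("E1", "expert", 1.0),
        RaterSpec("E2", "expert", 1.0),
        RaterSpec("E3", "expert", 1.0),
        RaterSpec("S1", "senior", 1.2),
        RaterSpec("S2", "senior", 1.2),
        RaterSpec("J1", "junior", 1.3),
        RaterSpec("J2", "junior", 1.3),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults follow the clinical reader study being emulated: 40 cases,
    7 raters in 3 experience groups, prostate volumes 15–199 cm³ sampled
    log-uniformly, sub-millimetre in-plane spacing.
    """

    n_cases: int = 40
    raters: tuple[RaterSpec, ...] = field(default_factory=default_raters)
    volume_range_cm3: tuple[float, float] = (15.0, 199.0)
    tz_fraction_range: tuple[float, float] = (0.25, 0.55)
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 1.0)
    contrast_range: tuple[float, float] = (0.01, 0.25)
    extreme_slice_noise_multiplier: float = 2.0
    contrast_noise_coupling: float = 0.0
    noise_correlation_mm: float = 8.0
    si_pz: float = 400.0
    intensity_noise_sd: float = 20.0
    lesion_prevalence: float = 0.425
    median_lobe_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.volume_range_cm3
        if not (0 < lo <= hi):
            raise ValueError(f"bad volume range {self.volume_range_cm3}")
        flo, fhi = self.tz_fraction_range
        if not (0 < flo <= fhi < 1):
            raise ValueError(f"TZ fraction range must sit in (0,1), got "
                             f"{self.tz_fraction_range}")
        clo, chi = self.contrast_range
        if not (0 <= clo <= chi <= 1):
            raise ValueError(f"bad contrast range {self.contrast_range}")
        if self.extreme_slice_noise_multiplier < 1:
            raise ValueError("extreme_slice_noise_multiplier must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"bad spacing {self.spacing_mm}")
        if self.contrast_noise_coupling < 0:
            raise ValueError("contrast_noise_coupling must be >= 0")

    def rater_index(self, rater_id: str) -> int:
        for j, r in enumerate(self.raters):
            if r.rater_id == rater_id:
                return j
        raise KeyError(rater_id)


@dataclass
class GroundTruthCase:
    """Latent truth for one simulated case (unavailable in clinical data)."""

    case_id: str
    case_index: int
    spec: CohortSpec
    true_wg: LabelVolume
    true_tz: LabelVolume
    intensity: IntensityVolume
    true_volume_cm3: float
    true_tz_fraction: float
    true_contrast: float
    si_tz: float
    si_pz: float
    lesion_flag: bool
    median_lobe_flag: bool
    noise_scale: float  # contrast-coupling multiplier applied to rater noise
    _sd_cache: dict = field(default_factory=dict, repr=False)

    def mask(self, structure: str) -> LabelVolume:
        if structure == "WG":
            return self.true_wg
        if structure == "TZ":
            return self.true_tz
        raise ValueError(f"unknown structure {structure!r}")

    def signed_distance(self, structure: str) -> np.ndarray:
        """Signed distance to the true surface (mm, negative inside).

        ``make_truth`` fills this with the analytic radial distance to the
        continuous superellipsoid surface, which resolves sub-voxel
        displacements; if absent (e.g. a truth built from voxel data), an
        exact Euclidean distance transform of the rasterised mask stands in,
        at the cost of quantising displacements to the voxel grid.
        """
        if structure not in self._sd_cache:
            vox = self.mask(structure).voxels
            spacing = self.mask(structure).spacing
            self._sd_cache[structure] = (
                ndi.distance_transform_edt(~vox, sampling=spacing)
                - ndi.distance_transform_edt(vox, sampling=spacing)
            ).astype(np.float32)
        return self._sd_cache[structure]


# ---------------------------------------------------------------------------
# Random-field helpers
# ---------------------------------------------------------------------------


def _smooth_unit_field(
    shape: tuple[int, ...],
    spacing: tuple[float, ...],
    correlation_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian field normalised to unit RMS."""
    white = rng.standard_normal(shape)
    sigma = [correlation_mm / s for s in spacing]
    smooth = ndi.gaussian_filter(white, sigma=sigma, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def _case_rng(spec: CohortSpec, case_index: int, *stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(case_index, *stream)
    )
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def make_truth(
    spec: CohortSpec,
    case_index: int,
    spacing: tuple[float, float, float] | None = None,
    grid_tag: int = 0,
) -> GroundTruthCase:
    """Build the latent anatomy and intensity image for one case.

    ``spacing``/``grid_tag`` allow re-rasterising the *same* anatomy
    (volume, TZ fraction, contrast are drawn from a grid-independent
    stream) on a different grid, e.g. a thick-slice 2D-acquisition grid.
    """
    spacing = tuple(spacing or spec.spacing_mm)
    rng_params = _case_rng(spec, case_index, 0)
    vlo, vhi = spec.volume_range_cm3
    volume_cm3 = float(np.exp(rng_params.uniform(np.log(vlo), np.log(vhi))))
    tz_fraction = float(rng_params.uniform(*spec.tz_fraction_range))
    contrast = float(rng_params.uniform(*spec.contrast_range))
    lesion = bool(rng_params.random() < spec.lesion_prevalence)
    median_lobe = bool(rng_params.random() < spec.median_lobe_prevalence)

    # semi-axes of the base ellipsoid hitting the target volume
    volume_mm3 = volume_cm3 * 1000.0
    scale = (volume_mm3 * 3.0 / (4.0 * math.pi * math.prod(_ASPECT))) ** (1 / 3)
    semi = np.asarray(_ASPECT) * scale  # mm

    margin_mm = 6.0
    half_extent = semi * (1.0 + 3.5 * _TRUTH_PERTURB_RMS) + margin_mm
    half_n = np.ceil(half_extent / np.asarray(spacing)).astype(int)
    shape = tuple(2 * half_n + 1)
    coords = [
        (np.arange(n) - h) * s for n, h, s in zip(shape, half_n, spacing)
    ]
    grids = np.meshgrid(*coords, indexing="ij", sparse=True)
    rho = np.sqrt(sum((g / a) ** 2 for g, a in zip(grids, semi)))
    radius_mm = np.sqrt(sum(g**2 for g in grids))  # Euclidean from centre

    rng_field = _case_rng(spec, case_index, 1, grid_tag)
    eps_wg = _TRUTH_PERTURB_RMS * _smooth_unit_field(
        shape, spacing, spec.noise_correlation_mm, rng_field
    )
    eps_tz = _TZ_PERTURB_RMS * _smooth_unit_field(
        shape, spacing, spec.noise_correlation_mm, rng_field
    )
    # Radial signed distance (mm) to the continuous perturbed surface:
    # the surface point along the ray through x sits at |x| (1+eps) / rho,
    # so sd = |x| - |x| (1+eps) / rho, sub-voxel accurate for smooth blobs.
    with np.errstate(invalid="ignore", divide="ignore"):
        direction_radius = np.where(rho > 1e-9, radius_mm / rho, semi.mean())
    s_tz = tz_fraction ** (1 / 3)
    sd_wg = (radius_mm - direction_radius * (1.0 + eps_wg)).astype(np.float32)
    sd_tz = (radius_mm - direction_radius * s_tz * (1.0 + eps_tz)).astype(
        np.float32
    )
    wg = sd_wg <= 0
    tz = (sd_tz <= 0) & wg
    if not wg.any() or not tz.any():
        raise ValueError(
            f"case {case_index}: requested TZ fraction {tz_fraction:.3f} "
            "incompatible with the WG shape at this resolution"
        )

    # zonal intensity levels hitting the target squared contrast exactly
    root = math.sqrt(contrast)
    si_pz = spec.si_pz
    si_tz = si_pz * (1.0 - root) / (1.0 + root)  # TZ darker than PZ
    image = np.full(shape, _BACKGROUND_SI, dtype=float)
    image[wg & ~tz] = si_pz
    image[tz] = si_tz
    rng_noise = _case_rng(spec, case_index, 2, grid_tag)
    image = image + spec.intensity_noise_sd * rng_noise.standard_normal(shape)

    coupling = 1.0
    if spec.contrast_noise_coupling > 0:
        clo, chi = spec.contrast_range
        span = max(chi - clo, 1e-12)
        low_contrast = 1.0 - (contrast - clo) / span  # 1 at clo, 0 at chi
        coupling = 1.0 + spec.contrast_noise_coupling * low_contrast

    truth = GroundTruthCase(
        case_id=f"case{case_index:03d}",
        case_index=case_index,
        spec=spec,
        true_wg=LabelVolume(wg, spacing),
        true_tz=LabelVolume(tz, spacing),
        intensity=IntensityVolume(image, spacing),
        true_volume_cm3=volume_cm3,
        true_tz_fraction=tz_fraction,
        true_contrast=contrast,
        si_tz=si_tz,
        si_pz=si_pz,
        lesion_flag=lesion,
        median_lobe_flag=median_lobe,
        noise_scale=coupling,
    )
    truth._sd_cache["WG"] = sd_wg
    truth._sd_cache["TZ"] = sd_tz
    return truth


# ---------------------------------------------------------------------------
# Rater simulation
# ---------------------------------------------------------------------------


def _extreme_slice_weights(
    mask: np.ndarray, multiplier: float
) -> np.ndarray | None:
    """Per-slice noise weights: apical and basal thirds inflated."""
    if multiplier == 1.0:
        return None
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    lo, hi = int(zs[0]), int(zs[-1]) + 1
    length = hi - lo
    third = length // 3
    weights = np.ones(mask.shape[2])
    weights[: lo + third] = multiplier  # apex third and everything caudal
    weights[hi - third :] = multiplier  # base third and everything cranial
    return weights


def _perturb_mask(
    mask: LabelVolume,
    signed_dist: np.ndarray,
    amplitude_mm: float,
    bias_mm: float,
    correlation_mm: float,
    multiplier: float,
    rng: np.random.Generator,
) -> LabelVolume:
    vox = mask.voxels
    spacing = mask.spacing
    if amplitude_mm == 0.0 and bias_mm == 0.0:
        return LabelVolume(vox.copy(), spacing)
    displacement = np.full(vox.shape, bias_mm)
    if amplitude_mm > 0:
        fld = amplitude_mm * _smooth_unit_field(
            vox.shape, spacing, correlation_mm, rng
        )
        weights = _extreme_slice_weights(vox, multiplier)
        if weights is not None:
            fld = fld * weights[None, None, :]
        displacement = displacement + fld
    sim = signed_dist <= displacement
    if not sim.any():
        raise ValueError("simulated mask vanished (bias/noise too negative)")
    labels, n = ndi.label(sim, structure=ndi.generate_binary_structure(3, 1))
    if n > 1:  # keep the largest connected component
        sizes = ndi.sum_labels(sim, labels, index=np.arange(1, n + 1))
        sim = labels == (1 + int(np.argmax(sizes)))
    return LabelVolume(sim, spacing)


def _simulate_structure(
    truth: GroundTruthCase,
    rater: RaterSpec,
    structure: str,
    ss: np.random.SeedSequence,
) -> LabelVolume:
    spec = truth.spec
    return _perturb_mask(
        truth.mask(structure),
        truth.signed_distance(structure),
        rater.boundary_noise_mm * truth.noise_scale,
        rater.bias_mm,
        spec.noise_correlation_mm,
        spec.extreme_slice_noise_multiplier,
        np.random.default_rng(ss),
    )


def simulate_rater(
    truth: GroundTruthCase,
    rater: RaterSpec,
    structure: str,
    seed: int | np.random.SeedSequence,
    wg_mask: LabelVolume | None = None,
) -> LabelVolume:
    """Simulate one rater's contour of WG or TZ for one case.

    The true boundary is displaced by a smooth random radial field with
    RMS amplitude ``rater.boundary_noise_mm`` (times the case's
    contrast-coupling scale) plus the constant ``rater.bias_mm``; the
    amplitude is multiplied by ``extreme_slice_noise_multiplier`` on the
    apical and basal thirds.  The simulated TZ is clipped to the same
    rater's simulated WG so zonal nesting is preserved; pass ``wg_mask``
    to reuse an already-simulated WG, otherwise it is regenerated from the
    same seed (the two calls agree because the WG stream is the first
    child of ``seed``).
    """
    if structure not in ("WG", "TZ"):
        raise ValueError(f"unknown structure {structure!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else (
        np.random.SeedSequence(seed)
    )
    wg_ss, tz_ss = ss.spawn(2)
    if structure == "WG":
        return _simulate_structure(truth, rater, "WG", wg_ss)
    if wg_mask is None:
        wg_mask = _simulate_structure(truth, rater, "WG", wg_ss)
    tz_sim = _simulate_structure(truth, rater, "TZ", tz_ss)
    return LabelVolume(tz_sim.voxels & wg_mask.voxels, tz_sim.spacing)


def rater_seed(
    spec: CohortSpec, case_index: int, rater_index: int, grid_tag: int = 0
) -> np.random.SeedSequence:
    """Counter-based stream for one (case, rater) on one grid."""
    return np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(case_index, 3, rater_index, grid_tag)
    )


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCase:
    truth: GroundTruthCase
    masks: dict[tuple[str, str], LabelVolume]  # (structure, rater_id) -> mask
    sequence_type: str = "3D_T2W"

    @property
    def case_id(self) -> str:
        return self.truth.case_id

    def rater_masks(self, structure: str) -> dict[str, LabelVolume]:
        return {
            rid: m for (s, rid), m in self.masks.items() if s == structure
        }


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    cases: list[SimulatedCase]

    @property
    def groups(self) -> dict[str, str]:
        return {r.rater_id: r.group for r in self.spec.raters}


def simulate_case(
    spec: CohortSpec,
    case_index: int,
    spacing: tuple[float, float, float] | None = None,
    grid_tag: int = 0,
    noise_multiplier: float = 1.0,
    sequence_type: str = "3D_T2W",
) -> SimulatedCase:
    """Truth plus all raters' WG and TZ masks for one case."""
    truth = make_truth(spec, case_index, spacing=spacing, grid_tag=grid_tag)
    masks: dict[tuple[str, str], LabelVolume] = {}
    for j, rater in enumerate(spec.raters):
        eff_rater = (
            rater
            if noise_multiplier == 1.0
            else replace(
                rater, boundary_noise_mm=rater.boundary_noise_mm * noise_multiplier
            )
        )
        wg = simulate_rater(
            truth, eff_rater, "WG", rater_seed(spec, case_index, j, grid_tag)
        )
        tz = simulate_rater(
            truth,
            eff_rater,
            "TZ",
            rater_seed(spec, case_index, j, grid_tag),
            wg_mask=wg,
        )
        masks[("WG", rater.rater_id)] = wg
        masks[("TZ", rater.rater_id)] = tz
    return SimulatedCase(truth=truth, masks=masks, sequence_type=sequence_type)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """All cases in memory; a pure function of (spec, spec.seed)."""
    cases = [simulate_case(spec, i) for i in range(spec.n_cases)]
    logger.info(
        "simulated cohort: %d cases, %d raters; volumes %.1f-%.1f cm3",
        len(cases),
        len(spec.raters),
        min(c.truth.true_volume_cm3 for c in cases),
        max(c.truth.true_volume_cm3 for c in cases),
    )
    return SimulatedCohort(spec=spec, cases=cases)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write all masks, intensity images, and the manifest CSV to disk.

    Returns the manifest DataFrame (also written as ``manifest.csv``);
    ground-truth case parameters go to ``truth.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for i in range(spec.n_cases):
        case = simulate_case(spec, i)
        cid = case.case_id
        write_volume(out_dir / f"{cid}_intensity.nii.gz", case.truth.intensity)
        for (structure, rid), mask in case.masks.items():
            rel = f"{cid}_{rid}_{structure}.nii.gz"
            write_volume(out_dir / rel, mask)
            rows.append(
                {
                    "case_id": cid,
                    "rater_id": rid,
                    "experience_group": spec.raters[
                        spec.rater_index(rid)
                    ].group,
                    "structure": structure,
                    "sequence_type": case.sequence_type,
                    "path": rel,
                }
            )
        t = case.truth
        truth_rows.append(
            {
                "case_id": cid,
                "true_volume_cm3": t.true_volume_cm3,
                "realized_volume_cm3": t.true_wg.volume_cm3,
                "tz_fraction": t.true_tz_fraction,
                "squared_contrast": t.true_contrast,
                "si_tz": t.si_tz,
                "si_pz": t.si_pz,
                "lesion_flag": t.lesion_flag,
                "median_lobe_flag": t.median_lobe_flag,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    logger.info(
        "wrote %d masks for %d cases to %s",
        len(rows), spec.n_cases, out_dir,
    )
    return manifest
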