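"""End-to-end study orchestration: simulate -> consensus -> metrics -> stats.

``run_study`` reproduces the structure of a multi-rater segmentation
variability analysis on a simulated cohort: pairwise and
consensus-referenced DSC/HD/AHD per case and structure, regional
(base/mid/apex) decomposition under both limit conventions, per-case
morphology covariates, and the nonparametric statistical layer with
Holm-corrected families (one family per report block).  Outputs are
written as ``metrics.csv``, ``features.csv``, ``report.json``, ``run.log``
and a plain-text summary table; the run is a pure function of the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    CaseFeatures,
    ellipsoid_volume,
    mask_ellipsoid_dims,
    roi_signal,
    squared_contrast,
)
from .mask_io import LabelVolume, RaterCohort
from .metrics import MetricRecord, dice, pair_surface_metrics
from .regional import decompose, regional_metrics
from .staple import ConsensusResult, staple
from .stats import (
    StatReport,
    compare_binary_factor,
    compare_groups_to_consensus,
    compare_regions,
    compare_structures,
    correlate_with_feature,
    holm_family,
    pairwise_summary,
    records_to_frame,
)
from .synthetic import CohortSpec, RaterSpec, SimulatedCase, simulate_cohort

logger = logging.getLogger("raterlab")

STRUCTURES = ("WG", "TZ")
ALL_METRICS = ("DSC", "HD", "AHD")
REGIONAL_METRICS = ("DSC", "HD")


@dataclass
class RunConfig:
    """Everything a study run depends on; serialized into the output dir."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    units: str = "voxels"
    hd_percentile: float = 100.0
    distance_support: str = "boundary"
    staple_prior: float | str = "sample-mean"
    staple_tol: float = 1e-7
    staple_max_iter: int = 100
    staple_threshold: float = 0.5
    pair_extent: str = "union"  # union | intersection
    regions: bool = True
    roi_radius_mm: float = 3.0
    out_dir: str = "raterlab_run"
    write_masks: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        raters = cohort_raw.pop("raters", None)
        if raters is not None:
            cohort_raw["raters"] = tuple(RaterSpec(**r) for r in raters)
        for key in ("volume_range_cm3", "tz_fraction_range", "spacing_mm",
                    "contrast_range"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        return cls(cohort=CohortSpec(**cohort_raw), **raw)


# ---------------------------------------------------------------------------
# Per-case computations
# ---------------------------------------------------------------------------


def case_pairwise_records(
    case_id: str,
    masks: dict[str, LabelVolume],
    structure: str,
    config: RunConfig,
    with_regions: bool = True,
) -> list[MetricRecord]:
    """All-pairs 3D metrics plus regional DSC/HD for one case/structure."""
    records: list[MetricRecord] = []
    for ra, rb in combinations(sorted(masks), 2):
        a, b = masks[ra], masks[rb]
        frame = f"pairwise({ra},{rb})"
        values = {"DSC": dice(a, b)}
        values.update(
            pair_surface_metrics(
                a, b, units=config.units, percentile=config.hd_percentile,
                distance_support=config.distance_support,
            )
        )
        for metric in ALL_METRICS:
            records.append(
                MetricRecord(
                    case_id=case_id,
                    structure=structure,
                    region="whole",
                    frame=frame,
                    metric=metric,
                    value=values[metric],
                    units="dimensionless" if metric == "DSC" else config.units,
                    rater_a=ra,
                    rater_b=rb,
                )
            )
        if with_regions:
            dec = decompose([a, b], f"pairwise-{config.pair_extent}")
            for metric in REGIONAL_METRICS:
                records.extend(
                    regional_metrics(
                        a, b, dec, metric=metric, units=config.units,
                        case_id=case_id, structure=structure, frame=frame,
                        rater_a=ra, rater_b=rb,
                        **(
                            {"percentile": config.hd_percentile}
                            if metric == "HD" else {}
                        ),
                    )
                )
    return records


def case_consensus_records(
    case_id: str,
    masks: dict[str, LabelVolume],
    structure: str,
    groups: dict[str, str],
    config: RunConfig,
    with_regions: bool = True,
) -> tuple[list[MetricRecord], ConsensusResult]:
    """STAPLE consensus and per-rater consensus-frame metrics for one case."""
    consensus = staple(
        masks,
        prior=config.staple_prior,
        tol=config.staple_tol,
        max_iter=config.staple_max_iter,
        threshold=config.staple_threshold,
    )
    records: list[MetricRecord] = []
    dec = (
        decompose([], "consensus", reference=consensus.consensus_mask)
        if with_regions
        else None
    )
    ref = consensus.consensus_mask
    for rid in sorted(masks):
        mask = masks[rid]
        group = groups.get(rid, "")
        values = {"DSC": dice(mask, ref)}
        values.update(
            pair_surface_metrics(
                mask, ref, units=config.units, percentile=config.hd_percentile,
                distance_support=config.distance_support,
            )
        )
        for metric in ALL_METRICS:
            records.append(
                MetricRecord(
                    case_id=case_id,
                    structure=structure,
                    region="whole",
                    frame=f"consensus({rid})",
                    metric=metric,
                    value=values[metric],
                    units="dimensionless" if metric == "DSC" else config.units,
                    rater_a=rid,
                    group=group,
                )
            )
        if dec is not None:
            for metric in REGIONAL_METRICS:
                records.extend(
                    regional_metrics(
                        mask, consensus.consensus_mask, dec,
                        metric=metric, units=config.units,
                        case_id=case_id, structure=structure,
                        frame=f"consensus({rid})", rater_a=rid, group=group,
                        **(
                            {"percentile": config.hd_percentile}
                            if metric == "HD" else {}
                        ),
                    )
                )
    return records, consensus


def case_features(case: SimulatedCase, config: RunConfig) -> CaseFeatures:
    """Morphology covariates measured from the simulated data.

    Per-rater volumes come from the ellipsoid formula applied to each
    rater's WG bounding-box extents; zonal signal intensities are measured
    in spherical ROIs placed at the deepest interior points of the true TZ
    and PZ.
    """
    from scipy import ndimage as ndi

    truth = case.truth
    volumes = []
    for mask in case.rater_masks("WG").values():
        volumes.append(ellipsoid_volume(*mask_ellipsoid_dims(mask)))

    tz = truth.true_tz.voxels
    pz = truth.true_wg.voxels & ~tz
    spacing = truth.true_wg.spacing
    si = {}
    for name, zone in (("TZ", tz), ("PZ", pz)):
        depth = ndi.distance_transform_edt(zone, sampling=spacing)
        center = np.unravel_index(int(np.argmax(depth)), zone.shape)
        radius = min(config.roi_radius_mm, max(float(depth.max()) - 1e-6, 0.0))
        si[name] = roi_signal(truth.intensity, center, radius)
    return CaseFeatures(
        case_id=case.case_id,
        volume_cm3_per_rater=volumes,
        volume_cm3_mean=float(np.mean(volumes)),
        volume_cm3_median=float(np.median(volumes)),
        si_tz=si["TZ"],
        si_pz=si["PZ"],
        squared_contrast=squared_contrast(si["TZ"], si["PZ"]),
        lesion_flag=truth.lesion_flag,
        median_lobe_flag=truth.median_lobe_flag,
    )


def features_to_frame(features: list[CaseFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": f.case_id,
            "volume_cm3": f.volume_cm3_mean,
            "volume_cm3_median": f.volume_cm3_median,
            "si_tz": f.si_tz,
            "si_pz": f.si_pz,
            "squared_contrast": f.squared_contrast,
            "lesion_flag": f.lesion_flag,
            "median_lobe_flag": f.median_lobe_flag,
        }
        for f in features
    )


# ---------------------------------------------------------------------------
# Cohort-level computation
# ---------------------------------------------------------------------------


def compute_cohort_records(
    cases: list[SimulatedCase] | None,
    config: RunConfig,
    cohort: RaterCohort | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Metric records for a simulated (or file-backed) cohort.

    Returns the tidy records DataFrame and the per-(case, structure)
    consensus results.
    """
    if cases is not None:
        groups = {r.rater_id: r.group for r in config.cohort.raters}
        iterator = [
            (c.case_id, {s: c.rater_masks(s) for s in STRUCTURES})
            for c in cases
        ]
    elif cohort is not None:
        groups = cohort.groups
        iterator = [
            (cid, {s: cohort.masks(cid, s) for s in STRUCTURES})
            for cid in cohort.case_ids
        ]
    else:
        raise ValueError("either cases or cohort must be given")

    records: list[MetricRecord] = []
    consensus_results: dict[tuple[str, str], ConsensusResult] = {}
    for case_id, per_structure in iterator:
        for structure, masks in per_structure.items():
            records.extend(
                case_pairwise_records(
                    case_id, masks, structure, config,
                    with_regions=config.regions,
                )
            )
            cons_records, consensus = case_consensus_records(
                case_id, masks, structure, groups, config,
                with_regions=config.regions,
            )
            records.extend(cons_records)
            consensus_results[(case_id, structure)] = consensus
        logger.info("case %s: %d metric records so far", case_id, len(records))
    return records_to_frame(records), consensus_results


def analysis_report(
    df: pd.DataFrame,
    features: pd.DataFrame,
    n_raters: int,
    groups_present: tuple[str, ...] = ("expert", "senior", "junior"),
) -> dict:
    """The statistical layer: summary blocks with Holm families per block."""
    report: dict = {"summaries": {}, "tests": {}}

    for frame in ("pairwise", "consensus"):
        for structure in STRUCTURES:
            for metric in ALL_METRICS:
                key = f"{structure}:{metric}:{frame}"
                if frame == "pairwise":
                    s = pairwise_summary(df, structure, n_raters, metric=metric)
                    mean, sd = s.grand_mean, s.grand_sd
                else:
                    from .stats import case_means

                    cm = case_means(df, structure, metric=metric, frame=frame)
                    mean = float(cm.mean())
                    sd = float(cm.std(ddof=1)) if len(cm) > 1 else 0.0
                report["summaries"][key] = {"mean": mean, "sd": sd}
        for region in ("base", "mid", "apex"):
            for metric in ("DSC", "HD"):
                try:
                    from .stats import case_means

                    cm = case_means(df, "WG", region, metric, frame)
                except ValueError:
                    continue
                report["summaries"][f"WG:{region}:{metric}:{frame}"] = {
                    "mean": float(cm.mean()),
                    "sd": float(cm.std(ddof=1)) if len(cm) > 1 else 0.0,
                }

    # WG vs TZ per metric and frame (one family per frame)
    for frame in ("pairwise", "consensus"):
        fam = [
            compare_structures(df, "WG", "TZ", metric=m, frame=frame)
            for m in ALL_METRICS
        ]
        report["tests"][f"WG-vs-TZ:{frame}"] = [
            r.as_dict() for r in holm_family(fam)
        ]

    # regional contrasts (family of 3 per metric/frame)
    if (df["region"] != "whole").any():
        for frame in ("pairwise", "consensus"):
            for metric in ("DSC", "HD"):
                reps = compare_regions(df, "WG", metric, frame)
                report["tests"][f"regions:WG:{metric}:{frame}"] = [
                    r.as_dict() for r in reps
                ]

    # morphology factors: one family per frame spanning the Spearman rows.
    # Correlations need >= 4 cases; smaller runs simply omit the block.
    if features["case_id"].nunique() >= 4:
        for frame in ("pairwise", "consensus"):
            fam: list[StatReport] = []
            for feature in ("volume_cm3", "squared_contrast"):
                for metric in ALL_METRICS:
                    fam.append(
                        correlate_with_feature(
                            df, features, feature, metric=metric, frame=frame
                        )
                    )
            report["tests"][f"morphology:{frame}"] = [
                r.as_dict() for r in holm_family(fam)
            ]
            fam_bin = [
                compare_binary_factor(
                    df, features, factor, metric=m, frame=frame
                )
                for factor in ("lesion_flag", "median_lobe_flag")
                for m in ALL_METRICS
                if features[factor].nunique() > 1
            ]
            if fam_bin:
                report["tests"][f"binary-factors:{frame}"] = [
                    r.as_dict() for r in holm_family(fam_bin)
                ]

    # experience groups vs consensus (family of 3 per structure/metric)
    group_col = df.loc[df["frame"] == "consensus", "group"]
    if set(groups_present) <= set(group_col.unique()):
        for structure in STRUCTURES:
            for metric in ALL_METRICS:
                reps = compare_groups_to_consensus(
                    df, groups_present, structure, metric
                )
                report["tests"][f"groups:{structure}:{metric}"] = [
                    r.as_dict() for r in reps
                ]
    return report


def summary_table(report: dict) -> str:
    """Human-readable structure/region summary, one row per block."""
    lines = [
        f"{'block':<34}{'mean':>10}{'sd':>10}",
        "-" * 54,
    ]
    for key, val in report["summaries"].items():
        lines.append(f"{key:<34}{val['mean']:>10.3f}{val['sd']:>10.3f}")
    return "\n".join(lines)


def run_study(config: RunConfig) -> dict:
    """Simulate a cohort and run the full variability analysis.

    Writes metrics.csv, features.csv, report.json, config.yaml, run.log and
    summary.txt into ``config.out_dir``; returns the report dict (with the
    records and features frames attached under ``_frames``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False)
        )
        cohort = simulate_cohort(config.cohort)
        if config.write_masks:
            from .synthetic import generate_cohort

            generate_cohort(config.cohort, out / "volumes")
        df, consensus_results = compute_cohort_records(cohort.cases, config)
        feats = features_to_frame(
            [case_features(c, config) for c in cohort.cases]
        )
        report = analysis_report(df, feats, n_raters=len(config.cohort.raters))
        report["consensus"] = {
            f"{cid}:{structure}": {
                "n_iterations": c.n_iterations,
                "converged": c.converged,
                "per_rater": [
                    {"rater_id": r, "sensitivity": p, "specificity": q}
                    for r, p, q in c.per_rater
                ],
            }
            for (cid, structure), c in consensus_results.items()
        }
        df.to_csv(out / "metrics.csv", index=False)
        feats.to_csv(out / "features.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "summary.txt").write_text(summary_table(report) + "\n")
        logger.info("study complete: %s", out)
        report["_frames"] = {"records": df, "features": feats}
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
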