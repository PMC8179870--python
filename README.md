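# raterlab

Multi-rater analysis of manual prostate zonal segmentation variability on
T2-weighted MRI.

When several radiologists contour the same organ, their masks disagree — and
that disagreement is the yardstick against which automated segmentation
should be judged. `raterlab` implements the complete analysis used in
multi-reader prostate studies: overlap and surface-distance metrics between
raters, an expectation–maximisation consensus (STAPLE), a cranio-caudal
regional breakdown, morphology covariates, and the nonparametric statistics
that relate them. Because clinical reader-study data are rarely shareable,
the package also ships a synthetic cohort generator that reproduces the
statistical structure of such a study — seven raters in three experience
groups contouring whole gland (WG) and transition zone (TZ) on ~40 cases —
so every stage is testable end to end against a known ground truth.

## The metrics and models

For two binary masks `A`, `B` on the same voxel grid:

- **Dice score** `DSC = 2|A∩B| / (|A| + |B|)` — volumetric overlap in [0, 1];
- **Hausdorff distance** `HD = max( h(A,B), h(B,A) )` with
  `h(A,B) = max_{a∈∂A} min_{b∈∂B} ‖a−b‖` — worst-case contour disagreement
  (in voxel or mm units, exact or at a percentile);
- **average Hausdorff distance** `AHD = max( d(A,B), d(B,A) )` with
  `d(A,B) = mean_{a∈∂A} min_{b∈∂B} ‖a−b‖` — outlier-robust contour
  disagreement.

Agreement is summarised two ways: **pairwise** (all 21 pairs of 7 raters,
averaged per case first) and **consensus-referenced**, where each rater is
scored against the **STAPLE** estimate. STAPLE treats the unknown true
segmentation as a latent binary field and each rater `j` as a noisy channel
with sensitivity `p_j` and specificity `q_j`, estimated jointly with the
voxelwise posterior by EM.

Regional analysis splits the cranio-caudal extent of each comparison into
apex / mid-gland / base thirds. Morphology covariates are the clinical
ellipsoid volume `V = length × width × height × 0.52` (cm³) and the squared
TZ-to-PZ signal contrast `((SI_TZ − SI_PZ)/(SI_TZ + SI_PZ))²`. The
statistical layer uses paired Wilcoxon signed-rank, Mann–Whitney U and
Spearman ρ (all two-sided) with Holm–Bonferroni correction per analysis
block.

## Worked example

```python
import raterlab as rl
from raterlab.pipeline import RunConfig, run_study

spec = rl.CohortSpec(n_cases=20, spacing_mm=(1.5, 1.5, 1.5), seed=5)
report = run_study(RunConfig(cohort=spec, out_dir="demo_run"))
for key in ("WG:DSC:pairwise", "WG:DSC:consensus",
            "TZ:DSC:pairwise", "WG:base:DSC:pairwise",
            "WG:mid:DSC:pairwise", "WG:apex:DSC:pairwise"):
    s = report["summaries"][key]
    print(f"{key:24s} {s['mean']:.3f} ± {s['sd']:.3f}")
```

prints

```
WG:DSC:pairwise          0.935 ± 0.011
WG:DSC:consensus         0.958 ± 0.007
TZ:DSC:pairwise          0.908 ± 0.026
WG:base:DSC:pairwise     0.900 ± 0.021
WG:mid:DSC:pairwise      0.969 ± 0.007
WG:apex:DSC:pairwise     0.898 ± 0.018
```

Read: whole-gland agreement is high (pairwise DSC 0.93) and higher still
against the STAPLE consensus (0.96) — the consensus averages away
individual raters' noise; the transition zone, a smaller structure with the
same absolute contouring noise, agrees less; and the mid-gland agrees far
better than the apical and basal extremes, where the generator (like real
readers) is noisiest. `demo_run/` also receives `metrics.csv` (one row per
measurement), `features.csv`, `report.json` with all test statistics and
Holm-adjusted p-values, and `summary.txt`.

The same pipeline runs from the shell:

```bash
raterlab simulate --spec spec.yaml --out cohort/ --seed 5
raterlab metrics --manifest cohort/manifest.csv --out metrics.csv
raterlab consensus --masks r1.nii.gz --masks r2.nii.gz --masks r3.nii.gz \
    --out consensus.nii.gz --report consensus.json
raterlab run --config config.yaml --out demo_run
```

File-backed cohorts use a CSV manifest
(`case_id,rater_id,experience_group,structure,sequence_type,path`) with
masks in NIfTI, NRRD or MetaImage format.

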