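"""Nonparametric reader-study statistics on metric records.

The sampling unit is the *case*: metric records are first averaged over
the 21 rater pairs (pairwise frame) or over the raters of a group
(consensus frame) within each case, and tests are then run across cases.
Pooling pairs directly would pseudo-replicate, since the 21 pairs of one
case share its anatomy.

Tests: paired Wilcoxon signed-rank for related samples (Pratt handling of
zero differences; exact null for n <= 25 without zeros/ties, otherwise the
normal approximation with continuity correction), Mann-Whitney U for
independent samples (exact null for tie-free groups of <= 25, otherwise
asymptotic with continuity correction), and Spearman rank correlation with
a 95% CI from the Fisher z-transform.  All tests are two-sided.  Families
of p-values are corrected with the Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricRecord


@dataclass
class PairwiseSummary:
    """Pairwise agreement summarised case-first, then across cases."""

    structure: str
    region: str
    metric: str
    per_case_mean: pd.Series  # index case_id
    per_case_sd: pd.Series
    grand_mean: float
    grand_sd: float
    n_cases: int
    n_pairs: int


@dataclass
class StatReport:
    """One two-sided test with raw and (optionally) Holm-adjusted p."""

    test: str  # wilcoxon-signed-rank | mann-whitney-u | spearman
    comparison: str
    n: int
    statistic: float
    p_raw: float
    effect: float | None = None  # rho, or median paired difference
    ci95: tuple[float, float] | None = None
    p_holm: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "comparison": self.comparison,
            "n": self.n,
            "statistic": self.statistic,
            "effect": self.effect,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "p_raw": self.p_raw,
            "p_holm": self.p_holm,
            "degenerate": self.degenerate,
        }


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    """Flatten MetricRecords to a tidy DataFrame (one row per measurement)."""
    return pd.DataFrame(
        {
            "case_id": r.case_id,
            "structure": r.structure,
            "region": r.region,
            "frame": "consensus" if r.frame.startswith("consensus") else "pairwise",
            "metric": r.metric,
            "value": r.value,
            "units": r.units,
            "mode": r.mode,
            "rater_a": r.rater_a,
            "rater_b": r.rater_b,
            "group": r.group,
        }
        for r in records
    )


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def holm_adjust(pvalues: list[float] | np.ndarray) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values.

    Sorted ascending, ``p_(k)`` is multiplied by ``m - k`` (0-based),
    running maxima enforce monotonicity, and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError(f"p-values must lie in [0,1], got {p}")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def holm_family(reports: list[StatReport]) -> list[StatReport]:
    """Adjust one family of StatReports together (returns new reports)."""
    adj = holm_adjust([r.p_raw for r in reports])
    return [replace(r, p_holm=a) for r, a in zip(reports, adj)]


# ---------------------------------------------------------------------------
# Test wrappers
# ---------------------------------------------------------------------------


def _wilcoxon_paired(x: np.ndarray, y: np.ndarray, comparison: str) -> StatReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    if np.all(diff == 0):
        return StatReport(
            test="wilcoxon-signed-rank",
            comparison=comparison,
            n=len(x),
            statistic=float("nan"),
            p_raw=1.0,
            effect=0.0,
            degenerate=True,
        )
    nonzero = diff[diff != 0]
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact_ok = (diff != 0).all() and not has_ties and len(x) <= 25
    res = sps.wilcoxon(
        x,
        y,
        zero_method="pratt",
        correction=True,
        alternative="two-sided",
        method="exact" if exact_ok else "approx",
    )
    return StatReport(
        test="wilcoxon-signed-rank",
        comparison=comparison,
        n=len(x),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        effect=float(np.median(diff)),
    )


def _mannwhitney(x: np.ndarray, y: np.ndarray, comparison: str) -> StatReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"empty group in comparison {comparison}")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact_ok = no_ties and max(len(x), len(y)) <= 25
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact_ok else "asymptotic",
    )
    return StatReport(
        test="mann-whitney-u",
        comparison=comparison,
        n=len(x) + len(y),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        effect=float(np.median(x) - np.median(y)),
    )


def _spearman(x: np.ndarray, y: np.ndarray, comparison: str) -> StatReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Spearman correlation needs at least 4 observations")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0:  # perfect monotone association: degenerate CI
        ci = (rho, rho)
    else:
        # Fisher z CI with the Spearman-adjusted standard error
        se = math.sqrt((1 + rho**2 / 2) / (n - 3)) if n > 3 else float("inf")
        z = math.atanh(rho)
        ci = (math.tanh(z - 1.959963985 * se), math.tanh(z + 1.959963985 * se))
    return StatReport(
        test="spearman",
        comparison=comparison,
        n=n,
        statistic=rho,
        p_raw=float(p),
        effect=rho,
        ci95=ci,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _select(
    df: pd.DataFrame,
    structure: str | None = None,
    region: str = "whole",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> pd.DataFrame:
    sel = (
        (df["region"] == region)
        & (df["metric"] == metric)
        & (df["frame"] == frame)
        & (df["mode"] == mode)
    )
    if structure is not None:
        sel &= df["structure"] == structure
    return df[sel]


def case_means(
    df: pd.DataFrame,
    structure: str | None = None,
    region: str = "whole",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> pd.Series:
    """Per-case mean of a metric over all its pairs/raters (case-first rule)."""
    sub = _select(df, structure, region, metric, frame, mode)
    if sub.empty:
        raise ValueError(
            f"no records for structure={structure} region={region} "
            f"metric={metric} frame={frame} mode={mode}"
        )
    return sub.groupby("case_id")["value"].mean().sort_index()


def pairwise_summary(
    df: pd.DataFrame,
    structure: str,
    n_raters: int,
    region: str = "whole",
    metric: str = "DSC",
    mode: str = "3D",
) -> PairwiseSummary:
    """Mean ± SD of a pairwise metric, aggregated case-first.

    Errors if any case is missing one of the C(n_raters, 2) pairs
    (completeness contract).
    """
    sub = _select(df, structure, region, metric, "pairwise", mode)
    if sub.empty:
        raise ValueError(f"no pairwise records for {structure}/{region}/{metric}")
    expected = n_raters * (n_raters - 1) // 2
    counts = sub.groupby("case_id").size()
    gaps = counts[counts != expected]
    if len(gaps):
        raise ValueError(
            f"incomplete pairwise records (expected {expected} pairs/case): "
            + ", ".join(f"{c}={n}" for c, n in gaps.items())
        )
    by_case = sub.groupby("case_id")["value"]
    per_mean = by_case.mean().sort_index()
    per_sd = by_case.std(ddof=1).sort_index()
    return PairwiseSummary(
        structure=structure,
        region=region,
        metric=metric,
        per_case_mean=per_mean,
        per_case_sd=per_sd,
        grand_mean=float(per_mean.mean()),
        grand_sd=float(per_mean.std(ddof=1)) if len(per_mean) > 1 else 0.0,
        n_cases=len(per_mean),
        n_pairs=expected,
    )


# ---------------------------------------------------------------------------
# The study's comparisons
# ---------------------------------------------------------------------------


def compare_structures(
    df: pd.DataFrame,
    structure_a: str = "WG",
    structure_b: str = "TZ",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> StatReport:
    """Paired Wilcoxon of per-case mean metric between two structures."""
    a = case_means(df, structure_a, metric=metric, frame=frame, mode=mode)
    b = case_means(df, structure_b, metric=metric, frame=frame, mode=mode)
    common = a.index.intersection(b.index)
    return _wilcoxon_paired(
        a.loc[common].to_numpy(),
        b.loc[common].to_numpy(),
        comparison=f"{metric}:{structure_a}-vs-{structure_b}:{frame}",
    )


def compare_regions(
    df: pd.DataFrame,
    structure: str = "WG",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> list[StatReport]:
    """The three pairwise regional contrasts (base/mid/apex), Holm-corrected."""
    reg_means = {
        region: case_means(df, structure, region, metric, frame, mode)
        for region in ("base", "mid", "apex")
    }
    reports = []
    for ra, rb in combinations(("base", "mid", "apex"), 2):
        a, b = reg_means[ra], reg_means[rb]
        common = a.index.intersection(b.index)
        reports.append(
            _wilcoxon_paired(
                a.loc[common].to_numpy(),
                b.loc[common].to_numpy(),
                comparison=f"{metric}:{structure}:{ra}-vs-{rb}:{frame}",
            )
        )
    return holm_family(reports)


def correlate_with_feature(
    df: pd.DataFrame,
    features: pd.DataFrame,
    feature_name: str,
    structure: str = "WG",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> StatReport:
    """Spearman rho of per-case mean metric against a per-case covariate.

    ``features`` must carry ``case_id`` plus the named column.
    """
    means = case_means(df, structure, metric=metric, frame=frame, mode=mode)
    feats = features.set_index("case_id")[feature_name]
    common = means.index.intersection(feats.index)
    if len(common) < len(means):
        raise ValueError(
            f"feature {feature_name} missing for cases "
            f"{sorted(set(means.index) - set(common))}"
        )
    return _spearman(
        feats.loc[common].to_numpy(),
        means.loc[common].to_numpy(),
        comparison=f"{metric}:{structure}:{frame}-vs-{feature_name}",
    )


def compare_groups_to_consensus(
    df: pd.DataFrame,
    groups: tuple[str, ...] = ("expert", "senior", "junior"),
    structure: str = "WG",
    metric: str = "DSC",
    mode: str = "3D",
) -> list[StatReport]:
    """Experience-group contrasts of consensus-frame agreement.

    Per case, the consensus-frame metric is averaged over the raters of
    each group; the three group contrasts are paired Wilcoxon tests,
    Holm-corrected as one family.
    """
    sub = _select(df, structure, "whole", metric, "consensus", mode)
    if sub.empty:
        raise ValueError(f"no consensus records for {structure}/{metric}")
    per = sub.groupby(["case_id", "group"])["value"].mean().unstack("group")
    missing = [g for g in groups if g not in per.columns]
    if missing:
        raise ValueError(f"no consensus records for group(s) {missing}")
    reports = []
    for ga, gb in combinations(groups, 2):
        both = per[[ga, gb]].dropna()
        reports.append(
            _wilcoxon_paired(
                both[ga].to_numpy(),
                both[gb].to_numpy(),
                comparison=f"{metric}:{structure}:{ga}-vs-{gb}:consensus",
            )
        )
    return holm_family(reports)


def compare_binary_factor(
    df: pd.DataFrame,
    features: pd.DataFrame,
    factor: str,
    structure: str = "WG",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> StatReport:
    """Mann-Whitney U of per-case mean metric split by a boolean factor."""
    means = case_means(df, structure, metric=metric, frame=frame, mode=mode)
    feats = features.set_index("case_id")[factor].astype(bool)
    feats = feats.loc[feats.index.intersection(means.index)]
    pos = means.loc[feats[feats].index].to_numpy()
    neg = means.loc[feats[~feats].index].to_numpy()
    return _mannwhitney(
        pos, neg, comparison=f"{metric}:{structure}:{frame}-by-{factor}"
    )


def compare_2d_3d(
    df: pd.DataFrame,
    structure: str | None = None,
    region: str = "whole",
    metric: str = "DSC",
    frame: str = "pairwise",
    mode: str = "3D",
) -> StatReport:
    """Paired Wilcoxon of per-case means between 2D and 3D acquisitions.

    ``df`` must carry a ``sequence`` column ('3D_T2W' / '2D_T2W'); ``mode``
    selects 3D metrics for whole structures and slicewise metrics for
    regional comparisons.
    """
    if "sequence" not in df.columns:
        raise ValueError("records need a 'sequence' column for the 2D/3D split")
    means = {}
    for seq in ("3D_T2W", "2D_T2W"):
        means[seq] = case_means(
            df[df["sequence"] == seq], structure, region, metric, frame, mode
        )
    common = means["3D_T2W"].index.intersection(means["2D_T2W"].index)
    return _wilcoxon_paired(
        means["2D_T2W"].loc[common].to_numpy(),
        means["3D_T2W"].loc[common].to_numpy(),
        comparison=f"{metric}:{structure}:{region}:2D-vs-3D",
    )
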