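"""Holm correction, aggregation rules, and the study's comparisons."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

import raterlab as rl


def records_frame(rows):
    """Tidy records frame with defaults matching records_to_frame output."""
    df = pd.DataFrame(rows)
    defaults = {
        "structure": "WG", "region": "whole", "frame": "pairwise",
        "metric": "DSC", "units": "dimensionless", "mode": "3D",
        "rater_a": "", "rater_b": "", "group": "",
    }
    for col, val in defaults.items():
        if col not in df:
            df[col] = val
    return df


def pairwise_rows(case_values, raters=("a", "b", "c"), **kw):
    """One DSC row per rater pair per case; case_values: case_id -> values."""
    rows = []
    for case_id, values in case_values.items():
        pairs = list(combinations(raters, 2))
        assert len(values) == len(pairs)
        for (ra, rb), v in zip(pairs, values):
            rows.append(
                dict(case_id=case_id, rater_a=ra, rater_b=rb, value=v, **kw)
            )
    return rows


class TestHolm:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.03], [0.03]),
            ([0.5, 0.9], [1.0, 1.0]),
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
        ],
    )
    def test_hand_computed_step_down(self, raw, expected):
        assert rl.holm_adjust(raw) == pytest.approx(expected)

    def test_all_permutations_of_three_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        for perm in permutations([0.011, 0.032, 0.047]):
            mine = rl.holm_adjust(list(perm))
            _, ref, _, _ = multipletests(list(perm), method="holm")
            assert mine == pytest.approx(list(ref), abs=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            raw = rng.random(rng.integers(1, 8))
            adj = np.asarray(rl.holm_adjust(raw))
            assert (adj >= raw - 1e-15).all() and (adj <= 1.0).all()
            order = np.argsort(raw)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            rl.holm_adjust([0.2, 1.4])


class TestPairwiseSummary:
    def test_constant_records(self):
        df = records_frame(pairwise_rows({"c1": [0.9] * 3, "c2": [0.9] * 3}))
        s = rl.pairwise_summary(df, "WG", n_raters=3)
        assert s.grand_mean == pytest.approx(0.9)
        assert s.grand_sd == 0.0
        assert s.n_pairs == 3

    def test_grand_mean_of_case_means(self):
        df = records_frame(
            pairwise_rows({"c1": [0.9] * 3, "c2": [0.8] * 3})
        )
        s = rl.pairwise_summary(df, "WG", n_raters=3)
        assert s.grand_mean == pytest.approx(0.85)

    def test_missing_pair_is_error(self):
        rows = pairwise_rows({"c1": [0.9] * 3})
        rows += pairwise_rows({"c2": [0.8] * 3})[:-1]  # drop one pair
        with pytest.raises(ValueError, match="c2"):
            rl.pairwise_summary(records_frame(rows), "WG", n_raters=3)

    def test_case_first_aggregation_sets_the_sd(self):
        """SD is across case means, not across pooled pairs."""
        df = records_frame(
            pairwise_rows({"c1": [1.0, 0.0, 0.5], "c2": [0.5, 0.5, 0.5]})
        )
        s = rl.pairwise_summary(df, "WG", n_raters=3)
        case_means = np.array([0.5, 0.5])
        pooled = np.array([1.0, 0.0, 0.5, 0.5, 0.5, 0.5])
        assert s.grand_sd == pytest.approx(case_means.std(ddof=1))
        assert s.grand_sd != pytest.approx(pooled.std(ddof=1))


class TestCompareStructures:
    def _two_structure_frame(self, wg_vals, tz_vals):
        rows = pairwise_rows(
            {f"c{i}": [v] * 3 for i, v in enumerate(wg_vals)}, structure="WG"
        )
        rows += pairwise_rows(
            {f"c{i}": [v] * 3 for i, v in enumerate(tz_vals)}, structure="TZ"
        )
        return records_frame(rows)

    def test_identical_values_degenerate(self):
        vals = [0.9, 0.91, 0.92, 0.93]
        df = self._two_structure_frame(vals, vals)
        rep = rl.compare_structures(df)
        assert rep.degenerate and rep.p_raw == 1.0

    def test_known_shift_detected(self):
        rng = np.random.default_rng(5)
        wg = 0.92 + rng.normal(0, 0.01, 20)
        tz = wg - 0.04 + rng.normal(0, 0.005, 20)
        df = self._two_structure_frame(wg, tz)
        rep = rl.compare_structures(df)
        assert rep.p_raw < 0.05
        assert rep.effect > 0  # WG more similar than TZ

    def test_swapped_arguments_flip_effect_keep_p(self):
        rng = np.random.default_rng(6)
        wg = 0.92 + rng.normal(0, 0.02, 15)
        tz = wg - 0.03 + rng.normal(0, 0.01, 15)
        df = self._two_structure_frame(wg, tz)
        fwd = rl.compare_structures(df, "WG", "TZ")
        rev = rl.compare_structures(df, "TZ", "WG")
        assert fwd.p_raw == rev.p_raw
        assert fwd.effect == pytest.approx(-rev.effect)


class TestCorrelateWithFeature:
    def _frame_and_features(self, metric_vals, feature_vals):
        df = records_frame(
            pairwise_rows(
                {f"c{i:02d}": [v] * 3 for i, v in enumerate(metric_vals)}
            )
        )
        feats = pd.DataFrame(
            {
                "case_id": [f"c{i:02d}" for i in range(len(feature_vals))],
                "volume_cm3": feature_vals,
            }
        )
        return df, feats

    def test_identical_feature_gives_rho_one(self):
        vals = [0.8, 0.85, 0.9, 0.95, 0.99]
        df, feats = self._frame_and_features(vals, vals)
        rep = rl.correlate_with_feature(df, feats, "volume_cm3")
        assert rep.statistic == pytest.approx(1.0)

    def test_antitone_feature_gives_rho_minus_one(self):
        vals = [0.8, 0.85, 0.9, 0.95, 0.99]
        df, feats = self._frame_and_features(vals, vals[::-1])
        rep = rl.correlate_with_feature(df, feats, "volume_cm3")
        assert rep.statistic == pytest.approx(-1.0)

    def test_permuted_feature_has_small_rho_on_average(self):
        rng = np.random.default_rng(1)
        vals = list(0.9 + rng.normal(0, 0.02, 24))
        rhos = []
        for _ in range(20):
            df, feats = self._frame_and_features(
                vals, list(rng.permutation(vals))
            )
            rhos.append(
                rl.correlate_with_feature(df, feats, "volume_cm3").statistic
            )
        assert abs(np.mean(rhos)) < 0.15

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(2)
        vals = list(0.9 + rng.normal(0, 0.02, 20))
        feat = [v + rng.normal(0, 0.01) for v in vals]
        rep = rl.correlate_with_feature(
            self._frame_and_features(vals, feat)[0],
            self._frame_and_features(vals, feat)[1],
            "volume_cm3",
        )
        lo, hi = rep.ci95
        assert lo <= rep.statistic <= hi


class TestGroupsAndFactors:
    def _consensus_frame(self, group_values, n_cases=20, seed=0):
        """group_values: group -> (mean, sd) of per-rater consensus DSC."""
        rng = np.random.default_rng(seed)
        rows = []
        raters = {"expert": ["E1", "E2", "E3"], "senior": ["S1", "S2"],
                  "junior": ["J1", "J2"]}
        for i in range(n_cases):
            for group, (mu, sd) in group_values.items():
                for rid in raters[group]:
                    rows.append(
                        dict(
                            case_id=f"c{i:02d}", frame="consensus",
                            rater_a=rid, group=group,
                            value=float(np.clip(rng.normal(mu, sd), 0, 1)),
                        )
                    )
        return records_frame(rows)

    def test_identical_groups_degenerate(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(6):
            v = float(rng.uniform(0.9, 0.95))
            for rid, group in [("E1", "expert"), ("S1", "senior"),
                               ("J1", "junior")]:
                rows.append(
                    dict(case_id=f"c{i}", frame="consensus", rater_a=rid,
                         group=group, value=v)
                )
        reports = rl.compare_groups_to_consensus(records_frame(rows))
        assert all(r.degenerate and r.p_holm == 1.0 for r in reports)

    def test_noisier_group_detected(self):
        df = self._consensus_frame(
            {"expert": (0.95, 0.005), "senior": (0.94, 0.005),
             "junior": (0.90, 0.005)},
            seed=4,
        )
        reports = {r.comparison: r for r in rl.compare_groups_to_consensus(df)}
        ej = reports["DSC:WG:expert-vs-junior:consensus"]
        assert ej.p_holm < 0.05 and ej.effect > 0

    def test_binary_factor_null_and_effect(self):
        rng = np.random.default_rng(8)
        vals = 0.9 + rng.normal(0, 0.01, 24)
        df = records_frame(
            pairwise_rows({f"c{i:02d}": [v] * 3 for i, v in enumerate(vals)})
        )
        feats = pd.DataFrame(
            {
                "case_id": [f"c{i:02d}" for i in range(24)],
                "lesion_flag": [i % 2 == 0 for i in range(24)],
            }
        )
        rep = rl.compare_binary_factor(df, feats, "lesion_flag")
        assert rep.test == "mann-whitney-u"
        assert rep.p_raw > 0.05  # no real effect
        # inject an effect
        vals2 = vals + np.where(np.arange(24) % 2 == 0, 0.05, 0.0)
        df2 = records_frame(
            pairwise_rows({f"c{i:02d}": [v] * 3 for i, v in enumerate(vals2)})
        )
        rep2 = rl.compare_binary_factor(df2, feats, "lesion_flag")
        assert rep2.p_raw < 0.01


class TestCompare2D3D:
    def test_paired_sequences_compared(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(12):
            base = 0.9 + rng.normal(0, 0.01)
            for seq, shift in (("3D_T2W", 0.01), ("2D_T2W", 0.0)):
                for pair_vals in [base + shift + rng.normal(0, 0.002, 3)]:
                    rows += pairwise_rows(
                        {f"c{i:02d}": list(pair_vals)}
                    )
                    for r in rows[-3:]:
                        r["sequence"] = seq
        df = records_frame(rows)
        rep = rl.compare_2d_3d(df, structure="WG")
        assert rep.n == 12
        assert rep.effect < 0  # 2D minus 3D is negative
        assert rep.p_raw < 0.05
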