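"""TOST equivalence, repeated-measures Bland-Altman, ICCs and confusion metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epochsleep import (
    bland_altman_rm,
    epoch_confusion,
    equivalence_table,
    icc_shrout_fleiss,
    tost_paired_t,
    tost_wilcoxon,
)

from oracles import icc_two_way, wilcoxon_exact_p


class TestTostPairedT:
    def test_matches_closed_form_t(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        margin = 10.0
        res = tost_paired_t(d, margin)
        # independent closed form: one-sided t with df = 4
        se = d.std(ddof=1) / np.sqrt(len(d))
        p_lower = stats.t.sf((d.mean() + margin) / se, len(d) - 1)
        p_upper = stats.t.cdf((d.mean() - margin) / se, len(d) - 1)
        assert res.p_lower == pytest.approx(p_lower, abs=1e-12)
        assert res.p_upper == pytest.approx(p_upper, abs=1e-12)
        assert res.p_tost == pytest.approx(max(p_lower, p_upper), abs=1e-12)
        assert res.p_tost < 0.001 and res.equivalent

    def test_degenerate_zero_variance(self):
        res = tost_paired_t([0.0] * 6, margin=30)
        assert res.p_tost == 0.0 and res.equivalent
        res = tost_paired_t([45.0] * 6, margin=30)
        assert res.p_tost == 1.0 and not res.equivalent

    def test_mean_on_the_margin_gives_half(self):
        d = np.array([28.0, 29.0, 30.0, 31.0, 32.0])  # mean exactly 30
        res = tost_paired_t(d, margin=30.0)
        assert res.p_upper == pytest.approx(0.5)
        assert not res.equivalent

    def test_margin_widening_drives_p_to_zero(self):
        d = np.array([3.0, -1.0, 4.0, 2.0, 0.0, 5.0])
        p_values = [tost_paired_t(d, m).p_tost for m in (5, 20, 100, 1000)]
        assert all(a >= b for a, b in zip(p_values, p_values[1:]))
        assert p_values[-1] < 1e-12

    def test_tiny_margin_never_equivalent(self):
        d = np.array([3.0, -1.0, 4.0, 2.0, 0.5, 5.0])
        assert not tost_paired_t(d, 1e-6).equivalent


class TestTostWilcoxon:
    def test_symmetric_small_diffs_equivalent(self):
        d = np.array([-2.0, -1.0, 0.5, 1.0, 2.0, -0.5, 1.5, -1.5])
        assert tost_wilcoxon(d, margin=30).equivalent

    def test_shifted_diffs_not_equivalent(self):
        res = tost_wilcoxon([12.0, 11.0, 13.0, 12.5, 12.0], margin=10)
        assert not res.equivalent
        assert res.p_upper > 0.9  # all upper-test values positive

    def test_exact_enumeration_matches_oracle(self):
        """Implementation equals brute-force 2^n sign enumeration for n <= 10."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 11))
            d = np.round(rng.normal(0, 5, n), 1)
            margin = float(rng.uniform(1, 10))
            res = tost_wilcoxon(d, margin)
            assert res.p_lower == pytest.approx(
                wilcoxon_exact_p(d + margin, "greater"), abs=1e-12)
            assert res.p_upper == pytest.approx(
                wilcoxon_exact_p(d - margin, "less"), abs=1e-12)

    def test_degenerate_constant_diffs(self):
        assert tost_wilcoxon([5.0] * 6, margin=30).equivalent
        assert not tost_wilcoxon([45.0] * 6, margin=30).equivalent


class TestBlandAltmanRM:
    def test_two_subject_hand_worked_variance_components(self):
        # two subjects, 3 days each, constant d = 1 and d = 3
        pairs = pd.DataFrame({
            "subject_id": ["p1"] * 3 + ["p2"] * 3,
            "a": [2.0] * 3 + [4.0] * 3,
            "b": [1.0] * 6,
        })
        res = bland_altman_rm(pairs)
        assert res.bias == pytest.approx(2.0)
        assert res.var_within == pytest.approx(0.0)
        assert res.var_between == pytest.approx(2.0)  # (MSB - MSW)/3 = 6/3
        assert res.loa_high == pytest.approx(2 + 1.96 * np.sqrt(2.0))
        assert res.loa_low == pytest.approx(2 - 1.96 * np.sqrt(2.0))

    def test_all_zero_differences(self):
        pairs = pd.DataFrame({
            "subject_id": ["p1", "p1", "p2", "p2"],
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [1.0, 2.0, 3.0, 4.0],
        })
        res = bland_altman_rm(pairs)
        assert (res.bias, res.loa_low, res.loa_high, res.slope) == (0.0, 0.0, 0.0, 0.0)

    def test_single_subject_rejected(self):
        pairs = pd.DataFrame({"subject_id": ["p1"] * 4, "a": [1.0, 2, 3, 4], "b": [0.0] * 4})
        with pytest.raises(ValueError, match="2 subjects"):
            bland_altman_rm(pairs)

    def test_proportional_bias_slope_recovery(self):
        """A true slope of 0.14 diff-per-unit-mean is inside the cluster-robust
        95% CI in at least 93% of replicates."""
        rng = np.random.default_rng(21)
        true_slope = 0.14
        hits = 0
        n_rep = 250
        for _ in range(n_rep):
            subj = np.repeat([f"p{i}" for i in range(30)], 7)
            mean = rng.normal(19, 1.1, 210) + np.repeat(rng.normal(0, 0.6, 30), 7)
            d = true_slope * mean + np.repeat(rng.normal(0, 0.05, 30), 7) + rng.normal(0, 0.1, 210)
            a = mean + d / 2
            b = mean - d / 2
            res = bland_altman_rm(pd.DataFrame({"subject_id": subj, "a": a, "b": b}))
            if res.slope_ci[0] <= true_slope <= res.slope_ci[1]:
                hits += 1
        assert hits / n_rep >= 0.93

    def test_loa_cover_about_95pct_of_exchangeable_differences(self):
        """Pooled over replicates, ~95% of differences fall inside the limits."""
        rng = np.random.default_rng(8)
        inside = total = 0
        for _ in range(500):
            d = np.repeat(rng.normal(0, 5, 30), 7) + rng.normal(0, 10, 210)
            subj = np.repeat(np.arange(30), 7)
            pairs = pd.DataFrame({"subject_id": subj, "a": d, "b": np.zeros(210)})
            res = bland_altman_rm(pairs)
            inside += int(np.sum((d >= res.loa_low) & (d <= res.loa_high)))
            total += d.size
        assert 0.94 <= inside / total <= 0.96


class TestIcc:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        res = icc_shrout_fleiss(x)
        assert res.icc_2_1 == pytest.approx(1.0)
        assert res.icc_3_1 == pytest.approx(1.0)

    def test_constant_offset_hurts_absolute_agreement_only(self):
        base = np.array([3.0, 7.0, 1.0, 9.0, 5.0, 6.0])
        x = np.column_stack([base, base + 5])
        res = icc_shrout_fleiss(x)
        assert res.icc_3_1 == pytest.approx(1.0)
        assert res.icc_2_1 < 1.0

    def test_six_subject_table_matches_anova_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            x = rng.normal(50, 10, size=(6, 2))
            x[:, 1] += rng.normal(0, 3, 6)
            res = icc_shrout_fleiss(x)
            icc21, icc31 = icc_two_way(x)
            assert res.icc_2_1 == pytest.approx(icc21, abs=1e-10)
            assert res.icc_3_1 == pytest.approx(icc31, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(29)
        x = rng.normal(100, 15, size=(12, 2))
        res = icc_shrout_fleiss(x)
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["A", "B"], 12),
            "ratings": x.ravel(),
        })
        icc = pingouin.intraclass_corr(frame, targets="targets", raters="raters",
                                       ratings="ratings").set_index("Type")
        assert res.icc_2_1 == pytest.approx(icc.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res.icc_3_1 == pytest.approx(icc.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_equal_rater_means_make_both_iccs_agree(self):
        """With identical rater means the two ICCs coincide up to the O(1/n)
        rater-mean-square term in the ICC(2,1) denominator."""
        rng = np.random.default_rng(31)
        n = 2000
        base = rng.normal(0, 4, n)
        noise = rng.normal(0, 1, n)
        noise -= noise.mean()  # force exactly equal column means
        x = np.column_stack([base + noise, base - noise])
        res = icc_shrout_fleiss(x)
        assert res.ms_raters == pytest.approx(0.0, abs=1e-9)
        assert res.icc_2_1 == pytest.approx(res.icc_3_1, abs=2e-3)

    def test_positive_rater_variance_orders_the_iccs(self):
        rng = np.random.default_rng(37)
        base = rng.normal(0, 4, 12)
        x = np.column_stack([base, base + 2 + rng.normal(0, 1, 12)])
        res = icc_shrout_fleiss(x)
        if res.ms_raters >= res.ms_error:  # rater variance component >= 0
            assert res.icc_3_1 >= res.icc_2_1

    def test_zero_subject_variance_degenerate(self):
        x = np.ones((5, 2))
        res = icc_shrout_fleiss(x)
        assert res.degenerate and res.icc_2_1 == 0.0


def _paired_frame(ref, test, subject="S1", start="2024-01-01 22:00"):
    n = len(ref)
    return pd.DataFrame({
        "subject_id": [subject] * n,
        "timestamp": pd.date_range(start, periods=n, freq="min"),
        "lying_a": 1, "sleeping_a": ref, "lying_b": 1, "sleeping_b": test,
    })


class TestEpochConfusion:
    def test_perfect_agreement(self):
        ref = [1, 0] * 20
        cm = epoch_confusion(_paired_frame(ref, ref))
        assert (cm.sensitivity, cm.specificity, cm.accuracy) == (1.0, 1.0, 1.0)

    def test_hand_counted_rates_and_likelihood_ratios(self):
        # reference: 10 sleep (9 matched), 10 wake (8 matched)
        ref = [1] * 10 + [0] * 10
        test = [1] * 9 + [0] + [0] * 8 + [1] * 2
        cm = epoch_confusion(_paired_frame(ref, test))
        assert cm.sensitivity == pytest.approx(0.9)
        assert cm.specificity == pytest.approx(0.8)
        assert cm.lr_pos == pytest.approx(4.5)
        assert cm.lr_neg == pytest.approx(0.125)
        assert cm.accuracy == pytest.approx(17 / 20)
        # identity: LR+ * (1 - spec) == sens exactly
        assert cm.lr_pos * (1 - cm.specificity) == pytest.approx(cm.sensitivity, abs=1e-15)

    def test_daytime_minutes_are_excluded(self):
        frame = _paired_frame([1] * 60, [0] * 60, start="2024-01-01 13:00")
        night = _paired_frame([1] * 60, [1] * 60, start="2024-01-01 23:00")
        cm = epoch_confusion(pd.concat([frame, night], ignore_index=True))
        assert cm.sensitivity == 1.0  # the 13:00 block never counted
        assert cm.n_epochs == 60

    def test_pooled_vs_per_subject_means_differ_with_unequal_minutes(self):
        a = _paired_frame([1] * 90 + [0] * 10, [1] * 80 + [0] * 20, subject="S1")
        b = _paired_frame([1] * 10 + [0] * 10, [1] * 10 + [0] * 10, subject="S2")
        cm = epoch_confusion(pd.concat([a, b], ignore_index=True))
        # brute-force counting oracle
        pooled_sens = (80 + 10) / (90 + 10)
        per_subject = np.mean([80 / 90, 10 / 10])
        assert cm.sensitivity == pytest.approx(pooled_sens)
        assert cm.mean_sensitivity == pytest.approx(per_subject)
        assert cm.sensitivity != cm.mean_sensitivity

    def test_subject_without_reference_wake_is_excluded_with_warning(self):
        a = _paired_frame([1] * 30, [1] * 30, subject="S1")  # no wake minutes
        b = _paired_frame([1, 0] * 15, [1, 0] * 15, subject="S2")
        with pytest.warns(UserWarning, match="no reference wake"):
            cm = epoch_confusion(pd.concat([a, b], ignore_index=True))
        assert cm.mean_specificity == pytest.approx(1.0)


class TestEquivalenceTable:
    def test_identical_weekly_tables_all_equivalent(self, small_study):
        from epochsleep import score_streams, weekly_table

        weekly = weekly_table(score_streams(small_study["device_a"]))
        report = equivalence_table(weekly, weekly.copy())
        assert report["equivalent"].all()
        assert (report["p_tost"] == 0.0).all()  # degenerate zero differences

    def test_margin_override_respected(self, small_study):
        from epochsleep import score_streams, weekly_table

        wa = weekly_table(score_streams(small_study["device_a"]))
        wb = wa.copy()
        wb["tst_mean"] = wb["tst_mean"] + 20.0
        strict = equivalence_table(wa, wb, margins={"tst": 5.0})
        loose = equivalence_table(wa, wb, margins={"tst": 60.0})
        row = lambda rep: rep.set_index("variable").loc["tst"]
        assert not row(strict)["equivalent"]
        assert row(loose)["equivalent"]
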