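import warnings

import numpy as np
import pandas as pd
import pytest

from tqtkit import analysis
from tqtkit.analysis import (
    CategoricalRules,
    UnestimableError,
    assay_sensitivity_test,
    categorical_analysis,
    compute_cfb,
    fit_contrast,
    fit_primary_ancova,
    fit_rmc_by_timepoint,
    notable_changes,
    one_step_qt_analysis,
    sensitivity_global_baseline,
    sensitivity_single_placebo,
    subgroup_analysis,
)
from tqtkit.synthetic import simulate_endpoint_level


def tp_frame(times, qtc, subject="S001", period=1, treatment="placebo"):
    return pd.DataFrame(
        {
            "subject_id": subject,
            "period": period,
            "treatment": treatment,
            "time_h": times,
            "qtc_ms": qtc,
        }
    )


def baseline_frame(subject="S001", period=1, value=400.0):
    return pd.DataFrame(
        {"subject_id": [subject], "period": [period], "baseline_qtc_ms": [value]}
    )


class TestComputeCfb:
    def test_flat_profile_zero_cfb(self):
        tp = tp_frame([1.0, 2.0, 3.0, 4.0], [400.0] * 4)
        out = compute_cfb(tp, baseline_frame(value=400.0))
        assert out["cfb_ms"].iloc[0] == pytest.approx(0.0)

    def test_hand_window_mean(self):
        # window values {402, 404, 406, 404, 402, 406}, baseline 400 -> CfB 4.0
        tp = tp_frame(
            [1.0, 1.5, 2.0, 2.5, 3.0, 4.0], [402.0, 404.0, 406.0, 404.0, 402.0, 406.0]
        )
        out = compute_cfb(tp, baseline_frame(value=400.0), scope="window_1_4h")
        assert out["cfb_ms"].iloc[0] == pytest.approx(4.0)
        assert out["n_timepoints"].iloc[0] == 6

    def test_window_1_4_uses_exactly_six_timepoints(self):
        tp = tp_frame([0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0], [400.0] * 8)
        out = compute_cfb(tp, baseline_frame(), scope="window_1_4h")
        assert out["n_timepoints"].iloc[0] == 6

    def test_2_4_window_on_control_schedule(self):
        times = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0]
        vals = [390.0, 390.0, 390.0, 410.0, 410.0, 410.0, 410.0, 390.0]
        tp = tp_frame(times, vals, treatment="control")
        out = compute_cfb(tp, baseline_frame(value=400.0), scope="window_2_4h")
        assert out["cfb_ms"].iloc[0] == pytest.approx(10.0)  # only {2,2.5,3,4} used

    def test_timepoint_scope_one_row_per_time(self):
        tp = tp_frame([0.5, 1.0], [402.0, 404.0])
        out = compute_cfb(tp, baseline_frame(value=400.0), scope="timepoint")
        assert len(out) == 2
        assert list(out["cfb_ms"]) == [pytest.approx(2.0), pytest.approx(4.0)]

    def test_missing_baseline_excluded_and_logged(self):
        tp = pd.concat(
            [
                tp_frame([1.0], [402.0], subject="S001"),
                tp_frame([1.0], [404.0], subject="S002"),
            ]
        )
        out = compute_cfb(tp, baseline_frame(subject="S001"), scope="timepoint")
        assert list(out["subject_id"]) == ["S001"]
        assert out.attrs["rows_dropped_missing_baseline"] == 1


class TestPrimaryAncova:
    def test_balanced_oracle_equals_means_contrast(self):
        """On balanced complete data with no covariate the mixed-model contrast
        equals the plug-in raw-means contrast (machine precision)."""
        df = simulate_endpoint_level(30, true_effects={"therapeutic": 2.0}, seed=3)
        res = fit_contrast(df, "therapeutic", covariates=())
        raw = (
            df.loc[df["treatment"] == "therapeutic", "cfb_ms"].mean()
            - df.loc[df["treatment"] == "placebo", "cfb_ms"].mean()
        )
        assert res.diff_ms == pytest.approx(raw, abs=1e-8)

    def test_effect_recovery(self):
        ests = [
            fit_contrast(
                simulate_endpoint_level(
                    27, true_effects={"supratherapeutic": 12.0}, seed=s
                ),
                "supratherapeutic",
                covariates=(),
            ).diff_ms
            for s in range(30)
        ]
        # each estimate has SE ~2.33 -> mean of 30 has SE ~0.43
        assert np.mean(ests) == pytest.approx(12.0, abs=1.5)

    def test_ci_duality_with_margin_test(self):
        """Exact duality: one-sided p < alpha iff upper 90% bound < margin."""
        for s in range(60):
            df = simulate_endpoint_level(20, true_effects={"therapeutic": 6.0}, seed=s)
            res = fit_contrast(df, "therapeutic", covariates=())
            assert (res.p_one_sided_vs_margin < 0.05) == (res.ci90[1] < 10.0)

    def test_null_rejection_rate_near_alpha(self):
        """Superiority test at zero true effect rejects ~5% (120 replicates,
        MC SE ~2%)."""
        rejections = [
            fit_contrast(
                simulate_endpoint_level(20, seed=s), "therapeutic", covariates=()
            ).p_superiority
            < 0.05
            for s in range(120)
        ]
        assert 0.0 <= np.mean(rejections) <= 0.12

    def test_all_actives_fitted(self, cfb_primary):
        res = fit_primary_ancova(cfb_primary)
        assert set(res) == {"therapeutic", "supratherapeutic", "control"}
        for r in res.values():
            assert r.ci90[0] < r.diff_ms < r.ci90[1]
            assert r.se_diff > 0

    def test_null_doses_negative_at_margin(self, cfb_primary):
        res = fit_primary_ancova(cfb_primary)
        assert res["therapeutic"].negative
        assert res["supratherapeutic"].negative

    def test_intersection_union_no_alpha_adjustment(self, cfb_primary):
        """Structural: each dose is tested at full one-sided alpha; the trial
        decision is the conjunction of per-dose decisions."""
        res = fit_primary_ancova(cfb_primary, alpha=0.05)
        for r in res.values():
            halfwidth = r.ci90[1] - r.diff_ms
            from scipy import stats

            assert halfwidth == pytest.approx(
                stats.t.ppf(0.95, r.df) * r.se_diff, rel=1e-9
            )

    def test_single_treatment_unestimable(self):
        df = simulate_endpoint_level(10, seed=0)
        with pytest.raises(UnestimableError):
            fit_contrast(df[df["treatment"] == "placebo"], "therapeutic")


class TestRmcByTimepoint:
    def test_constant_effect_recovered_per_timepoint(self):
        rng = np.random.default_rng(7)
        rows = []
        layouts = [  # rotate so treatment is not aliased with period
            ["placebo", "placebo", "therapeutic"],
            ["placebo", "therapeutic", "placebo"],
            ["therapeutic", "placebo", "placebo"],
        ]
        for i in range(24):
            sid = f"S{i:03d}"
            for p, trt in enumerate(layouts[i % 3], start=1):
                for t in (0.5, 1.0, 2.0):
                    eff = 5.0 if trt == "therapeutic" else 0.0
                    rows.append(
                        {
                            "subject_id": sid,
                            "period": p,
                            "treatment": trt,
                            "time_h": t,
                            "cfb_ms": eff + rng.normal(0, 3.0),
                        }
                    )
        out = fit_rmc_by_timepoint(pd.DataFrame(rows))
        assert len(out) == 3
        assert np.allclose(out["diff_ms"], 5.0, atol=2.5)

    def test_control_missing_late_timepoints_skipped(self, cfb_timepoint):
        out = fit_rmc_by_timepoint(cfb_timepoint, actives=("control",))
        assert not set(out["time_h"]) & {8.0, 12.0, 24.0}
        assert "control" in out.attrs["max_upper_ci"]

    def test_null_dose_estimates_small(self, cfb_timepoint):
        out = fit_rmc_by_timepoint(cfb_timepoint, actives=("supratherapeutic",))
        # true effect 0 at every timepoint; per-timepoint SE ~ 3.7 ms
        assert out["diff_ms"].abs().max() < 12.0


class TestAssaySensitivity:
    def test_control_effect_detected(self, corrected, baselines):
        cfb = compute_cfb(corrected, baselines, scope="window_2_4h")
        res = assay_sensitivity_test(cfb)
        assert res.extra["assay_sensitive"]
        assert res.diff_ms == pytest.approx(12.0, abs=4.0)

    def test_zero_effect_not_systematically_sensitive(self):
        hits = []
        for s in range(40):
            df = simulate_endpoint_level(20, seed=100 + s)
            res = fit_contrast(df, "control", covariates=())
            hits.append(res.p_superiority < 0.05)
        assert np.mean(hits) < 0.2  # ~5% expected; 40 reps, MC SE ~3.5%


class TestCategorical:
    def _toy(self):
        # 28 subjects on therapeutic, one exceeding 450 ms at 1 h
        rows = []
        for i in range(28):
            val = 460.0 if i == 0 else 420.0
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "period": 3,
                    "treatment": "therapeutic",
                    "time_h": 1.0,
                    "qtc_ms": val,
                }
            )
        return pd.DataFrame(rows)

    def test_one_of_28_is_3_6_pct(self):
        tp = self._toy()
        cfb = tp.assign(cfb_ms=0.0)
        out = categorical_analysis(tp, cfb)
        row = out[(out["rule"] == "qtc_ms>450") & (out["treatment"] == "therapeutic")]
        assert row["n_exceeding"].iloc[0] == 1
        assert row["incidence_pct"].iloc[0] == pytest.approx(3.6, abs=0.05)

    def test_all_below_thresholds_zero(self):
        tp = self._toy()
        tp["qtc_ms"] = 400.0
        out = categorical_analysis(tp, tp.assign(cfb_ms=0.0))
        assert (out["n_exceeding"] == 0).all()

    def test_hand_enumeration_five_subjects(self):
        rows = []
        specs = {  # subject -> (qtc at 1h, cfb at 1h)
            "S1": (455.0, 35.0),
            "S2": (445.0, 31.0),
            "S3": (485.0, 10.0),
            "S4": (430.0, 5.0),
            "S5": (451.0, 29.0),
        }
        for sid, (qtc, cfb) in specs.items():
            rows.append(
                {
                    "subject_id": sid,
                    "period": 1,
                    "treatment": "therapeutic",
                    "time_h": 1.0,
                    "qtc_ms": qtc,
                    "cfb_ms": cfb,
                }
            )
        df = pd.DataFrame(rows)
        out = categorical_analysis(df, df).set_index("rule")
        assert out.loc["qtc_ms>450", "n_exceeding"] == 3  # S1, S3, S5
        assert out.loc["qtc_ms>480", "n_exceeding"] == 1  # S3
        assert out.loc["change>30", "n_exceeding"] == 2  # S1, S2

    def test_placebo_period_adjusted_denominator(self):
        rows = []
        for i in range(10):
            for p in (1, 5):
                rows.append(
                    {
                        "subject_id": f"S{i:03d}",
                        "period": p,
                        "treatment": "placebo",
                        "time_h": 1.0,
                        "qtc_ms": 455.0 if (i == 0 and p == 1) else 430.0,
                    }
                )
        tp = pd.DataFrame(rows)
        out = categorical_analysis(tp, tp.assign(cfb_ms=0.0))
        row = out[out["rule"] == "qtc_ms>450"]
        # 1 exceeding subject-period out of 20: period-adjusted 5%
        assert row["n_subject_periods"].iloc[0] == 20
        assert row["incidence_pct"].iloc[0] == pytest.approx(5.0)


class TestNotableChanges:
    def _frame(self, hr=60.0, pr=160.0, qrs=95.0):
        tp = pd.DataFrame(
            {
                "subject_id": ["S001"],
                "period": [1],
                "treatment": ["therapeutic"],
                "time_h": [2.0],
                "hr_bpm": [hr],
                "pr_ms": [pr],
                "qrs_ms": [qrs],
            }
        )
        base = pd.DataFrame(
            {
                "subject_id": ["S001"],
                "period": [1],
                "baseline_hr_bpm": [70.0],
                "baseline_pr_ms": [160.0],
                "baseline_qrs_ms": [95.0],
            }
        )
        return tp, base

    def test_hr_low_with_large_decrease_notable(self):
        tp, base = self._frame(hr=48.0)  # ~31% below baseline 70, below 50 bpm
        out = notable_changes(tp, base)
        assert ("hr" == out["parameter"]).any()

    def test_hr_low_small_decrease_not_notable(self):
        tp, base = self._frame(hr=48.0)
        base["baseline_hr_bpm"] = 53.0  # ~9% change only: fails % condition
        out = notable_changes(tp, base)
        assert not ("hr" == out["parameter"]).any()

    def test_pr_increase_notable(self):
        tp, base = self._frame(pr=210.0)
        base["baseline_pr_ms"] = 165.0  # +27% and > 200 ms
        out = notable_changes(tp, base)
        assert ("pr" == out["parameter"]).any()

    def test_pr_high_but_small_increase_not_notable(self):
        tp, base = self._frame(pr=210.0)
        base["baseline_pr_ms"] = 200.0  # +5%: fails % condition
        out = notable_changes(tp, base)
        assert not ("pr" == out["parameter"]).any()

    def test_default_trial_notables_are_rare(self, corrected, baselines):
        # the iid HR noise occasionally trips the conjunction rule; notable
        # records must stay a small fraction of the post-dose records
        out = notable_changes(corrected, baselines)
        n_post = (corrected["time_h"] > 0).sum()
        assert len(out) / n_post < 0.05


class TestSubgroup:
    def test_both_sexes_estimated(self, cfb_primary):
        out = subgroup_analysis(cfb_primary, factor="sex")
        assert set(out) == {"M", "F"}
        for level in out.values():
            assert abs(level["supratherapeutic"].diff_ms) < 10.0

    def test_single_level_warns_and_skips(self, cfb_primary):
        males = cfb_primary[cfb_primary["sex"] == "M"].copy()
        males = males[males["treatment"].isin(["placebo"])]
        df = males.assign(sex="M")
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out = subgroup_analysis(df, factor="sex")
        assert out == {}
        assert rec


class TestSensitivityAnalyses:
    def test_single_placebo_table_shape_and_ratios(self, cfb_primary):
        out = sensitivity_single_placebo(cfb_primary, actives=("supratherapeutic",))
        assert set(out["model"]) == {
            "placebo_period_1_only",
            "placebo_period_2_only",
            "both_placebo_periods",
        }
        both = out[out["model"] == "both_placebo_periods"]["se_ratio_vs_double"]
        assert np.allclose(both, 1.0)
        singles = out[out["model"] != "both_placebo_periods"]["se_ratio_vs_double"]
        assert (singles >= 0.85).all()  # single never dramatically below double

    def test_double_se_not_above_singles_on_endpoint_data(self):
        worse = 0
        for s in range(12):
            df = simulate_endpoint_level(27, seed=200 + s)
            out = sensitivity_single_placebo(df, actives=("therapeutic",))
            singles = out.loc[
                out["model"] != "both_placebo_periods", "se_ratio_vs_double"
            ]
            worse += int((singles < 1.0).any())
        assert worse <= 3  # pooled placebo almost always at least as precise

    def test_identical_placebo_periods_degenerate_limit(self):
        """If the two placebo occasions carry identical values (zero
        within-subject placebo noise), the single- and double-placebo fits
        coincide.  Design factors are stripped so the placebo rows are truly
        exchangeable."""
        df = simulate_endpoint_level(20, seed=5)
        occ1 = df[(df["treatment"] == "placebo") & (df["placebo_occasion"] == 1)]
        act = df[df["treatment"] == "therapeutic"]
        occ2 = occ1.copy()  # identical values, second occasion
        bare_cols = ["subject_id", "treatment", "cfb_ms"]
        single = fit_contrast(
            pd.concat([act, occ1])[bare_cols], "therapeutic", covariates=()
        )
        double = fit_contrast(
            pd.concat([act, occ1, occ2])[bare_cols], "therapeutic", covariates=()
        )
        assert single.diff_ms == pytest.approx(double.diff_ms, abs=1e-7)

    def test_global_baseline_equal_baselines_matches_primary(self):
        df = simulate_endpoint_level(24, seed=9)
        df["baseline_ms"] = 400.0  # identical across periods
        primary = fit_primary_ancova(df, actives=("therapeutic",))
        glob = sensitivity_global_baseline(df, actives=("therapeutic",))
        assert glob["therapeutic"].diff_ms == pytest.approx(
            primary["therapeutic"].diff_ms, abs=1e-6
        )

    def test_global_baseline_null_near_zero(self):
        ests = []
        for s in range(20):
            df = simulate_endpoint_level(24, seed=300 + s)
            df["baseline_ms"] = 400.0
            ests.append(sensitivity_global_baseline(df, actives=("therapeutic",))["therapeutic"].diff_ms)
        assert np.mean(ests) == pytest.approx(0.0, abs=2.0)

    def test_one_step_rr_constant_equals_uncorrected(self):
        df = simulate_endpoint_level(24, seed=10)
        df["baseline_ms"] = 400.0
        rr = df.copy()
        rr["cfb_ms"] = 0.0  # constant RR CfB: covariate dropped
        one = one_step_qt_analysis(df, rr, actives=("therapeutic",))
        plain = fit_primary_ancova(df, actives=("therapeutic",))
        assert one["therapeutic"].diff_ms == pytest.approx(
            plain["therapeutic"].diff_ms, abs=1e-6
        )

    def test_one_step_sign_concordance(self, corrected, baselines):
        qt_cfb = compute_cfb(corrected, baselines, scope="window_2_4h", value_col="qt_ms")
        rr_cfb = compute_cfb(corrected, baselines, scope="window_2_4h", value_col="rr_ms")
        one = one_step_qt_analysis(qt_cfb, rr_cfb, actives=("control",))
        qtc_cfb = compute_cfb(corrected, baselines, scope="window_2_4h")
        two = fit_primary_ancova(qtc_cfb, actives=("control",))
        assert np.sign(one["control"].diff_ms) == np.sign(two["control"].diff_ms)
        assert one["control"].diff_ms == pytest.approx(two["control"].diff_ms, abs=4.0)
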