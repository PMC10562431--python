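"""Adjusted treatment differences, HOMA-IR, Holm step-down, adherence
summaries and participant-flow accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from genodiet.analysis import (
    TreatmentEffectModel,
    adjusted_difference,
    consort_accounting,
    holm_adjust,
    homa_ir,
    insulin_association,
    summarize_adherence,
)


class TestHomaIr:
    def test_standard_example(self):
        assert homa_ir(100, 10) == pytest.approx(2.469, abs=5e-4)

    def test_zero_insulin(self):
        assert homa_ir(100, 0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            homa_ir(-5, 10)

    def test_bilinear(self):
        assert homa_ir(200, 10) == pytest.approx(2 * homa_ir(100, 10))
        assert homa_ir(100, 20) == pytest.approx(2 * homa_ir(100, 10))

    def test_molar_denominator(self):
        assert homa_ir(5.5, 10, denominator=22.5) == pytest.approx(5.5 * 10 / 22.5)


def _trial_frame(n_per_arm, effect, sd, seed, baseline_slope=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    group = np.repeat([False, True], n_per_arm)
    baseline = rng.normal(95, 15, n)
    y = effect * group + baseline_slope * (baseline - 95) + rng.normal(0, sd, n)
    return pd.DataFrame(
        {
            "weight_change": y,
            "concordant": group,
            "sex": rng.choice(["female", "male"], n, p=[0.84, 0.16]),
            "race": rng.choice(["white", "black", "other"], n, p=[0.68, 0.295, 0.025]),
            "weight": baseline,
        }
    )


class TestAdjustedDifference:
    def test_unadjusted_equals_pooled_t_oracle(self):
        """With no covariates the model reduces to the pooled-variance
        two-sample t-test (independent scipy oracle)."""
        df = _trial_frame(30, effect=-1.5, sd=2.8, seed=1)
        est = adjusted_difference(df, "weight_change", "concordant", covariates=())
        a = df.loc[df["concordant"], "weight_change"]
        b = df.loc[~df["concordant"], "weight_change"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert est.estimate == pytest.approx(a.mean() - b.mean(), abs=1e-10)
        assert est.p_value == pytest.approx(p, abs=1e-10)

    def test_injected_effect_recovered_at_large_n(self):
        df = _trial_frame(5000, effect=-2.0, sd=2.8, seed=2, baseline_slope=0.02)
        est = adjusted_difference(
            df, "weight_change", "concordant", covariates=("sex", "race"), baseline="weight"
        )
        se = 2.8 * np.sqrt(2 / 5000)
        assert abs(est.estimate - (-2.0)) < 3 * se

    def test_constant_covariate_dropped_with_warning(self):
        df = _trial_frame(20, effect=0.0, sd=1.0, seed=3)
        df["race"] = "white"
        with pytest.warns(UserWarning, match="race"):
            est = adjusted_difference(
                df, "weight_change", "concordant", covariates=("sex", "race")
            )
        assert "race" not in est.covariates

    def test_identical_constant_outcomes_degenerate(self):
        df = pd.DataFrame(
            {
                "weight_change": [1.0] * 8,
                "concordant": [False, True] * 4,
                "sex": ["female"] * 8,
            }
        )
        est = adjusted_difference(df, "weight_change", "concordant", covariates=())
        assert est.estimate == pytest.approx(0.0, abs=1e-9)
        assert est.p_value == 1.0 and est.degenerate

    def test_all_missing_outcome_errors(self):
        df = _trial_frame(10, 0, 1, 4)
        df["weight_change"] = np.nan
        with pytest.raises(ValueError):
            adjusted_difference(df, "weight_change", "concordant", covariates=())

    def test_complete_case_drops_missing(self):
        df = _trial_frame(30, effect=0.0, sd=1.0, seed=5)
        df.loc[:9, "weight_change"] = np.nan
        est = adjusted_difference(df, "weight_change", "concordant", covariates=())
        assert est.n_used == 50

    def test_subject_order_and_race_label_invariance(self):
        df = _trial_frame(40, effect=-1.0, sd=2.0, seed=6)
        est1 = adjusted_difference(df, "weight_change", "concordant", covariates=("sex", "race"))
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        shuffled["race"] = shuffled["race"].map({"white": "w", "black": "b", "other": "o"})
        est2 = adjusted_difference(
            shuffled, "weight_change", "concordant", covariates=("sex", "race")
        )
        assert est1.estimate == pytest.approx(est2.estimate, abs=1e-10)
        assert est1.p_value == pytest.approx(est2.p_value, abs=1e-10)

    def test_null_type_one_error_calibrated(self):
        """500 null replicates at n=32/arm: rejection rate within 3 binomial
        SEs of 0.05 (the ANCOVA route, small-sample t inference)."""
        rejections = 0
        reps = 500
        for i in range(reps):
            df = _trial_frame(32, effect=0.0, sd=2.8, seed=1000 + i)
            est = adjusted_difference(
                df, "weight_change", "concordant", covariates=("sex",), baseline="weight"
            )
            rejections += est.p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_mixed_model_variant_agrees_with_ancova(self):
        """The two-timepoint random-intercept fit gives the same contrast as
        change-score ANCOVA to within a small tolerance."""
        df = _trial_frame(150, effect=-2.0, sd=2.8, seed=7)
        df["subject_id"] = [f"s{i}" for i in range(len(df))]
        model = TreatmentEffectModel(
            df, "weight_change", "concordant", covariates=("sex",), baseline="weight"
        )
        ancova = model.fit("ancova")
        mixed = model.fit("mixed")
        assert mixed.estimate == pytest.approx(ancova.estimate, abs=0.3)

    def test_summary_contains_key_numbers(self):
        df = _trial_frame(30, effect=-1.0, sd=2.0, seed=8)
        res = TreatmentEffectModel(df, "weight_change", "concordant", covariates=("sex",)).fit()
        text = res.summary()
        assert f"{res.estimate:.3f}" in text and "95% CI" in text


class TestHolm:
    def test_smallest_of_six_scaled_to_0006(self):
        res = holm_adjust([0.001, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert res.adjusted_p[0] == pytest.approx(0.006)

    def test_single_p_identity(self):
        assert holm_adjust([0.03]).adjusted_p == (0.03,)

    def test_hand_run_step_down(self):
        assert holm_adjust([0.01, 0.04, 0.03]).adjusted_p == pytest.approx((0.03, 0.06, 0.06))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=150, derandomize=True)
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        res = holm_adjust(ps)
        oracle = multipletests(ps, method="holm")[1]
        assert np.allclose(res.adjusted_p, oracle, atol=1e-12)
        assert all(a >= r for a, r in zip(res.adjusted_p, res.raw_p))
        assert all(a <= 1 for a in res.adjusted_p)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_order_invariance(self, ps):
        res = holm_adjust(ps)
        rev = holm_adjust(ps[::-1])
        assert np.allclose(res.adjusted_p, rev.adjusted_p[::-1], atol=1e-12)

    def test_all_equal_p(self):
        res = holm_adjust([0.02, 0.02, 0.02])
        assert res.adjusted_p[0] == pytest.approx(min(1.0, 3 * 0.02))
        assert res.adjusted_p == tuple(sorted(res.adjusted_p))


class TestInsulinAssociation:
    def _frame(self, n, slope, seed, interaction=0.0):
        rng = np.random.default_rng(seed)
        arm = rng.choice(["high_fat", "high_carb"], n)
        insulin = rng.lognormal(np.log(12), 0.45, n)
        y = -5 + slope * insulin + interaction * insulin * (arm == "high_fat") + rng.normal(0, 2.8, n)
        return pd.DataFrame(
            {
                "weight_change": y,
                "fasting_insulin": insulin,
                "arm": arm,
                "sex": rng.choice(["female", "male"], n),
                "race": rng.choice(["white", "black"], n),
            }
        )

    def test_slope_recovered(self):
        df = self._frame(4000, slope=-0.1, seed=1)
        res = insulin_association(df, "fasting_insulin")
        assert res["slope"].ci_low < -0.1 < res["slope"].ci_high

    def test_linear_reparameterization_halves_slope(self):
        df = self._frame(500, slope=-0.1, seed=2)
        res1 = insulin_association(df, "fasting_insulin")
        df["doubled"] = 2 * df["fasting_insulin"]
        res2 = insulin_association(df, "doubled")
        assert res2["slope"].estimate == pytest.approx(res1["slope"].estimate / 2, rel=1e-9)

    def test_zero_variance_predictor_rejected(self):
        df = self._frame(50, 0, 3)
        df["fasting_insulin"] = 7.0
        with pytest.raises(ValueError):
            insulin_association(df, "fasting_insulin")

    def test_null_interaction_p_roughly_uniform(self):
        """Under no true interaction the interaction p-values are U(0,1):
        KS check over 200 replicates."""
        ps = [
            insulin_association(self._frame(120, slope=-0.05, seed=100 + i), "fasting_insulin")[
                "interaction_p"
            ]
            for i in range(200)
        ]
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_coverage_of_null_slope(self):
        """CI for a zero slope covers 0 in >=94% of 300 replicates."""
        covered = 0
        for i in range(300):
            res = insulin_association(self._frame(250, slope=0.0, seed=2000 + i), "fasting_insulin")
            covered += res["slope"].ci_low <= 0 <= res["slope"].ci_high
        assert covered / 300 >= 0.94


class TestSummarizeAdherence:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["subject_id", "arm", "week", "carb_pct", "fat_pct", "protein_pct"]
        )

    def test_exact_target_zero_deviation(self):
        recs = self._records(
            [["s1", "high_carb", 4, 65.0, 20.0, 15.0], ["s2", "high_carb", 4, 65.0, 20.0, 15.0]]
        )
        out = summarize_adherence(recs)
        assert (out["deviation"].abs() < 1e-12).all()

    def test_single_record_sd_missing(self):
        recs = self._records([["s1", "high_fat", 4, 45.0, 40.0, 15.0]])
        out = summarize_adherence(recs)
        assert out["sd"].isna().all() and (out["n"] == 1).all()

    def test_mean_and_deviation(self):
        recs = self._records(
            [["s1", "high_carb", 4, 62.0, 22.0, 16.0], ["s2", "high_carb", 4, 64.0, 20.0, 16.0]]
        )
        out = summarize_adherence(recs)
        carb = out[(out["macro"] == "carb")].iloc[0]
        assert carb["mean"] == pytest.approx(63.0)
        assert carb["deviation"] == pytest.approx(-2.0)


class TestConsortAccounting:
    def test_stage_counts(self):
        ids = [f"s{i}" for i in range(10)]
        stages = {"screened": ids, "eligible": ids[:8], "completed": ids[:7]}
        out = consort_accounting(stages)
        assert list(out["n"]) == [10, 8, 7]
        assert list(out["excluded_from_previous"]) == [0, 2, 1]

    def test_non_nested_flags_error(self):
        with pytest.raises(ValueError, match="not nested"):
            consort_accounting({"screened": ["a", "b"], "eligible": ["a", "c"]})

    def test_class_fractions_attached(self):
        stages = {"genotyped": ["a", "b", "c", "d"], "randomized": ["a", "b"]}
        classes = {"a": "fat_responder", "b": "fat_responder", "c": "carb_responder", "d": "both"}
        out = consort_accounting(stages, class_by_subject=classes)
        assert out.attrs["class_fractions"]["fat_responder"] == pytest.approx(0.5)
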