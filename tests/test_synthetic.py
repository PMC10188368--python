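import math

import numpy as np
import pandas as pd
import pytest

from perimort import (
    ReportingErrorParams,
    TrueCohortParams,
    build_interval_counts,
    calibrated_cohort_params,
    error_preset,
    expected_interval_deaths,
    inject_reporting_errors,
    recovery_experiment,
    simulate_cohort,
    true_rates,
)


def small_params(n=2000, **kw):
    return calibrated_cohort_params(n, **kw)


class TestParamsValidation:
    def test_wrong_hazard_count_rejected(self):
        with pytest.raises(ValueError, match="9"):
            TrueCohortParams(1000, 0.02, daily_hazards=(0.01,) * 8)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TrueCohortParams(1000, 1.5, daily_hazards=(0.01,) * 9)

    def test_error_probability_sums_checked(self):
        with pytest.raises(ValueError):
            ReportingErrorParams(p_sb_omit=0.7, p_sb_to_d0=0.5)

    def test_invalid_heap_day_rejected(self):
        with pytest.raises(ValueError):
            ReportingErrorParams(p_heap={7: 0.5})

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            error_preset("mild")


class TestCalibration:
    def test_expected_ratios_hit_reference_constants_exactly(self):
        params = small_params(50000, sbr_per_1000=22.0)
        e = expected_interval_deaths(params)
        assert e[0] / e[1] == pytest.approx(1.89, rel=1e-9)
        assert e[1] / e[2:7].sum() == pytest.approx(2.4, rel=1e-9)

    def test_true_rates_arithmetic(self):
        params = TrueCohortParams(
            1000, 0.02, daily_hazards=(0.01, 0.002, 0.002, 0.002, 0.002, 0.002, 0, 0, 0)
        )
        r = true_rates(params)
        q_en = 1 - 0.99 * (1 - 0.002) ** 5
        assert r.sbr == pytest.approx(20.0)
        assert r.enmr == pytest.approx(1000 * q_en)
        assert r.pmr == pytest.approx(1000 * (1 - 0.98 * (1 - q_en)))

    def test_calibrated_truth_matches_requested_sbr(self):
        params = small_params(1000, sbr_per_1000=30.0)
        assert true_rates(params).sbr == pytest.approx(30.0)


class TestSimulateCohort:
    def test_seed_determinism(self):
        params = small_params()
        df1, _ = simulate_cohort(params, seed=11)
        df2, _ = simulate_cohort(params, seed=11)
        pd.testing.assert_frame_equal(df1, df2)
        df3, _ = simulate_cohort(params, seed=12)
        assert not df1.equals(df3)

    def test_zero_hazards_everyone_survives(self):
        params = TrueCohortParams(
            500, 0.0, daily_hazards=(0.0,) * 9, ongoing_fraction=0.0
        )
        df, truth = simulate_cohort(params, seed=1)
        assert (df["outcome"] == "livebirth").all()
        assert df["child_alive"].all()
        assert (truth.sbr, truth.enmr, truth.pmr) == (0.0, 0.0, 0.0)

    def test_large_sample_tracks_true_stillbirth_risk(self):
        params = small_params(100000, sbr_per_1000=22.0)
        df, _ = simulate_cohort(params, seed=5)
        completed = df[df["outcome"] != "ongoing"]
        p_hat = (completed["outcome"] == "stillbirth").mean()
        se = math.sqrt(0.022 * 0.978 / len(completed))
        assert abs(p_hat - 0.022) < 3 * se

    def test_frame_feeds_tabulation_consistently(self):
        params = small_params(5000)
        df, _ = simulate_cohort(params, seed=2)
        table = build_interval_counts(df)
        n_sb = int((df["outcome"] == "stillbirth").sum())
        n_ongoing = int((df["outcome"] == "ongoing").sum())
        assert table.deaths[0] == n_sb
        assert table.censored[0] == n_ongoing
        assert table.total_pregnancies == len(df)

    def test_ongoing_records_have_interview_offset(self):
        params = small_params(3000)
        df, _ = simulate_cohort(params, seed=3)
        ongoing = df[df["outcome"] == "ongoing"]
        assert len(ongoing) > 0
        assert (
            ongoing["conception_offset_months"] == ongoing["gestation_months"]
        ).all()


class TestInjectErrors:
    def test_zero_errors_identity(self):
        df, _ = simulate_cohort(small_params(), seed=7)
        out, ledger = inject_reporting_errors(df, error_preset("none"))
        pd.testing.assert_frame_equal(out, df)
        assert ledger.empty

    def test_error_seed_determinism(self):
        df, _ = simulate_cohort(small_params(20000), seed=7)
        errs = ReportingErrorParams(p_sb_omit=0.5, seed=42)
        out1, led1 = inject_reporting_errors(df, errs)
        out2, led2 = inject_reporting_errors(df, errs)
        pd.testing.assert_frame_equal(out1, out2)
        pd.testing.assert_frame_equal(led1, led2)

    def test_certain_stillbirth_omission_removes_them_all(self):
        df, _ = simulate_cohort(small_params(20000), seed=7)
        out, ledger = inject_reporting_errors(df, ReportingErrorParams(p_sb_omit=1.0))
        assert (out["outcome"] != "stillbirth").all()
        n_sb = int((df["outcome"] == "stillbirth").sum())
        assert (ledger["action"] == "omitted").sum() == n_sb

    def test_row_conservation(self):
        df, _ = simulate_cohort(small_params(20000), seed=9)
        errs = ReportingErrorParams(p_sb_omit=0.3, p_d01_omit=0.4, seed=1)
        out, ledger = inject_reporting_errors(df, errs)
        n_omitted = int((ledger["action"] == "omitted").sum())
        assert len(out) == len(df) - n_omitted
        # non-omitted record ids are preserved
        assert set(out["record_id"]) == set(df["record_id"]) - set(
            ledger.loc[ledger["action"] == "omitted", "record_id"]
        )

    def test_transference_is_symmetric_in_counts(self):
        df, _ = simulate_cohort(small_params(100000), seed=13)
        errs = ReportingErrorParams(p_sb_to_d0=0.2, p_d0_to_sb=0.2, seed=3)
        out, ledger = inject_reporting_errors(df, errs)
        n_sb_true = int((df["outcome"] == "stillbirth").sum())
        moved_out = int((ledger["action"] == "relabelled_sb_to_d0").sum())
        moved_in = int((ledger["action"] == "relabelled_d0_to_sb").sum())
        assert int((out["outcome"] == "stillbirth").sum()) == (
            n_sb_true - moved_out + moved_in
        )
        # fraction moved matches the probability within 4 binomial SE
        se = math.sqrt(0.2 * 0.8 / n_sb_true)
        assert abs(moved_out / n_sb_true - 0.2) < 4 * se

    def test_certain_day5_heaping_moves_every_day5_death(self):
        df, _ = simulate_cohort(small_params(200000), seed=21)
        n_day5 = int((df["age_at_death_days"] == 5).sum())
        assert n_day5 > 0
        out, ledger = inject_reporting_errors(df, ReportingErrorParams(p_heap={5: 1.0}))
        assert int((out["age_at_death_days"] == 5).sum()) == 0
        assert int((ledger["action"] == "heaped_to_day7").sum()) == n_day5
        n_day7 = int((df["age_at_death_days"] == 7).sum())
        assert int((out["age_at_death_days"] == 7).sum()) == n_day7 + n_day5

    def test_ledger_records_truth(self):
        df, _ = simulate_cohort(small_params(50000), seed=23)
        out, ledger = inject_reporting_errors(
            df, ReportingErrorParams(p_sb_to_d0=1.0)
        )
        moved = ledger[ledger["action"] == "relabelled_sb_to_d0"]
        assert (moved["true_outcome"] == "stillbirth").all()
        assert (moved["recorded_outcome"] == "livebirth").all()
        assert (moved["recorded_age_at_death_days"] == 0).all()


class TestRecoveryExperiment:
    def test_single_rep_deterministic(self):
        params = small_params(4000)
        errs = error_preset("typical")
        r1 = recovery_experiment(params, errs, n_reps=1, seed=99)
        r2 = recovery_experiment(params, errs, n_reps=1, seed=99)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)
        assert r1.n_failed == 0

    def test_clean_data_leaves_models_unbiased(self):
        # ratios calibrated clearly above both triggers, so with error-free
        # data no adjustment should fire in any replicate
        params = small_params(20000, target_sb_d01=2.3, target_d01_d26=3.2)
        result = recovery_experiment(
            params, error_preset("none"), n_reps=8, seed=5, keep_reps=True
        )
        # with no reporting errors every model should sit near the truth
        for m in (1, 2, 3, 4):
            assert abs(result.summary.loc[m, "bias_sbr"]) < 2.0
            assert abs(result.summary.loc[m, "bias_pmr"]) < 3.0
        assert result.per_rep is not None
        assert set(result.per_rep["model"]) == {1, 2, 3, 4}

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            recovery_experiment(small_params(), error_preset("none"), n_reps=0, seed=1)
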