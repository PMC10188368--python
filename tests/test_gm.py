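import math

import numpy as np
import pytest
from sklearn.base import clone

from perimort import (
    AdjustmentConfig,
    GompertzMakehamModel,
    PiecewiseExponentialModel,
    adjust_survey,
    apply_d01_weighting,
    fit_gm,
    quality_report,
)
from perimort.gm import DAY_MIDPOINTS, SurveyAdjuster, _relative_diffs
from perimort.lifetable import MortalityRates
from tests.conftest import make_random_table, make_table


class TestD01Weighting:
    def test_low_ratio_scaled_to_reference(self):
        # D0-1/D2-6 = 96/60 = 1.6 -> weight 1.5, new D0-1 deaths 144
        table = make_table([100, 96, 20, 15, 12, 8, 5, 0, 0, 0], total=10000)
        weighted, w = apply_d01_weighting(table)
        assert w == pytest.approx(1.5)
        assert weighted.deaths[1] == pytest.approx(144.0)
        assert weighted.d01 / weighted.d26 == pytest.approx(2.4)

    def test_flow_conservation_preserved(self):
        table = make_table([100, 96, 20, 15, 12, 8, 5, 0, 0, 0], total=10000)
        weighted, _ = apply_d01_weighting(table)
        for j in range(9):
            assert weighted.entrants[j + 1] == pytest.approx(
                weighted.entrants[j] - weighted.deaths[j] - weighted.censored[j]
            )
        # extra deaths deplete the later at-risk counts
        assert weighted.entrants[2] == pytest.approx(table.entrants[2] - 48)

    def test_inflate_cohort_balance_keeps_later_entrants(self):
        table = make_table([100, 96, 20, 15, 12, 8, 5, 0, 0, 0], total=10000)
        weighted, _ = apply_d01_weighting(table, balance="inflate-cohort")
        assert weighted.total_pregnancies == pytest.approx(10048.0)
        assert weighted.entrants[2] == pytest.approx(table.entrants[2])

    def test_ratio_at_or_above_reference_unchanged(self):
        table = make_table([100, 180, 20, 15, 12, 8, 5, 0, 0, 0], total=10000)
        weighted, w = apply_d01_weighting(table)
        assert w == 1.0
        np.testing.assert_array_equal(weighted.deaths, table.deaths)

    def test_zero_d26_is_an_error(self):
        table = make_table([100, 96, 0, 0, 0, 0, 0, 0, 0, 0], total=10000)
        with pytest.raises(ValueError, match="weighting undefined"):
            apply_d01_weighting(table)

    def test_zero_d01_is_degenerate_noop(self):
        table = make_table([100, 0, 5, 3, 2, 1, 1, 0, 0, 0], total=10000)
        weighted, w = apply_d01_weighting(table)
        assert w == 1.0
        assert weighted.deaths[1] == 0.0


def _grid_best_loglik(d, n):
    """Independent coarse-grid MLE for the smooth days-2-9 hazard."""
    best = -np.inf
    x = np.arange(2.5, 10.0)
    for g0 in np.linspace(0.0, 0.01, 11):
        for a in np.linspace(-12.0, -2.0, 26):
            for b in np.linspace(-2.0, 0.5, 26):
                h = g0 + np.exp(a + b * x)
                q = 1.0 - np.exp(-h)
                with np.errstate(divide="ignore"):
                    ll = np.sum(np.where(d > 0, d * np.log(q), 0.0) + (n - d) * np.log1p(-q))
                best = max(best, ll)
    return best


class TestConstraint:
    def test_observed_ratio_one_is_constrained_to_reference(self):
        # observed STB/D0-1 = 1.0 -> constraint lifts the fitted hazard ratio
        table = make_table([50, 50, 10, 8, 6, 4, 3, 5, 2, 1], total=5000)
        model = GompertzMakehamModel(constraint="auto").fit(table)
        assert model.constraint_active_
        p = model.params_
        assert math.exp(p.gamma1 - p.gamma2) == pytest.approx(1.89, rel=1e-12)
        q = model.life_table_.q
        assert q[0] / q[1] == pytest.approx(1.89, rel=0.01)

    def test_trigger_respected_when_ratio_high(self):
        # observed ratio 2.5 >= 1.89: constraint skipped, saturated q1/q2 kept
        table = make_table([125, 50, 10, 8, 6, 4, 3, 5, 2, 1], total=5000)
        gm = GompertzMakehamModel(constraint="auto").fit(table)
        assert not gm.constraint_active_
        assert any("constraint skipped" in f for f in gm.flags_)
        pwe = PiecewiseExponentialModel().fit(table)
        assert gm.life_table_.q[0] == pytest.approx(pwe.life_table_.q[0], abs=1e-9)
        assert gm.life_table_.q[1] == pytest.approx(pwe.life_table_.q[1], abs=1e-9)

    def test_fit_gm_demotes_constraint_when_quality_trigger_false(self):
        table = make_table([50, 50, 10, 8, 6, 4, 3, 5, 2, 1], total=5000)
        qm = quality_report(table)
        qm.trigger_sb_constraint = False  # externally supplied assessment
        params, _ = fit_gm(table, quality=qm, constraint="auto")
        assert not params.constraint_active


class TestSmoothing:
    def test_day7_heap_redistributed(self, heaped_table):
        model = GompertzMakehamModel(constraint="auto").fit(heaped_table)
        q7 = model.life_table_.q[7]
        expected_day7 = q7 * heaped_table.entrants[7]
        assert expected_day7 < 12  # the observed heap
        assert 0.8 <= model.fitted_heaping_index_ <= 1.3

    def test_optimizer_beats_independent_grid_search(self, heaped_table):
        model = GompertzMakehamModel(constraint=False).fit(heaped_table)
        d, n = heaped_table.deaths[2:], heaped_table.entrants[2:]
        p = model.params_
        h = p.gamma0 + np.exp(p.alpha + p.beta * DAY_MIDPOINTS)
        q = 1.0 - np.exp(-h)
        ll_fit = np.sum(np.where(d > 0, d * np.log(q), 0.0) + (n - d) * np.log1p(-q))
        assert ll_fit >= _grid_best_loglik(d, n) - 1e-6

    def test_all_zero_late_deaths_yield_zero_hazard(self):
        table = make_table([20, 10, 0, 0, 0, 0, 0, 0, 0, 0], total=1000)
        model = GompertzMakehamModel().fit(table)
        assert np.all(model.life_table_.q[2:] == 0.0)
        assert model.fitted_heaping_index_ is None


class TestAdjustSurvey:
    def test_no_triggers_all_models_agree_on_stillbirths(self):
        # SB/D0-1 = 2.0 >= 1.89 and D0-1/D2-6 = 2.5 >= 2.4: nothing to adjust
        table = make_table([200, 100, 12, 10, 8, 6, 4, 3, 2, 1], total=10000)
        est = adjust_survey(table)
        sbrs = [est.models[m].rates.sbr for m in (1, 2, 3, 4)]
        assert max(sbrs) - min(sbrs) < 1e-9

    def test_model3_never_moves_stillbirth_rate(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            table = make_random_table(rng)
            if table.d26 == 0:
                continue
            est = adjust_survey(table)
            assert est.models[3].rates.sbr == pytest.approx(
                est.models[1].rates.sbr, abs=1e-9
            )

    def test_rate_ordering_when_both_triggers_fire(self):
        table = make_table([115, 100, 20, 15, 12, 8, 5, 9, 2, 1], total=10000)
        est = adjust_survey(table)
        assert est.quality.trigger_sb_constraint and est.quality.trigger_d01_weight
        sbr = {m: est.models[m].rates.sbr for m in (1, 2, 3, 4)}
        enmr = {m: est.models[m].rates.enmr for m in (1, 2, 3, 4)}
        assert sbr[4] >= sbr[2] >= sbr[1]
        assert enmr[3] >= enmr[1]

    def test_unconstrained_loglik_dominates_constrained(self):
        table = make_table([115, 100, 20, 15, 12, 8, 5, 9, 2, 1], total=10000)
        free = GompertzMakehamModel(constraint=False).fit(table)
        constrained = GompertzMakehamModel(constraint="auto").fit(table)
        assert constrained.constraint_active_
        assert free.loglik_input_ >= constrained.loglik_input_

    def test_relative_difference_arithmetic(self):
        m1 = MortalityRates(sbr=12.2, enmr=19.2, pmr=32.6, model="model1")
        m4 = MortalityRates(sbr=25.6, enmr=19.5, pmr=44.8, model="model4")
        diffs = _relative_diffs(m4, m1)
        assert diffs["sbr"] == pytest.approx(109.8, abs=0.05)

    def test_model_failure_isolated(self):
        # no deaths on days 2-6: models 3 and 4 cannot weight, others intact
        table = make_table([30, 20, 0, 0, 0, 0, 0, 0, 0, 0], total=1000)
        est = adjust_survey(table)
        assert est.models[3].error is not None
        assert est.models[4].error is not None
        assert est.models[1].error is None and est.models[1].rates.sbr > 0
        assert est.models[2].error is None

    def test_weighted_model4_reevaluates_trigger(self):
        # raw SB/D0-1 = 1.8 < 1.89 but after weighting D0-1 the ratio drops
        # further, so the constraint must still be applied on the weighted table
        table = make_table([180, 100, 20, 15, 12, 8, 5, 0, 0, 0], total=10000)
        est = adjust_survey(table)
        p4 = est.models[4].params
        assert p4.d01_weight > 1.0
        assert p4.constraint_active

    def test_output_serializes_to_json(self, heaped_table):
        est = adjust_survey(heaped_table)
        payload = est.to_json()
        assert '"models"' in payload and '"quality"' in payload


class TestSurveyAdjuster:
    def test_sklearn_api_and_results(self, heaped_table):
        adj = SurveyAdjuster(models=(1, 2))
        assert clone(adj).get_params()["models"] == (1, 2)
        adj.fit(heaped_table)
        assert set(adj.rates_) == {1, 2}
        assert adj.quality_.heaping_index_day7 == pytest.approx(2.4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdjustmentConfig(models=(1, 5))
        with pytest.raises(ValueError):
            AdjustmentConfig(tol=-1.0)
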