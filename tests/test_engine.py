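"""Markov engine: odds-ratio transform, transition building, cycle stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cctecea as cc
from cctecea.engine import apply_odds_ratio, build_transitions, step_cycle
from cctecea.population import generate_population
from cctecea.toys import make_homogeneous_cohort

ALL_Q = frozenset({1, 2})


def null_strategy():
    return cc.StrategyConfig(False, False, ALL_Q)


def test_apply_odds_ratio_matches_direct_odds_arithmetic():
    # odds 1.0 -> 1.31, back-transformed
    assert apply_odds_ratio(0.5, 1.31) == pytest.approx(1.31 / 2.31)
    assert apply_odds_ratio(0.5, 1.31) == pytest.approx(0.56710, abs=1e-5)


@given(p=st.floats(0, 1), or_value=st.floats(0.01, 100))
def test_apply_odds_ratio_stays_in_unit_interval(p, or_value):
    out = apply_odds_ratio(p, or_value)
    assert 0.0 <= out <= 1.0


@given(p=st.floats(0.01, 0.99))
def test_apply_odds_ratio_identity_and_monotonicity(p):
    assert apply_odds_ratio(p, 1.0) == pytest.approx(p)
    assert apply_odds_ratio(0.0, 7.0) == 0.0
    assert apply_odds_ratio(p, 1.5) < apply_odds_ratio(p, 2.5)


def test_apply_odds_ratio_rejects_bad_inputs():
    with pytest.raises(ValueError):
        apply_odds_ratio(1.2, 1.0)
    with pytest.raises(ValueError):
        apply_odds_ratio(0.5, 0.0)


def _individual(params, state=cc.HealthState.UNDIAGNOSED, quintile=1):
    coh = make_homogeneous_cohort(1, params, age=50, quintile=quintile,
                                  cascade=state)
    return coh.individual(0)


def test_diagnosis_coverage_boosts_p_dx_for_eligible(params):
    ind = _individual(params)
    covered = build_transitions(ind, cc.StrategyConfig(True, False, ALL_Q), params)
    plain = build_transitions(ind, null_strategy(), params)
    assert plain.p_diagnosis == params.cascade.p_dx
    assert covered.p_diagnosis == pytest.approx(
        apply_odds_ratio(params.cascade.p_dx, 1.31))
    assert covered.p_diagnosis > plain.p_diagnosis
    # ineligible quintile: no boost
    ind3 = _individual(params, quintile=3)
    out = build_transitions(ind3, cc.StrategyConfig(True, False, ALL_Q), params)
    assert out.p_diagnosis == params.cascade.p_dx


def test_null_strategy_leaves_nonadherence_unchanged(params):
    ind = _individual(params, state=cc.HealthState.ORAL_THERAPY)
    out = build_transitions(ind, null_strategy(), params)
    assert out.p_nonadherence == params.cascade.p_tna


def test_treatment_coverage_reduces_nonadherence_on_adherence_odds(params):
    ind = _individual(params, state=cc.HealthState.ORAL_THERAPY)
    out = build_transitions(ind, cc.StrategyConfig(False, True, ALL_Q), params)
    adherence = apply_odds_ratio(1 - params.cascade.p_tna, 1.31)
    assert out.p_nonadherence == pytest.approx(1 - adherence)
    assert out.p_nonadherence < params.cascade.p_tna


def test_therapy_effect_multiplies_complication_risk(params):
    untreated = _individual(params, state=cc.HealthState.UNDIAGNOSED)
    treated = _individual(params, state=cc.HealthState.ORAL_THERAPY)
    k = list(cc.COMPLICATION_STATES).index(cc.HealthState.NEPHROPATHY)
    p_unt = build_transitions(untreated, null_strategy(), params)
    p_trt = build_transitions(treated, null_strategy(), params)
    assert p_unt.complication_probs[k] == pytest.approx(0.010)
    assert p_trt.complication_probs[k] == pytest.approx(0.010 * 0.30)


def test_step_with_all_rates_zero_is_identity(params_copy):
    p = params_copy
    p.strata.bg_mortality[:] = 0
    p.strata.dm_mortality[:] = 0
    p.strata.dm_incidence[:] = 0
    p.cascade.p_dx = 0.0
    for c, prof in list(p.complications.items()):
        p.complications[c] = type(prof)(0.0, prof.therapy_effect)
    coh = make_homogeneous_cohort(10, p, cascade=cc.HealthState.HEALTHY)
    before = coh.cascade.copy()
    ev = step_cycle(coh, null_strategy(), p, 0)
    np.testing.assert_array_equal(coh.cascade, before)
    assert coh.alive.all()
    assert not ev.complication_events.any()


def test_certain_mortality_absorbs_everyone_in_one_cycle(params_copy):
    p = params_copy
    p.strata.bg_mortality[:] = 1.0
    coh = generate_population(200, (1, 2), p, seed=5)
    ev = step_cycle(coh, null_strategy(), p, 0)
    assert ev.died_other.all()
    assert not coh.alive.any()
    ev2 = step_cycle(coh, null_strategy(), p, 1)
    assert not ev2.alive_start.any()
    assert not ev2.screened.any() and not ev2.complication_events.any()


def test_complication_event_marginal_frequency(params_copy):
    # hyperglycaemia events among untreated diabetics occur at the printed
    # annual incidence once competing deaths are switched off
    p = params_copy
    p.strata.bg_mortality[:] = 0
    p.strata.dm_mortality[:] = 0
    n = 100_000
    coh = make_homogeneous_cohort(n, p, seed=5, cascade=cc.HealthState.UNDIAGNOSED)
    ev = step_cycle(coh, null_strategy(), p, 0)
    k = list(cc.COMPLICATION_STATES).index(cc.HealthState.HYPERGLYCAEMIA)
    frac = ev.complication_events[:, k].mean()
    assert frac == pytest.approx(0.18, abs=3 * np.sqrt(0.18 * 0.82 / n))


def test_common_random_numbers_pair_arms_exactly(params):
    coh = generate_population(3000, (1,), params, seed=21)
    base = cc.run_strategy(coh, null_strategy(), params)
    again = cc.run_strategy(coh, null_strategy(), params)
    np.testing.assert_array_equal(base.dalys, again.dalys)
    np.testing.assert_array_equal(base.hs_cost, again.hs_cost)


def test_death_is_absorbing_no_accrual_after_death(params_copy):
    p = params_copy
    p.strata.bg_mortality[:] = 1.0
    coh = generate_population(100, (1,), p, seed=6)
    res = cc.run_strategy(coh, null_strategy(), p)
    # dead from cycle 0: only the years-of-life-lost stream, no costs
    assert (res.hs_cost == 0).all()
    assert (res.oop_gross == 0).all()
    assert (res.death_cycle == 0).all()


def test_scalar_bundle_consistent_with_vectorized_cycle(params):
    # the scalar transition bundle and the vectorized step see the same rates
    ind = _individual(params, state=cc.HealthState.UNDIAGNOSED)
    bundle = build_transitions(ind, null_strategy(), params)
    assert bundle.p_other_death == params.strata.lookup("bg_mortality", 50, 0)
    assert bundle.p_dm_death == params.strata.lookup("dm_mortality", 50, 0, 1)
    assert bundle.p_initiate_treatment == params.cascade.p_dt


def test_monotonicity_stronger_effect_more_treated_years(params_copy):
    p_lo = params_copy.copy()
    p_lo.effect.odds_ratio = 1.12
    p_hi = params_copy.copy()
    p_hi.effect.odds_ratio = 1.54
    coh = generate_population(20_000, (1,), params_copy, seed=8)
    strat = cc.StrategyConfig(True, True, ALL_Q)
    lo = cc.run_strategy(coh, strat, p_lo)
    hi = cc.run_strategy(coh, strat, p_hi)
    assert hi.treated_years.sum() > lo.treated_years.sum()
    assert hi.diagnoses >= lo.diagnoses
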