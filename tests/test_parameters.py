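"""Parameter registry: config I/O, validation, synthetic strata calibration."""

import numpy as np
import pytest
import yaml

import cctecea as cc
from cctecea.parameters import (
    AGE_BANDS,
    CalibrationTargets,
    HealthState,
    StrataRateTable,
    _cohort_prevalence,
    load_parameters,
    save_parameters,
    synthesize_default_strata,
)

# Published point estimates the packaged default config must carry verbatim:
# state -> (direct medical cost, OOP cost, disability weight), and
# complication -> (untreated incidence, therapy effect).
STATE_TABLE = {
    "healthy": (0.0, 0.0, 0.0),
    "undiagnosed": (0.0, 0.0, 0.049),
    "diagnosed_untreated": (23.0, 13.0, 0.049),
    "oral_therapy": (185.0, 51.0, 0.049),
    "insulin_therapy": (277.0, 51.0, 0.049),
    "combination_therapy": (301.0, 51.0, 0.049),
    "nephropathy": (1207.0, 90.0, 1.0),
    "retinopathy": (56.0, 13.0, 0.184),
    "neuropathy": (6340.0, 13.0, 0.133),
    "angina": (16.0, 13.0, 0.080),
    "peripheral_vascular": (16.0, 13.0, 0.014),
    "myocardial_infarction": (1291.0, 90.0, 0.432),
    "stroke": (2168.0, 90.0, 0.588),
    "heart_failure": (2493.0, 90.0, 0.179),
    "hyperglycaemia": (83.0, 90.0, 0.133),
    "hypoglycaemia": (76.0, 90.0, 0.133),
    "diabetes_death": (0.0, 0.0, 1.0),
    "other_death": (0.0, 0.0, 1.0),
}
COMPLICATION_TABLE = {
    "nephropathy": (0.010, 0.30),
    "retinopathy": (0.021, 0.68),
    "neuropathy": (0.047, 0.94),
    "angina": (0.0067, 0.68),
    "peripheral_vascular": (0.0085, 0.74),
    "myocardial_infarction": (0.017, 0.61),
    "stroke": (0.0053, 0.59),
    "heart_failure": (0.0033, 0.68),
    "hyperglycaemia": (0.18, 1.0),
    "hypoglycaemia": (0.18, 0.68),
}
CASCADE_SPLIT = {
    "undiagnosed": 0.600,
    "diagnosed_untreated": 0.007,
    "oral_therapy": 0.196,
    "insulin_therapy": 0.036,
    "combination_therapy": 0.160,
}


@pytest.mark.parametrize("state,expected", sorted(STATE_TABLE.items()))
def test_default_state_economics_match_published_values(params, state, expected):
    e = params.state_economics[HealthState[state.upper()]]
    assert (e.direct_medical_cost, e.oop_cost, e.disability_weight) == expected


@pytest.mark.parametrize("comp,expected", sorted(COMPLICATION_TABLE.items()))
def test_default_complication_profiles_match_published_values(params, comp, expected):
    c = params.complications[HealthState[comp.upper()]]
    assert (c.untreated_incidence, c.therapy_effect) == expected


def test_default_economic_constants(params):
    econ = params.econ
    assert econ.ce_threshold == 3015.0
    assert econ.discount_rate == 0.05
    assert econ.che_thresholds == (0.10, 0.25, 0.40)
    assert econ.cct_diagnosis_amount == 13.0
    assert econ.cct_treatment_amount == 51.0
    assert econ.cct_transfers_per_year == 4
    assert params.horizon_years == 45
    assert params.effect.odds_ratio == 1.31
    assert (params.effect.ci_low, params.effect.ci_high) == (1.12, 1.54)


def test_cascade_split_printed_values_and_renormalization(params):
    split = {s.key: v for s, v in params.baseline_cascade_split.items()}
    assert split == CASCADE_SPLIT
    assert sum(CASCADE_SPLIT.values()) == pytest.approx(0.999)
    norm = params.cascade_split_normalized
    assert norm.sum() == pytest.approx(1.0)
    assert norm[0] == pytest.approx(0.600 / 0.999)


def test_partial_config_inherits_defaults(tmp_path, params):
    cfg = tmp_path / "override.yaml"
    cfg.write_text(yaml.safe_dump({"econ": {"discount_rate": 0.03}}))
    p = load_parameters(cfg)
    assert p.econ.discount_rate == 0.03
    # everything else defaulted, e.g. omitted CHE thresholds
    assert p.econ.che_thresholds == (0.10, 0.25, 0.40)
    assert p.econ.ce_threshold == 3015.0


@pytest.mark.parametrize("override,fragment", [
    ({"econ": {"discount_rate": -0.01}}, "discount_rate"),
    ({"cascade": {"p_dx": 1.5}}, "p_dx"),
    ({"econ": {"che_thresholds": [0.4, 0.25, 0.1]}}, "che_thresholds"),
    ({"complications": {"stroke": {"untreated_incidence": -0.1,
                                   "therapy_effect": 0.59}}}, "stroke"),
])
def test_invalid_values_raise_naming_the_key(tmp_path, override, fragment):
    cfg = tmp_path / "bad.yaml"
    cfg.write_text(yaml.safe_dump(override))
    with pytest.raises(cc.ValidationError, match=fragment):
        load_parameters(cfg)


def test_missing_required_key_raises_configuration_error(tmp_path):
    # a standalone (non-merged) config missing a required key names it
    cfg = tmp_path / "bad.yaml"
    cfg.write_text(yaml.safe_dump(
        {"states": {"stroke": {"direct_medical_cost": 2168.0, "oop_cost": 90.0}}}
    ))
    with pytest.raises(cc.ConfigurationError, match="disability_weight"):
        load_parameters(cfg, merge_defaults=False)


def test_round_trip_parameter_set(tmp_path, params):
    out = tmp_path / "params.yaml"
    save_parameters(params, out)
    again = load_parameters(out)
    assert again == params
    # and the round-trip is a fixed point
    out2 = tmp_path / "params2.yaml"
    save_parameters(again, out2)
    assert load_parameters(out2) == again


def test_strata_csv_round_trip(tmp_path, params):
    path = tmp_path / "strata.csv"
    params.strata.to_csv(path)
    again = StrataRateTable.from_csv(path)
    np.testing.assert_allclose(again.dm_incidence, params.strata.dm_incidence)
    np.testing.assert_allclose(again.bg_mortality, params.strata.bg_mortality)


def test_synthetic_strata_deterministic(params):
    a = synthesize_default_strata(0, params.calibration, params.strata_synthesis,
                                  params.population, params.cascade)
    b = synthesize_default_strata(0, params.calibration, params.strata_synthesis,
                                  params.population, params.cascade)
    assert a == b


def test_background_mortality_nondecreasing_in_age(params):
    bg = params.strata.bg_mortality
    assert (np.diff(bg, axis=0) >= 0).all()


def test_strata_calibration_hits_prevalence_targets(params):
    for q, target in params.calibration.prevalence_by_quintile.items():
        achieved = _cohort_prevalence(params.strata, params, q)
        assert achieved == pytest.approx(target, abs=1e-6)


def test_zero_prevalence_target_zeroes_incidence(params):
    cal = CalibrationTargets(prevalence_by_quintile={1: 0.0, 2: 0.184})
    table = synthesize_default_strata(0, cal, params.strata_synthesis,
                                      params.population, params.cascade)
    assert (table.dm_incidence[:, :, 0] == 0).all()
    assert (table.dm_incidence[:, :, 1] > 0).all()


def test_infeasible_calibration_reports_closest(params):
    cal = CalibrationTargets(prevalence_by_quintile={1: 0.99})
    with pytest.raises(cc.CalibrationError) as err:
        synthesize_default_strata(0, cal, params.strata_synthesis,
                                  params.population, params.cascade)
    assert err.value.closest is not None
    assert 0 < err.value.closest < 0.99


def test_female_incidence_exceeds_male(params):
    inc = params.strata.dm_incidence
    assert (inc[:, 0, :] > inc[:, 1, :]).all()
    ratio = inc[:, 0, 0] / inc[:, 1, 0]
    np.testing.assert_allclose(ratio, 1.3, rtol=1e-9)


def test_age_bands_cover_recruitment_window():
    assert AGE_BANDS[0] == (25, 29)
    assert AGE_BANDS[-1] == (65, 69)
    assert len(AGE_BANDS) == 9
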