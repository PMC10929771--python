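"""Toy scenarios and the deterministic cohort-recursion oracle.

Miniature parameter sets and cohorts whose outcomes are known analytically
(closed form) or computable by the expected-value recursion below, so every
stage of the pipeline is testable without external data. The recursion
mirrors the microsimulation's event hierarchy exactly and serves as the
independent check that the stochastic engine has the intended expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import (
    StrategyConfig,
    apply_odds_ratio,
    effective_nonadherence,
)
from .parameters import (
    HealthState,
    ParameterSet,
    StrataRateTable,
    default_parameters,
)
from .population import Cohort, generate_population

__all__ = ["ToyScenario", "make_toy", "TOY_NAMES", "cohort_recursion",
           "make_homogeneous_cohort", "RECURSION_STATES"]

TOY_NAMES = ("null_effect", "certain_death", "single_stratum",
             "full_protection", "deterministic_cascade")

#: State order of the recursion's occupancy vector.
RECURSION_STATES = (
    HealthState.HEALTHY, HealthState.UNDIAGNOSED,
    HealthState.DIAGNOSED_UNTREATED, HealthState.ORAL_THERAPY,
    HealthState.INSULIN_THERAPY, HealthState.COMBINATION_THERAPY,
    HealthState.DIABETES_DEATH, HealthState.OTHER_DEATH,
)


@dataclass
class ToyScenario:
    """A named scenario with parameters, a cohort factory and its expected
    analytic behaviour (described; asserted quantitatively by the tests)."""

    name: str
    description: str
    params: ParameterSet
    make_cohort: Callable[[int, int], Cohort]  # (n, seed) -> Cohort
    strategy: StrategyConfig
    params_arm: ParameterSet | None = None


def _zero_mortality(params: ParameterSet) -> None:
    params.strata.bg_mortality[:] = 0.0
    params.strata.dm_mortality[:] = 0.0


def make_homogeneous_cohort(n: int, params: ParameterSet, seed: int = 0, *,
                            age: int = 45, sex: int = 0, quintile: int = 1,
                            cascade: HealthState = HealthState.UNDIAGNOSED,
                            income: float | None = None) -> Cohort:
    """A single-stratum cohort: everyone shares age, sex, quintile, income
    and starting cascade state (the oracle-equivalence configuration)."""
    lo, hi = params.income.band(quintile)
    return Cohort(
        ids=np.arange(n, dtype=np.int64),
        age=np.full(n, age, dtype=np.int16),
        sex=np.full(n, sex, dtype=np.int8),
        quintile=np.full(n, quintile, dtype=np.int8),
        income=np.full(n, (lo + hi) / 2.0 if income is None else income),
        cascade=np.full(n, int(cascade), dtype=np.int8),
        alive=np.ones(n, dtype=bool),
        seed=int(seed),
        quintiles=(quintile,),
        scale_factor=params.econ.population_per_quintile / n,
    )


def make_toy(name: str) -> ToyScenario:
    """Build one of the named toy scenarios.

    null_effect
        Odds ratio 1 and transfer amounts 0: every arm is the no-programme
        arm, so all increments are exactly zero under common random numbers.
    certain_death
        Background mortality 1 everywhere: everyone dies in cycle 0 and
        accrues the full discounted years-of-life-lost sum, sum over t of
        (1 + r)^(-t).
    single_stratum
        Homogeneous cohort (one age/sex/quintile cell) for microsimulation
        versus cohort-recursion equivalence.
    full_protection
        Arm parameter set with all OOP costs zero: CHE cases averted equal
        the base run's total CHE cases.
    deterministic_cascade
        P_dx = P_dt = 1, P_tna = 0, no deaths or complications, oral therapy
        only: a single undiagnosed diabetic is diagnosed in cycle 0 (one
        diagnosis transfer in diagnosis-covering arms) and accrues a full
        treatment transfer each year on therapy in treatment-covering arms.
    """
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy {name!r}; expected one of {TOY_NAMES}")
    params = default_parameters()
    strategy = StrategyConfig(True, True, frozenset({1, 2}))
    params_arm = None

    if name == "null_effect":
        params.effect.odds_ratio = 1.0
        params.effect.ci_low = 1.0
        params.effect.ci_high = 1.0
        params.econ.cct_diagnosis_amount = 0.0
        params.econ.cct_treatment_amount = 0.0
        make = lambda n, seed: generate_population(n, (1, 2), params, seed)
        desc = "OR = 1 and zero transfers: all increments vanish"
    elif name == "certain_death":
        params.strata.bg_mortality[:] = 1.0
        make = lambda n, seed: generate_population(n, (1, 2), params, seed)
        desc = "everyone dies in cycle 0; DALYs pp = discounted horizon sum"
    elif name == "single_stratum":
        make = lambda n, seed: make_homogeneous_cohort(n, params, seed)
        desc = "homogeneous stratum for recursion equivalence"
    elif name == "full_protection":
        params_arm = params.copy()
        for s, e in list(params_arm.state_economics.items()):
            params_arm.state_economics[s] = type(e)(
                e.direct_medical_cost, 0.0, e.disability_weight
            )
        make = lambda n, seed: generate_population(n, (1, 2), params, seed)
        desc = "arm OOP forced to zero: averted CHE equals base CHE"
    else:  # deterministic_cascade
        params.cascade.p_dx = 1.0
        params.cascade.p_dt = 1.0
        params.cascade.p_tna = 0.0
        _zero_mortality(params)
        for c, prof in list(params.complications.items()):
            params.complications[c] = type(prof)(0.0, prof.therapy_effect)
        params.baseline_cascade_split = {
            HealthState.UNDIAGNOSED: 1.0,
            HealthState.DIAGNOSED_UNTREATED: 0.0,
            HealthState.ORAL_THERAPY: 1.0,  # therapy split: oral only
            HealthState.INSULIN_THERAPY: 0.0,
            HealthState.COMBINATION_THERAPY: 0.0,
        }
        make = lambda n, seed: make_homogeneous_cohort(
            n, params, seed, age=40, cascade=HealthState.UNDIAGNOSED
        )
        desc = ("all-or-nothing cascade: diagnosis in cycle 0, oral therapy "
                "for the rest of the horizon")

    return ToyScenario(name=name, description=desc, params=params,
                       make_cohort=make, strategy=strategy,
                       params_arm=params_arm)


def cohort_recursion(params: ParameterSet, strategy: StrategyConfig, *,
                     age0: int, sex: int, quintile: int,
                     x0: np.ndarray | None = None,
                     horizon: int | None = None) -> np.ndarray:
    """Deterministic expected-value recursion for a homogeneous stratum.

    Propagates occupancy fractions over the eight non-transient states (see
    ``RECURSION_STATES``) through exactly the same hierarchical event order
    as the microsimulation. Returns an array of shape (horizon, 8): the
    expected end-of-cycle occupancy for each cycle.
    """
    horizon = params.horizon_years if horizon is None else horizon
    cascade = params.cascade
    effect = params.effect
    eligible = quintile in strategy.eligible_quintiles
    mult = cascade.treated_mortality_multiplier
    split = params.therapy_split

    p_dx = cascade.p_dx
    if strategy.covers_diagnosis and eligible:
        p_dx = apply_odds_ratio(p_dx, effect.or_for("diagnosis"))
    p_tna = cascade.p_tna
    if strategy.covers_treatment and eligible:
        p_tna = effective_nonadherence(
            cascade.p_tna, effect.or_for("treatment"), cascade.adherence_effect_mode
        )

    if x0 is None:
        x0 = np.zeros(len(RECURSION_STATES))
        x0[RECURSION_STATES.index(HealthState.UNDIAGNOSED)] = 1.0
    h, u, du, o, i_, c, dd, do = (float(v) for v in x0)

    out = np.zeros((horizon, len(RECURSION_STATES)))
    strata = params.strata
    for t in range(horizon):
        age = age0 + t
        bg = float(strata.lookup("bg_mortality", age, sex))
        dmm = float(strata.lookup("dm_mortality", age, sex, quintile))
        inc = float(strata.lookup("dm_incidence", age, sex, quintile))

        # deaths (other-cause first, then diabetes among survivors)
        do += (h + u + du + o + i_ + c) * bg
        h1, u1, du1 = h * (1 - bg), u * (1 - bg), du * (1 - bg)
        o1, i1, c1 = o * (1 - bg), i_ * (1 - bg), c * (1 - bg)
        dd += (u1 + du1) * dmm + (o1 + i1 + c1) * dmm * mult
        u1 *= 1 - dmm
        du1 *= 1 - dmm
        o1 *= 1 - dmm * mult
        i1 *= 1 - dmm * mult
        c1 *= 1 - dmm * mult

        # onset, then screening/diagnosis
        flow_on = h1 * inc
        h1 -= flow_on
        u1 += flow_on
        dx = u1 * p_dx
        u1 -= dx

        # initiation (newly diagnosed; dropouts retry only with re-initiation)
        reinit = du1 * cascade.p_dt if cascade.allow_reinitiation else 0.0
        init = dx * cascade.p_dt + reinit
        du1 = du1 - reinit + dx * (1 - cascade.p_dt)

        # non-adherence applies to the start-of-cycle treated stock
        drop = (o1 + i1 + c1) * p_tna
        o1, i1, c1 = o1 * (1 - p_tna), i1 * (1 - p_tna), c1 * (1 - p_tna)
        du1 += drop
        o1 += init * split[0]
        i1 += init * split[1]
        c1 += init * split[2]

        h, u, du, o, i_, c = h1, u1, du1, o1, i1, c1
        out[t] = (h, u, du, o, i_, c, dd, do)
    return out
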