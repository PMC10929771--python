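"""Annual-cycle Markov microsimulation engine.

Advances the cohort through one-year cycles over the 45-year horizon. Within
a cycle events resolve hierarchically, earlier events pre-empting later ones:

    other-cause death -> diabetes death -> diabetes onset -> screening /
    diagnosis -> treatment initiation -> non-adherence -> complication draw

Complication states are transient: the person occupies the complication state
for the cycle (for costing and disability) and returns to their care-cascade
state the next cycle. Strategy arms are compared under common random numbers:
every random slot is drawn for every individual in every cycle from streams
keyed by (cohort seed, cycle), independent of the strategy, so paired arms
see identical randomness and incremental outcomes difference out shared
Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import accounting
from .parameters import (
    COMPLICATION_STATES,
    HealthState,
    ParameterSet,
    TREATED_STATES,
)
from .population import Cohort, Individual, generate_population

__all__ = [
    "StrategyConfig",
    "STRATEGY_NAMES",
    "study_strategies",
    "TransitionBundle",
    "CycleEvents",
    "RunResult",
    "apply_odds_ratio",
    "effective_nonadherence",
    "build_transitions",
    "step_cycle",
    "run_strategy",
    "run_study",
]

_CASC_H = int(HealthState.HEALTHY)
_CASC_U = int(HealthState.UNDIAGNOSED)
_CASC_DU = int(HealthState.DIAGNOSED_UNTREATED)
_TREATED_CODES = tuple(int(s) for s in TREATED_STATES)
_COMP_OFFSET = int(HealthState.NEPHROPATHY)
#: Stream tag separating cycle streams from the population-generation stream.
_CYCLE_STREAM = 7919

STRATEGY_NAMES = ("none", "diagnosis", "treatment", "diagnosis_treatment")


@dataclass(frozen=True)
class StrategyConfig:
    """Which services the CCT covers and which income quintiles are eligible."""

    covers_diagnosis: bool
    covers_treatment: bool
    eligible_quintiles: frozenset[int] = frozenset({1, 2})

    def __post_init__(self):
        if any(q < 1 or q > 5 for q in self.eligible_quintiles):
            raise ValueError("eligible_quintiles must be within 1..5")

    @property
    def name(self) -> str:
        if self.covers_diagnosis and self.covers_treatment:
            return "diagnosis_treatment"
        if self.covers_diagnosis:
            return "diagnosis"
        if self.covers_treatment:
            return "treatment"
        return "none"

    def eligible_mask(self, quintile: np.ndarray) -> np.ndarray:
        if not (self.covers_diagnosis or self.covers_treatment):
            return np.zeros(len(quintile), dtype=bool)
        return np.isin(quintile, list(self.eligible_quintiles))


def study_strategies(eligible_quintiles=(1, 2)) -> dict[str, StrategyConfig]:
    """The four study arms for one eligibility scenario."""
    elig = frozenset(int(q) for q in eligible_quintiles)
    return {
        "none": StrategyConfig(False, False, elig),
        "diagnosis": StrategyConfig(True, False, elig),
        "treatment": StrategyConfig(False, True, elig),
        "diagnosis_treatment": StrategyConfig(True, True, elig),
    }


def apply_odds_ratio(p, or_value):
    """Apply an odds ratio to a probability: (p*OR) / (1 - p + p*OR).

    Monotone increasing in OR; maps [0, 1] to [0, 1]; identity at OR = 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probability outside [0, 1]")
    if np.any(np.asarray(or_value) <= 0):
        raise ValueError("odds ratio must be > 0")
    out = (p * or_value) / (1.0 - p + p * or_value)
    return float(out) if out.ndim == 0 else out


def effective_nonadherence(p_tna: float, or_value: float, mode: str = "odds") -> float:
    """Non-adherence probability under a CCT covering treatment services.

    'odds' mode applies the odds ratio to the adherence probability
    (1 - p_tna) on the odds scale, respecting the effect's semantics of
    improving the likelihood of remaining in treatment; 'direct' divides
    p_tna by the odds ratio.
    """
    if mode == "odds":
        return 1.0 - apply_odds_ratio(1.0 - p_tna, or_value)
    if mode == "direct":
        return min(p_tna / or_value, 1.0)
    raise ValueError(f"unknown adherence effect mode {mode!r}")


@dataclass
class TransitionBundle:
    """Per-individual annual transition probabilities for one cycle."""

    p_other_death: float
    p_dm_death: float
    p_dm_incidence: float
    p_diagnosis: float
    p_initiate_treatment: float
    p_nonadherence: float
    complication_probs: np.ndarray  # fixed complication order

    def validate(self) -> None:
        vals = [self.p_other_death, self.p_dm_death, self.p_dm_incidence,
                self.p_diagnosis, self.p_initiate_treatment,
                self.p_nonadherence, *self.complication_probs]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("transition probability outside [0, 1]")


def build_transitions(ind: Individual, strategy: StrategyConfig,
                      params: ParameterSet) -> TransitionBundle:
    """Transition probabilities for one individual under one strategy arm.

    The CCT boosts the diagnosis probability (odds scale) when the arm covers
    diagnosis services and the individual's quintile is eligible, and lowers
    non-adherence when the arm covers treatment services; complication risks
    carry the therapy-effect multiplier while on pharmacological treatment.
    """
    if not ind.alive:
        raise ValueError("build_transitions requires a living individual")
    sex_idx = 0 if ind.sex == "female" else 1
    strata = params.strata
    try:
        bg = float(strata.lookup("bg_mortality", ind.age, sex_idx))
        dm_mort = float(strata.lookup("dm_mortality", ind.age, sex_idx, ind.quintile))
        dm_inc = float(strata.lookup("dm_incidence", ind.age, sex_idx, ind.quintile))
    except IndexError as exc:
        raise KeyError(
            f"missing strata cell (age={ind.age}, sex={ind.sex}, "
            f"quintile={ind.quintile})"
        ) from exc

    eligible = ind.quintile in strategy.eligible_quintiles
    cascade = params.cascade
    effect = params.effect

    p_dx = cascade.p_dx
    if strategy.covers_diagnosis and eligible:
        p_dx = apply_odds_ratio(p_dx, effect.or_for("diagnosis"))

    p_tna = cascade.p_tna
    if strategy.covers_treatment and eligible:
        p_tna = effective_nonadherence(
            cascade.p_tna, effect.or_for("treatment"), cascade.adherence_effect_mode
        )

    on_therapy = ind.state in TREATED_STATES
    inc, eff = params.complication_vectors()
    comp = inc * (eff if on_therapy else 1.0)
    diabetic = ind.state != HealthState.HEALTHY

    bundle = TransitionBundle(
        p_other_death=bg,
        p_dm_death=(dm_mort * (cascade.treated_mortality_multiplier if on_therapy else 1.0)
                    if diabetic else 0.0),
        p_dm_incidence=dm_inc if not diabetic else 0.0,
        p_diagnosis=p_dx,
        p_initiate_treatment=cascade.p_dt,
        p_nonadherence=p_tna,
        complication_probs=comp,
    )
    bundle.validate()
    return bundle


@dataclass
class CycleEvents:
    """Everything that happened to the cohort in one cycle, for accounting."""

    cycle: int
    alive_start: np.ndarray
    died_other: np.ndarray
    died_diabetes: np.ndarray
    alive_end: np.ndarray
    onset: np.ndarray
    screened: np.ndarray          # screening/diagnosis service attendance
    diagnosed: np.ndarray         # undiagnosed diabetic diagnosed this cycle
    initiated: np.ndarray
    dropped: np.ndarray           # left treatment this cycle
    treated_cycle: np.ndarray     # occupies a treated cascade state this cycle
    complication_events: np.ndarray  # (n, n_complications) independent draws
    occupied_state: np.ndarray    # HealthState codes occupied this cycle


def _cycle_rng(seed: int, cycle: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _CYCLE_STREAM, int(cycle)]))


def step_cycle(cohort: Cohort, strategy: StrategyConfig, params: ParameterSet,
               cycle: int, rng: np.random.Generator | None = None) -> CycleEvents:
    """Advance the cohort by one cycle in place and report the cycle's events.

    ``rng`` defaults to the common-random-number stream keyed by
    (cohort.seed, cycle); passing the same cohort and cycle under different
    strategies consumes identical draws in identical order.
    """
    if rng is None:
        rng = _cycle_rng(cohort.seed, cycle)
    n = cohort.n
    casc = cohort.cascade
    alive_start = cohort.alive.copy()

    # fixed draw-slot order (identical across arms)
    u_od = rng.random(n)
    u_dd = rng.random(n)
    u_on = rng.random(n)
    u_dx = rng.random(n)
    u_in = rng.random(n)
    u_th = rng.random(n)
    u_na = rng.random(n)
    u_cx = rng.random((n, len(COMPLICATION_STATES)))

    sex = cohort.sex
    q = cohort.quintile
    strata = params.strata
    bg = strata.lookup("bg_mortality", cohort.age, sex)
    dm_mort = strata.lookup("dm_mortality", cohort.age, sex, q)
    dm_inc = strata.lookup("dm_incidence", cohort.age, sex, q)

    cascade = params.cascade
    effect = params.effect
    eligible = strategy.eligible_mask(q)

    treated_pre = alive_start & np.isin(casc, _TREATED_CODES)
    diabetic_pre = alive_start & (casc != _CASC_H)

    # 1-2. deaths
    died_other = alive_start & (u_od < bg)
    mort = dm_mort * np.where(treated_pre, cascade.treated_mortality_multiplier, 1.0)
    died_dm = alive_start & ~died_other & diabetic_pre & (u_dd < mort)
    alive = alive_start & ~died_other & ~died_dm

    # 3. diabetes onset
    onset = alive & (casc == _CASC_H) & (u_on < dm_inc)
    casc[onset] = _CASC_U

    # 4. screening attendance / diagnosis
    p_dx_base = cascade.p_dx
    if strategy.covers_diagnosis:
        p_dx_boost = apply_odds_ratio(p_dx_base, effect.or_for("diagnosis"))
        p_dx_i = np.where(eligible, p_dx_boost, p_dx_base)
    else:
        p_dx_i = np.full(n, p_dx_base)
    undiagnosed = alive & ((casc == _CASC_H) | (casc == _CASC_U))
    screened = undiagnosed & (u_dx < p_dx_i)
    diagnosed = screened & (casc == _CASC_U)

    # 5. treatment initiation (newly diagnosed; dropouts/decliners only if
    # re-initiation is enabled)
    candidates = diagnosed.copy()
    if cascade.allow_reinitiation:
        candidates |= alive & (casc == _CASC_DU)
    initiated = candidates & (u_in < cascade.p_dt)
    casc[diagnosed & ~initiated] = _CASC_DU
    split = params.therapy_split
    cuts = np.cumsum(split)
    therapy_idx = np.searchsorted(cuts, u_th[initiated], side="right")
    therapy_idx = np.minimum(therapy_idx, 2)
    casc[initiated] = np.array(_TREATED_CODES, dtype=casc.dtype)[therapy_idx]

    # 6. non-adherence (people treated at cycle start; the newly initiated
    # complete their first treatment-year)
    p_tna_base = cascade.p_tna
    if strategy.covers_treatment:
        p_tna_boost = effective_nonadherence(
            p_tna_base, effect.or_for("treatment"), cascade.adherence_effect_mode
        )
        p_tna_i = np.where(eligible, p_tna_boost, p_tna_base)
    else:
        p_tna_i = np.full(n, p_tna_base)
    dropped = treated_pre & alive & (u_na < p_tna_i)
    casc[dropped] = _CASC_DU

    # 7. complication draws (independent per complication; occupancy goes to
    # the first that fires, in the fixed table order)
    diabetic_now = alive & (casc != _CASC_H)
    on_therapy = alive & np.isin(casc, _TREATED_CODES)
    inc_c, eff_c = params.complication_vectors()
    probs = inc_c[None, :] * np.where(on_therapy[:, None], eff_c[None, :], 1.0)
    comp_events = diabetic_now[:, None] & (u_cx < probs)
    any_comp = comp_events.any(axis=1)
    first_comp = np.argmax(comp_events, axis=1)

    occupied = casc.astype(np.int16).copy()
    occupied[any_comp] = (_COMP_OFFSET + first_comp[any_comp]).astype(np.int16)
    occupied[died_dm] = int(HealthState.DIABETES_DEATH)
    occupied[died_other] = int(HealthState.OTHER_DEATH)

    cohort.alive = alive
    cohort.age = cohort.age + 1

    return CycleEvents(
        cycle=cycle,
        alive_start=alive_start,
        died_other=died_other,
        died_diabetes=died_dm,
        alive_end=alive,
        onset=onset,
        screened=screened,
        diagnosed=diagnosed,
        initiated=initiated,
        dropped=dropped,
        treated_cycle=alive & np.isin(casc, _TREATED_CODES),
        complication_events=comp_events,
        occupied_state=occupied,
    )


@dataclass
class RunResult:
    """Per-strategy run output: per-individual discounted ledgers plus the
    cohort descriptors needed for subgroup disaggregation and pairing."""

    strategy: StrategyConfig
    n: int
    seed: int
    quintiles: tuple[int, ...]
    scale_factor: float
    horizon: int
    sex: np.ndarray
    quintile: np.ndarray
    income: np.ndarray
    hs_cost: np.ndarray        # discounted health-system cost per person
    oop_gross: np.ndarray      # discounted OOP before transfers
    oop_net: np.ndarray        # discounted OOP net of transfers received
    cct: np.ndarray            # discounted transfers received
    dalys: np.ndarray
    treated_years: np.ndarray  # discounted person-years in treated states
    che_years: np.ndarray      # (n, n_thresholds) person-years in CHE
    che_ever: np.ndarray       # (n, n_thresholds) ever-in-CHE flags
    death_cycle: np.ndarray    # -1 if alive at horizon end
    screening_visits: int
    diagnoses: int
    complication_counts: np.ndarray  # totals per complication

    def comparable_with(self, other: "RunResult") -> bool:
        return (self.n == other.n and self.seed == other.seed
                and self.quintiles == other.quintiles
                and self.scale_factor == other.scale_factor
                and self.horizon == other.horizon)


def run_strategy(cohort: Cohort, strategy: StrategyConfig,
                 params: ParameterSet) -> RunResult:
    """Run one strategy arm over the full horizon on a copy of the cohort.

    The input cohort is not mutated, so the same cohort object can be passed
    to every arm; common random numbers make the arms' randomness identical.
    """
    state = cohort.copy()
    ledger = accounting.Ledger.zeros(state.n, len(params.econ.che_thresholds))
    death_cycle = np.full(state.n, -1, dtype=np.int16)
    screening_visits = 0
    diagnoses = 0
    comp_counts = np.zeros(len(COMPLICATION_STATES), dtype=np.int64)

    for cycle in range(params.horizon_years):
        events = step_cycle(state, strategy, params, cycle)
        accounting.accrue_cycle(ledger, state, events, strategy, params, cycle)
        newly_dead = events.died_other | events.died_diabetes
        death_cycle[newly_dead] = cycle
        screening_visits += int(events.screened.sum())
        diagnoses += int(events.diagnosed.sum())
        comp_counts += events.complication_events.sum(axis=0)

    return RunResult(
        strategy=strategy,
        n=cohort.n,
        seed=cohort.seed,
        quintiles=cohort.quintiles,
        scale_factor=cohort.scale_factor,
        horizon=params.horizon_years,
        sex=cohort.sex.copy(),
        quintile=cohort.quintile.copy(),
        income=cohort.income.copy(),
        hs_cost=ledger.hs_cost,
        oop_gross=ledger.oop_gross,
        oop_net=ledger.oop_net,
        cct=ledger.cct,
        dalys=ledger.dalys,
        treated_years=ledger.treated_years,
        che_years=ledger.che_years,
        che_ever=ledger.che_ever,
        death_cycle=death_cycle,
        screening_visits=screening_visits,
        diagnoses=diagnoses,
        complication_counts=comp_counts,
    )


def run_study(n: int, quintiles, params: ParameterSet, seed: int,
              arms: dict[str, StrategyConfig] | None = None,
              cohort: Cohort | None = None,
              ) -> tuple[RunResult, dict[str, RunResult]]:
    """Generate one cohort and run the no-programme arm plus each CCT arm on
    it under common random numbers. Returns (base_result, {name: result})."""
    if cohort is None:
        cohort = generate_population(n, quintiles, params, seed)
    if arms is None:
        arms = {k: v for k, v in study_strategies(quintiles).items() if k != "none"}
    base = run_strategy(cohort, StrategyConfig(False, False, frozenset(quintiles)), params)
    results = {name: run_strategy(cohort, strat, params)
               for name, strat in arms.items() if strat.name != "none"}
    return base, results
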