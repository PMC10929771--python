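"""Model parameter registry.

Houses every parameter of the diabetes care-cascade microsimulation: the
health-state economics (annual direct medical cost, out-of-pocket cost and
disability weight per state), complication incidence and therapy effects,
care-cascade utilization probabilities, economic constants, the conditional
cash transfer (CCT) effect size, the income model, and the synthetic
age/sex/quintile rate tables that stand in for survey-derived inputs.

Parameters are read from / written to a flat YAML config; a packaged default
(``params_default.yaml``) encodes the published point estimates, with
documented placeholder defaults for quantities only available in unpublished
supplementary material (income gamma parameters, food poverty line, baseline
utilization probabilities, strata rate curves).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "HealthState",
    "CASCADE_STATES",
    "TREATED_STATES",
    "COMPLICATION_STATES",
    "DEATH_STATES",
    "StateEconomics",
    "ComplicationProfile",
    "CascadeRates",
    "EconomicConstants",
    "InterventionEffect",
    "IncomeModel",
    "StrataRateTable",
    "CalibrationTargets",
    "PopulationConfig",
    "StrataSynthesisConfig",
    "PsaConfig",
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "CalibrationError",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "default_config_dict",
    "synthesize_default_strata",
    "baseline_prevalence_curve",
    "AGE_BANDS",
]


class ConfigurationError(ValueError):
    """A required configuration key is missing or unparsable."""


class ValidationError(ValueError):
    """A parameter value violates its invariant."""


class CalibrationError(RuntimeError):
    """Strata calibration could not reach its target within bounds."""

    def __init__(self, message: str, closest: float | None = None):
        super().__init__(message)
        self.closest = closest


class HealthState(IntEnum):
    """States of the annual-cycle Markov model.

    The first six form the care cascade (occupied year over year); the ten
    complication states are transient, occupied for exactly one cycle; the
    two death states are absorbing.
    """

    HEALTHY = 0
    UNDIAGNOSED = 1
    DIAGNOSED_UNTREATED = 2
    ORAL_THERAPY = 3
    INSULIN_THERAPY = 4
    COMBINATION_THERAPY = 5
    NEPHROPATHY = 6
    RETINOPATHY = 7
    NEUROPATHY = 8
    ANGINA = 9
    PERIPHERAL_VASCULAR = 10
    MYOCARDIAL_INFARCTION = 11
    STROKE = 12
    HEART_FAILURE = 13
    HYPERGLYCAEMIA = 14
    HYPOGLYCAEMIA = 15
    DIABETES_DEATH = 16
    OTHER_DEATH = 17

    @property
    def key(self) -> str:
        return self.name.lower()


CASCADE_STATES = tuple(HealthState(i) for i in range(6))
TREATED_STATES = (
    HealthState.ORAL_THERAPY,
    HealthState.INSULIN_THERAPY,
    HealthState.COMBINATION_THERAPY,
)
#: Fixed resolution order for complication draws (first drawn wins occupancy).
COMPLICATION_STATES = tuple(HealthState(i) for i in range(6, 16))
DEATH_STATES = (HealthState.DIABETES_DEATH, HealthState.OTHER_DEATH)

#: Five-year age bands covering the recruitment window 25-69.
AGE_BANDS = tuple((lo, lo + 4) for lo in range(25, 70, 5))


def age_band_index(age) -> np.ndarray:
    """Band index for an age (held at the top band past 69)."""
    return np.clip((np.asarray(age) - 25) // 5, 0, len(AGE_BANDS) - 1).astype(int)


@dataclass(frozen=True)
class StateEconomics:
    """Annual USD-2020 costs and disability weight for one health state."""

    direct_medical_cost: float
    oop_cost: float
    disability_weight: float

    def validate(self, key: str) -> None:
        if self.direct_medical_cost < 0 or self.oop_cost < 0:
            raise ValidationError(f"states.{key}: costs must be >= 0")
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValidationError(
                f"states.{key}.disability_weight={self.disability_weight} outside [0, 1]"
            )


@dataclass(frozen=True)
class ComplicationProfile:
    """Annual complication risk for untreated diabetics and the therapy effect.

    ``therapy_effect`` is a multiplicative risk ratio applied while the person
    is on any pharmacological therapy, so treated incidence =
    ``untreated_incidence * therapy_effect``.
    """

    untreated_incidence: float
    therapy_effect: float

    def validate(self, key: str) -> None:
        if not 0.0 <= self.untreated_incidence <= 1.0:
            raise ValidationError(
                f"complications.{key}.untreated_incidence outside [0, 1]"
            )
        if not 0.0 < self.therapy_effect <= 1.0:
            raise ValidationError(
                f"complications.{key}.therapy_effect outside (0, 1]"
            )


@dataclass
class CascadeRates:
    """Baseline care-cascade utilization probabilities.

    p_dx
        Annual probability an undiagnosed diabetic attends screening and is
        diagnosed.
    p_dt
        Probability a newly diagnosed person initiates pharmacological therapy.
    p_tna
        Annual probability a treated person becomes non-adherent and leaves
        treatment.
    allow_reinitiation
        Whether untreated diagnosed people (decliners and dropouts) retry
        initiation each cycle at ``p_dt``. Default off: one treatment spell per
        diagnosis, reflecting the adherence-limited cascade.
    adherence_effect_mode
        'odds': the CCT odds ratio is applied to adherence (1 - p_tna) on the
        odds scale; 'direct': p_tna is divided by the odds ratio.
    treated_mortality_multiplier
        Risk ratio on stratum diabetes mortality while on therapy.
    """

    p_dx: float = 0.08
    p_dt: float = 0.30
    p_tna: float = 0.25
    allow_reinitiation: bool = False
    adherence_effect_mode: str = "odds"
    treated_mortality_multiplier: float = 0.25

    def validate(self) -> None:
        for key in ("p_dx", "p_dt", "p_tna"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"cascade.{key}={v} outside [0, 1]")
        if self.adherence_effect_mode not in ("odds", "direct"):
            raise ValidationError(
                "cascade.adherence_effect_mode must be 'odds' or 'direct'"
            )
        if not 0.0 < self.treated_mortality_multiplier <= 1.0:
            raise ValidationError(
                "cascade.treated_mortality_multiplier outside (0, 1]"
            )


@dataclass
class EconomicConstants:
    """Economic constants and disbursement rules."""

    discount_rate: float = 0.05
    ce_threshold: float = 3015.0
    che_thresholds: tuple[float, ...] = (0.10, 0.25, 0.40)
    food_poverty_line: float = 120.0
    cct_diagnosis_amount: float = 13.0
    cct_treatment_amount: float = 51.0
    cct_transfers_per_year: int = 4
    admin_cost_fraction: float = 0.0
    population_per_quintile: float = 6.0e6
    screening_cct: bool = True
    discount_dalys: bool = True
    che_net_of_cct: bool = True
    che_unit: str = "person_year"

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ValidationError(f"econ.discount_rate={self.discount_rate} must be >= 0")
        if self.ce_threshold <= 0:
            raise ValidationError("econ.ce_threshold must be > 0")
        thr = tuple(self.che_thresholds)
        if not thr or any(not 0.0 < t < 1.0 for t in thr) or list(thr) != sorted(set(thr)):
            raise ValidationError(
                "econ.che_thresholds must be strictly increasing fractions in (0, 1)"
            )
        for key in ("food_poverty_line", "cct_diagnosis_amount", "cct_treatment_amount"):
            if getattr(self, key) < 0:
                raise ValidationError(f"econ.{key} must be >= 0")
        if self.admin_cost_fraction < 0:
            raise ValidationError("econ.admin_cost_fraction must be >= 0")
        if self.population_per_quintile <= 0:
            raise ValidationError("econ.population_per_quintile must be > 0")
        if self.che_unit not in ("person_year", "person_ever"):
            raise ValidationError("econ.che_unit must be 'person_year' or 'person_ever'")


@dataclass
class InterventionEffect:
    """CCT effect on service utilization, as an odds ratio with its 95% CI.

    The same odds ratio applies to the diagnosis and treatment channels unless
    a channel-specific override (``or_diagnosis`` / ``or_treatment``) is set,
    as in the one-way sensitivity analyses.
    """

    odds_ratio: float = 1.31
    ci_low: float = 1.12
    ci_high: float = 1.54
    or_diagnosis: float | None = None
    or_treatment: float | None = None

    def or_for(self, channel: str) -> float:
        if channel == "diagnosis":
            return self.odds_ratio if self.or_diagnosis is None else self.or_diagnosis
        if channel == "treatment":
            return self.odds_ratio if self.or_treatment is None else self.or_treatment
        raise ValueError(f"unknown effect channel {channel!r}")

    def validate(self) -> None:
        if self.odds_ratio <= 0:
            raise ValidationError("effect.odds_ratio must be > 0")
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValidationError("effect: ci_low <= odds_ratio <= ci_high required")
        for key in ("or_diagnosis", "or_treatment"):
            v = getattr(self, key)
            if v is not None and v <= 0:
                raise ValidationError(f"effect.{key} must be > 0")


@dataclass
class IncomeModel:
    """Per-quintile gamma income model truncated to the quintile band.

    Each quintile q draws from Gamma(shape, scale_q) rejected to the band
    [boundaries[q-1], boundaries[q]]; scales default so the untruncated mean
    sits at the band midpoint.
    """

    quintile_boundaries: tuple[float, ...] = (120.0, 480.0, 960.0, 1800.0, 3600.0, 14400.0)
    gamma_shape: float = 2.0
    gamma_scales: tuple[float, ...] | None = None

    def band(self, quintile: int) -> tuple[float, float]:
        if not 1 <= quintile <= 5:
            raise ValueError(f"quintile {quintile} outside 1..5")
        b = self.quintile_boundaries
        return b[quintile - 1], b[quintile]

    def scale(self, quintile: int) -> float:
        if self.gamma_scales is not None:
            return self.gamma_scales[quintile - 1]
        lo, hi = self.band(quintile)
        return (lo + hi) / 2.0 / self.gamma_shape

    def validate(self) -> None:
        b = list(self.quintile_boundaries)
        if len(b) != 6 or b != sorted(b) or len(set(b)) != 6 or b[0] < 0:
            raise ValidationError(
                "income.quintile_boundaries must be 6 strictly increasing non-negative values"
            )
        if self.gamma_shape <= 0:
            raise ValidationError("income.gamma_shape must be > 0")


@dataclass
class PopulationConfig:
    """Demographic structure of the simulated eligible population."""

    female_share: float = 0.5
    female_incidence_ratio: float = 1.3
    age_min: int = 25
    age_max: int = 69
    #: Optional relative weights per 5-year band (default uniform).
    age_pyramid: tuple[float, ...] | None = None

    def validate(self) -> None:
        if not 0.0 <= self.female_share <= 1.0:
            raise ValidationError("population.female_share outside [0, 1]")
        if self.female_incidence_ratio <= 0:
            raise ValidationError("population.female_incidence_ratio must be > 0")
        if not (25 <= self.age_min <= self.age_max <= 69):
            raise ValidationError("population ages must satisfy 25 <= age_min <= age_max <= 69")
        if self.age_pyramid is not None:
            w = np.asarray(self.age_pyramid, dtype=float)
            if len(w) != len(AGE_BANDS) or (w < 0).any() or w.sum() <= 0:
                raise ValidationError(
                    "population.age_pyramid needs one non-negative weight per 5-year band"
                )


@dataclass
class StrataSynthesisConfig:
    """Smooth exponential-in-age curves behind the synthetic rate tables."""

    seed: int = 0
    dm_incidence_base: float = 0.006
    dm_incidence_slope: float = 0.05
    dm_mortality_base: float = 0.016
    dm_mortality_slope: float = 0.055
    bg_mortality_base: float = 0.0025
    bg_mortality_slope: float = 0.068

    def validate(self) -> None:
        for key in ("dm_incidence_base", "dm_mortality_base", "bg_mortality_base"):
            if getattr(self, key) < 0:
                raise ValidationError(f"strata.synthesize.{key} must be >= 0")


@dataclass
class CalibrationTargets:
    """Printed anchors the synthetic strata tables are calibrated to."""

    prevalence_by_quintile: dict[int, float] = field(
        default_factory=lambda: {1: 0.175, 2: 0.184, 3: 0.195, 4: 0.205, 5: 0.215}
    )
    diagnosed_fraction: float = 0.40
    tolerance: float = 0.015

    def validate(self) -> None:
        for q, p in self.prevalence_by_quintile.items():
            if not 1 <= int(q) <= 5:
                raise ValidationError(f"calibration quintile {q} outside 1..5")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"calibration.prevalence_by_quintile[{q}] outside [0, 1]")
        if not 0.0 <= self.diagnosed_fraction <= 1.0:
            raise ValidationError("calibration.diagnosed_fraction outside [0, 1]")


@dataclass
class PsaConfig:
    """Default uncertainty magnitudes for probabilistic sensitivity analysis."""

    cost_cv: float = 0.2
    probability_cv: float = 0.2

    def validate(self) -> None:
        if self.cost_cv < 0 or self.probability_cv < 0:
            raise ValidationError("psa coefficients of variation must be >= 0")


class StrataRateTable:
    """Age/sex/quintile rate tables for diabetes incidence, diabetes mortality
    and other-cause (background) mortality.

    Internally dense numpy arrays indexed [band, sex, quintile-1] (incidence,
    diabetes mortality) and [band, sex] (background mortality), with sex coded
    0 = female, 1 = male. Ages beyond 69 use the top band.
    """

    SEX_LABELS = ("female", "male")

    def __init__(self, dm_incidence: np.ndarray, dm_mortality: np.ndarray,
                 bg_mortality: np.ndarray):
        self.dm_incidence = np.asarray(dm_incidence, dtype=float)
        self.dm_mortality = np.asarray(dm_mortality, dtype=float)
        self.bg_mortality = np.asarray(bg_mortality, dtype=float)
        self.validate()

    def validate(self) -> None:
        nb = len(AGE_BANDS)
        if self.dm_incidence.shape != (nb, 2, 5):
            raise ValidationError(f"strata dm_incidence shape {self.dm_incidence.shape} != {(nb, 2, 5)}")
        if self.dm_mortality.shape != (nb, 2, 5):
            raise ValidationError(f"strata dm_mortality shape {self.dm_mortality.shape} != {(nb, 2, 5)}")
        if self.bg_mortality.shape != (nb, 2):
            raise ValidationError(f"strata bg_mortality shape {self.bg_mortality.shape} != {(nb, 2)}")
        for name, arr in (("dm_incidence", self.dm_incidence),
                          ("dm_mortality", self.dm_mortality),
                          ("bg_mortality", self.bg_mortality)):
            if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
                raise ValidationError(f"strata.{name} has rates outside [0, 1]")

    def __eq__(self, other) -> bool:
        return (isinstance(other, StrataRateTable)
                and np.array_equal(self.dm_incidence, other.dm_incidence)
                and np.array_equal(self.dm_mortality, other.dm_mortality)
                and np.array_equal(self.bg_mortality, other.bg_mortality))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: age_band, sex, quintile, dm_incidence,
        dm_mortality, bg_mortality."""
        rows = []
        for b, (lo, hi) in enumerate(AGE_BANDS):
            for s, sex in enumerate(self.SEX_LABELS):
                for q in range(1, 6):
                    rows.append({
                        "age_band": f"{lo}-{hi}",
                        "sex": sex,
                        "quintile": q,
                        "dm_incidence": self.dm_incidence[b, s, q - 1],
                        "dm_mortality": self.dm_mortality[b, s, q - 1],
                        "bg_mortality": self.bg_mortality[b, s],
                    })
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StrataRateTable":
        nb = len(AGE_BANDS)
        inc = np.full((nb, 2, 5), np.nan)
        mort = np.full((nb, 2, 5), np.nan)
        bg = np.full((nb, 2), np.nan)
        labels = {f"{lo}-{hi}": i for i, (lo, hi) in enumerate(AGE_BANDS)}
        for _, row in df.iterrows():
            b = labels[str(row["age_band"])]
            s = cls.SEX_LABELS.index(str(row["sex"]))
            q = int(row["quintile"]) - 1
            inc[b, s, q] = row["dm_incidence"]
            mort[b, s, q] = row["dm_mortality"]
            bg[b, s] = row["bg_mortality"]
        if np.isnan(inc).any() or np.isnan(mort).any() or np.isnan(bg).any():
            missing = [(f"{AGE_BANDS[b][0]}-{AGE_BANDS[b][1]}", cls.SEX_LABELS[s], q + 1)
                       for b, s, q in zip(*np.nonzero(np.isnan(inc)))][:5]
            raise ConfigurationError(f"strata table has unpopulated cells, e.g. {missing}")
        return cls(inc, mort, bg)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StrataRateTable":
        return cls.from_frame(pd.read_csv(path))

    def lookup(self, which: str, age, sex, quintile=None) -> np.ndarray:
        """Vectorized rate lookup by exact age (banded internally)."""
        b = age_band_index(age)
        s = np.asarray(sex, dtype=int)
        if which == "bg_mortality":
            return self.bg_mortality[b, s]
        q = np.asarray(quintile, dtype=int) - 1
        if (q < 0).any() or (q > 4).any():
            raise KeyError(f"strata cell lookup: quintile outside 1..5 in {np.unique(q + 1)}")
        return getattr(self, which)[b, s, q]


@dataclass
class ParameterSet:
    """The complete model parameterization."""

    state_economics: dict[HealthState, StateEconomics]
    complications: dict[HealthState, ComplicationProfile]
    cascade: CascadeRates
    econ: EconomicConstants
    effect: InterventionEffect
    income: IncomeModel
    population: PopulationConfig
    calibration: CalibrationTargets
    strata_synthesis: StrataSynthesisConfig
    psa: PsaConfig
    baseline_cascade_split: dict[HealthState, float]
    strata: StrataRateTable
    horizon_years: int = 45
    cycle_length: int = 1

    # -- derived conveniences -------------------------------------------------

    @property
    def therapy_split(self) -> np.ndarray:
        """Probability a newly initiated person starts oral/insulin/combination
        therapy (renormalized treated-state shares of the baseline split)."""
        shares = np.array([self.baseline_cascade_split[s] for s in TREATED_STATES])
        return shares / shares.sum()

    @property
    def cascade_split_normalized(self) -> np.ndarray:
        """Baseline occupancy over the five diabetic cascade states, summing
        to 1 (printed values sum to 0.999)."""
        order = (HealthState.UNDIAGNOSED, HealthState.DIAGNOSED_UNTREATED,
                 *TREATED_STATES)
        v = np.array([self.baseline_cascade_split[s] for s in order])
        return v / v.sum()

    def econ_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(direct_cost, oop_cost, disability_weight) arrays indexed by
        HealthState integer value."""
        n = len(HealthState)
        cost = np.zeros(n)
        oop = np.zeros(n)
        weight = np.zeros(n)
        for s, e in self.state_economics.items():
            cost[s] = e.direct_medical_cost
            oop[s] = e.oop_cost
            weight[s] = e.disability_weight
        return cost, oop, weight

    def complication_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(untreated_incidence, therapy_effect) arrays in the fixed
        complication resolution order."""
        inc = np.array([self.complications[c].untreated_incidence
                        for c in COMPLICATION_STATES])
        eff = np.array([self.complications[c].therapy_effect
                        for c in COMPLICATION_STATES])
        return inc, eff

    def validate(self) -> None:
        for s in HealthState:
            if s not in self.state_economics:
                raise ConfigurationError(f"states.{s.key}: missing economics entry")
            self.state_economics[s].validate(s.key)
        for s in DEATH_STATES:
            if self.state_economics[s].disability_weight != 1.0:
                raise ValidationError(f"states.{s.key}.disability_weight must be 1")
        if self.state_economics[HealthState.HEALTHY].disability_weight != 0.0:
            raise ValidationError("states.healthy.disability_weight must be 0")
        for c in COMPLICATION_STATES:
            if c not in self.complications:
                raise ConfigurationError(f"complications.{c.key}: missing entry")
            self.complications[c].validate(c.key)
        self.cascade.validate()
        self.econ.validate()
        self.effect.validate()
        self.income.validate()
        self.population.validate()
        self.calibration.validate()
        self.strata_synthesis.validate()
        self.psa.validate()
        split = self.baseline_cascade_split
        expected = (HealthState.UNDIAGNOSED, HealthState.DIAGNOSED_UNTREATED,
                    *TREATED_STATES)
        for s in expected:
            if s not in split:
                raise ConfigurationError(f"baseline_cascade_split.{s.key}: missing")
            if split[s] < 0:
                raise ValidationError(f"baseline_cascade_split.{s.key} must be >= 0")
        if sum(split.values()) <= 0:
            raise ValidationError("baseline_cascade_split must have positive total")
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")
        if self.cycle_length != 1:
            raise ValidationError("cycle_length: only 1-year cycles are supported")
        self.strata.validate()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return to_config_dict(self) == to_config_dict(other)


# ---------------------------------------------------------------------------
# Synthetic strata tables
# ---------------------------------------------------------------------------

def _band_mid_ages() -> np.ndarray:
    return np.array([(lo + hi) / 2.0 for lo, hi in AGE_BANDS])


def _sex_factors(female_ratio: float, female_share: float) -> np.ndarray:
    """Multipliers (female, male) with population-weighted mean 1."""
    denom = female_share * female_ratio + (1.0 - female_share)
    return np.array([female_ratio / denom, 1.0 / denom])


def baseline_prevalence_curve(strata: StrataRateTable, params: "ParameterSet",
                              quintile: int) -> np.ndarray:
    """Expected diabetes prevalence among survivors at each integer age 25-69.

    Deterministic recursion: a closed cohort starts disease-free at 25 and
    accumulates diabetes at the stratum incidence, with differential survival
    through background and diabetes mortality (diabetes mortality blended over
    the baseline cascade split and the treated mortality multiplier).

    Returns an array of shape (45, 2): prevalence per age, per sex.
    """
    split = params.cascade_split_normalized
    treated_share = split[2:].sum()
    mult = params.cascade.treated_mortality_multiplier
    blend = (1.0 - treated_share) + treated_share * mult
    ages = np.arange(25, 70)
    prev = np.zeros((len(ages), 2))
    for s in (0, 1):
        p = 0.0
        for i, age in enumerate(ages):
            prev[i, s] = p
            inc = strata.dm_incidence[age_band_index(age), s, quintile - 1]
            m_dm = strata.dm_mortality[age_band_index(age), s, quintile - 1] * blend
            # survivors: diabetics face both hazards, the healthy only background
            diab = p * (1.0 - m_dm) + (1.0 - p) * inc
            healthy = (1.0 - p) * (1.0 - inc)
            p = diab / (diab + healthy) if diab + healthy > 0 else 0.0
    return prev


def _cohort_prevalence(strata: StrataRateTable, params: "ParameterSet",
                       quintile: int) -> float:
    """Age/sex-weighted expected baseline prevalence for one quintile."""
    pop = params.population
    prev = baseline_prevalence_curve(strata, params, quintile)
    ages = np.arange(25, 70)
    mask = (ages >= pop.age_min) & (ages <= pop.age_max)
    if pop.age_pyramid is None:
        age_w = mask.astype(float)
    else:
        age_w = np.asarray(pop.age_pyramid, dtype=float)[age_band_index(ages)] * mask
    age_w = age_w / age_w.sum()
    sex_w = np.array([pop.female_share, 1.0 - pop.female_share])
    return float(age_w @ prev @ sex_w)


def synthesize_default_strata(seed: int, calibration: CalibrationTargets,
                              synthesis: StrataSynthesisConfig | None = None,
                              population: PopulationConfig | None = None,
                              cascade: CascadeRates | None = None,
                              ) -> StrataRateTable:
    """Build the synthetic age/sex/quintile rate tables.

    Incidence and mortality follow smooth exponential-in-age curves; diabetes
    incidence carries a female:male ratio and a per-quintile multiplier found
    by bounded root search so that the expected baseline diabetes prevalence
    of a generated cohort matches the calibration target for that quintile.

    Deterministic given (seed, calibration); the seed is part of the interface
    for forward compatibility but the default synthesis is curve-based and
    consumes no randomness.
    """
    synthesis = synthesis or StrataSynthesisConfig()
    population = population or PopulationConfig()
    cascade = cascade or CascadeRates()

    mids = _band_mid_ages()
    nb = len(AGE_BANDS)
    sexf = _sex_factors(population.female_incidence_ratio, population.female_share)

    bg = np.clip(
        synthesis.bg_mortality_base
        * np.exp(synthesis.bg_mortality_slope * (mids - 25.0)),
        0.0, 1.0,
    )
    bg_mortality = np.repeat(bg[:, None], 2, axis=1)

    dm_mort_curve = np.clip(
        synthesis.dm_mortality_base
        * np.exp(synthesis.dm_mortality_slope * (mids - 25.0)),
        0.0, 1.0,
    )
    dm_mortality = np.broadcast_to(
        dm_mort_curve[:, None, None], (nb, 2, 5)
    ).copy()

    inc_curve = synthesis.dm_incidence_base * np.exp(
        synthesis.dm_incidence_slope * (mids - 25.0)
    )
    base_inc = inc_curve[:, None] * sexf[None, :]  # (band, sex)

    dm_incidence = np.zeros((nb, 2, 5))
    table = StrataRateTable(dm_incidence, dm_mortality, bg_mortality)

    # minimal ParameterSet stand-in for the recursion's needs
    class _P:
        pass
    p = _P()
    p.population = population
    p.cascade = cascade
    split = np.array([0.600, 0.007, 0.196, 0.036, 0.160])
    p.cascade_split_normalized = split / split.sum()

    max_mult = 0.5 / max(float(base_inc.max()), 1e-12)

    for q in range(1, 6):
        target = float(calibration.prevalence_by_quintile.get(q, 0.0))
        if target <= 0.0:
            table.dm_incidence[:, :, q - 1] = 0.0
            continue

        def objective(mult: float, q=q) -> float:
            table.dm_incidence[:, :, q - 1] = np.clip(mult * base_inc, 0.0, 1.0)
            return _cohort_prevalence(table, p, q) - target

        hi = max_mult
        f_hi = objective(hi)
        if f_hi < 0.0:
            closest = f_hi + target
            raise CalibrationError(
                f"quintile {q}: prevalence target {target:.4f} infeasible within "
                f"incidence bounds; closest achieved {closest:.4f}",
                closest=closest,
            )
        mult = brentq(objective, 0.0, hi, xtol=1e-10)
        table.dm_incidence[:, :, q - 1] = np.clip(mult * base_inc, 0.0, 1.0)

    table.validate()
    return table


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def _packaged_default_text() -> str:
    return (importlib.resources.files("cctecea") / "params_default.yaml").read_text()


def default_config_dict() -> dict:
    """The packaged default configuration as a plain dict."""
    return yaml.safe_load(_packaged_default_text())


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


_STATE_BY_KEY = {s.key: s for s in HealthState}


def _require(section: Mapping, key: str, context: str):
    if key not in section:
        raise ConfigurationError(f"missing configuration key: {context}.{key}")
    return section[key]


def _build_parameter_set(cfg: dict) -> ParameterSet:
    try:
        states = {}
        for key, entry in _require(cfg, "states", "<root>").items():
            if key not in _STATE_BY_KEY:
                raise ConfigurationError(f"states.{key}: unknown health state")
            states[_STATE_BY_KEY[key]] = StateEconomics(
                direct_medical_cost=float(_require(entry, "direct_medical_cost", f"states.{key}")),
                oop_cost=float(_require(entry, "oop_cost", f"states.{key}")),
                disability_weight=float(_require(entry, "disability_weight", f"states.{key}")),
            )
        comps = {}
        for key, entry in _require(cfg, "complications", "<root>").items():
            if key not in _STATE_BY_KEY:
                raise ConfigurationError(f"complications.{key}: unknown state")
            comps[_STATE_BY_KEY[key]] = ComplicationProfile(
                untreated_incidence=float(_require(entry, "untreated_incidence", f"complications.{key}")),
                therapy_effect=float(_require(entry, "therapy_effect", f"complications.{key}")),
            )
        split = {
            _STATE_BY_KEY[k]: float(v)
            for k, v in _require(cfg, "baseline_cascade_split", "<root>").items()
        }
        casc_cfg = cfg.get("cascade", {})
        cascade = CascadeRates(**casc_cfg)
        econ_cfg = dict(cfg.get("econ", {}))
        if "che_thresholds" in econ_cfg:
            econ_cfg["che_thresholds"] = tuple(float(t) for t in econ_cfg["che_thresholds"])
        econ = EconomicConstants(**econ_cfg)
        effect = InterventionEffect(**cfg.get("effect", {}))
        inc_cfg = dict(cfg.get("income", {}))
        if "quintile_boundaries" in inc_cfg:
            inc_cfg["quintile_boundaries"] = tuple(float(b) for b in inc_cfg["quintile_boundaries"])
        if inc_cfg.get("gamma_scales") is not None:
            inc_cfg["gamma_scales"] = tuple(float(s) for s in inc_cfg["gamma_scales"])
        income = IncomeModel(**inc_cfg)
        pop_cfg = dict(cfg.get("population", {}))
        if pop_cfg.get("age_pyramid") is not None:
            pop_cfg["age_pyramid"] = tuple(float(w) for w in pop_cfg["age_pyramid"])
        population = PopulationConfig(**pop_cfg)
        cal_cfg = dict(cfg.get("calibration", {}))
        if "prevalence_by_quintile" in cal_cfg:
            cal_cfg["prevalence_by_quintile"] = {
                int(q): float(p) for q, p in cal_cfg["prevalence_by_quintile"].items()
            }
        calibration = CalibrationTargets(**cal_cfg)
        psa = PsaConfig(**cfg.get("psa", {}))

        strata_cfg = cfg.get("strata", {"synthesize": {}})
        synth_cfg = strata_cfg.get("synthesize") or {}
        synthesis = StrataSynthesisConfig(**synth_cfg)
        if "table" in strata_cfg and strata_cfg["table"] is not None:
            strata = StrataRateTable.from_frame(pd.DataFrame(strata_cfg["table"]))
        elif "csv" in strata_cfg and strata_cfg["csv"] is not None:
            strata = StrataRateTable.from_csv(strata_cfg["csv"])
        else:
            strata = synthesize_default_strata(
                synthesis.seed, calibration, synthesis, population, cascade
            )
    except TypeError as exc:
        raise ConfigurationError(f"unrecognized configuration key: {exc}") from exc

    ps = ParameterSet(
        state_economics=states,
        complications=comps,
        cascade=cascade,
        econ=econ,
        effect=effect,
        income=income,
        population=population,
        calibration=calibration,
        strata_synthesis=synthesis,
        psa=psa,
        baseline_cascade_split=split,
        strata=strata,
        horizon_years=int(cfg.get("horizon_years", 45)),
        cycle_length=int(cfg.get("cycle_length", 1)),
    )
    ps.validate()
    return ps


def load_parameters(config_path: str | Path | None = None, *,
                    merge_defaults: bool = True) -> ParameterSet:
    """Load and validate a ParameterSet.

    ``config_path=None`` loads the packaged defaults. A user config is merged
    over the defaults, so partial configs (overriding only some keys) are
    valid; every invariant is checked and violations name the offending key.
    ``merge_defaults=False`` treats the file as a complete standalone config,
    in which case missing required keys raise a configuration error.
    """
    cfg = default_config_dict() if merge_defaults else {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        user_cfg = yaml.safe_load(path.read_text())
        if user_cfg is None:
            user_cfg = {}
        if not isinstance(user_cfg, dict):
            raise ConfigurationError(f"config file {path} does not parse to a mapping")
        cfg = _deep_merge(cfg, user_cfg)
    return _build_parameter_set(cfg)


def default_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Alias for :func:`load_parameters` emphasizing the packaged defaults."""
    return load_parameters(config_path)


def to_config_dict(params: ParameterSet) -> dict:
    """Serialize a ParameterSet to a plain config dict (strata inlined)."""
    cfg: dict = {
        "horizon_years": params.horizon_years,
        "cycle_length": params.cycle_length,
        "states": {
            s.key: {
                "direct_medical_cost": e.direct_medical_cost,
                "oop_cost": e.oop_cost,
                "disability_weight": e.disability_weight,
            }
            for s, e in sorted(params.state_economics.items())
        },
        "complications": {
            c.key: {
                "untreated_incidence": p.untreated_incidence,
                "therapy_effect": p.therapy_effect,
            }
            for c, p in sorted(params.complications.items())
        },
        "baseline_cascade_split": {
            s.key: v for s, v in sorted(params.baseline_cascade_split.items())
        },
        "cascade": asdict(params.cascade),
        "econ": {**asdict(params.econ),
                 "che_thresholds": list(params.econ.che_thresholds)},
        "effect": asdict(params.effect),
        "income": {
            "quintile_boundaries": list(params.income.quintile_boundaries),
            "gamma_shape": params.income.gamma_shape,
            "gamma_scales": (None if params.income.gamma_scales is None
                             else list(params.income.gamma_scales)),
        },
        "population": {**asdict(params.population),
                       "age_pyramid": (None if params.population.age_pyramid is None
                                       else list(params.population.age_pyramid))},
        "calibration": asdict(params.calibration),
        "psa": asdict(params.psa),
        "strata": {
            "synthesize": asdict(params.strata_synthesis),
            "table": params.strata.to_frame().to_dict(orient="list"),
        },
    }
    return cfg


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to YAML; ``load_parameters`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(to_config_dict(params), sort_keys=True))
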