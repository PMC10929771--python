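"""Synthetic eligible population.

Generates the cohort of simulated individuals (ages 25-69 in the selected
income quintiles) with incomes drawn from truncated per-quintile gamma
distributions, baseline diabetes status assigned from the calibrated
prevalence-by-age curve, and prevalent diabetics split across the care
cascade by the baseline occupancy proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    HealthState,
    IncomeModel,
    ParameterSet,
    baseline_prevalence_curve,
)

__all__ = ["Individual", "Cohort", "generate_population", "sample_income"]

SEX_LABELS = ("female", "male")


@dataclass
class Individual:
    """One simulated person (scalar view, used for inspection and testing).

    The engine operates on the cohort's column arrays; this dataclass is the
    row-wise view of the same fields.
    """

    id: int
    age: int
    sex: str
    quintile: int
    income: float
    state: HealthState
    alive: bool = True
    cycle_entered_state: int = 0


@dataclass
class Cohort:
    """Struct-of-arrays container for the simulated population.

    ``scale_factor`` is the ratio of the represented population (about 6
    million people aged 25-69 per income quintile) to the simulated count, so
    population totals are ``simulated total x scale_factor``.
    """

    ids: np.ndarray
    age: np.ndarray
    sex: np.ndarray          # 0 = female, 1 = male
    quintile: np.ndarray
    income: np.ndarray
    cascade: np.ndarray      # HealthState codes 0..5
    alive: np.ndarray
    seed: int
    quintiles: tuple[int, ...]
    scale_factor: float

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cohort ids must be unique")

    @property
    def n(self) -> int:
        return len(self.ids)

    def copy(self) -> "Cohort":
        return Cohort(
            ids=self.ids.copy(), age=self.age.copy(), sex=self.sex.copy(),
            quintile=self.quintile.copy(), income=self.income.copy(),
            cascade=self.cascade.copy(), alive=self.alive.copy(),
            seed=self.seed, quintiles=self.quintiles,
            scale_factor=self.scale_factor,
        )

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]), age=int(self.age[i]),
            sex=SEX_LABELS[int(self.sex[i])], quintile=int(self.quintile[i]),
            income=float(self.income[i]),
            state=HealthState(int(self.cascade[i])),
            alive=bool(self.alive[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Cohort snapshot: id, age, sex, quintile, income, state."""
        return pd.DataFrame({
            "id": self.ids,
            "age": self.age,
            "sex": np.asarray(SEX_LABELS)[self.sex],
            "quintile": self.quintile,
            "income": self.income,
            "state": [HealthState(c).key for c in self.cascade],
        })

    def baseline_prevalence(self) -> float:
        """Share of the cohort with diabetes (any non-healthy cascade state)."""
        return float((self.cascade != HealthState.HEALTHY).mean())


def sample_income(quintile: int, model: IncomeModel, rng: np.random.Generator,
                  size: int = 1) -> np.ndarray:
    """Draw incomes for one quintile: gamma rejected to the quintile band.

    Strictly positive; every draw falls inside the band [lower, upper).
    """
    lo, hi = model.band(quintile)
    if hi <= lo:
        raise ValueError(f"quintile {quintile} band [{lo}, {hi}) has zero width")
    shape, scale = model.gamma_shape, model.scale(quintile)
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        need = size - filled
        if need == 0:
            break
        draw = rng.gamma(shape, scale, size=max(need * 2, 16))
        ok = draw[(draw >= lo) & (draw < hi)][:need]
        out[filled:filled + len(ok)] = ok
        filled += len(ok)
    if filled < size:  # pathological band: fall back to uniform within band
        out[filled:] = rng.uniform(lo, hi, size - filled)
    return np.maximum(out, np.finfo(float).tiny)


def generate_population(n: int, quintiles, params: ParameterSet,
                        seed: int) -> Cohort:
    """Generate the synthetic eligible population.

    Ages come from the configured pyramid (default uniform over 25-69), sex
    from the configured female share, incomes from the truncated per-quintile
    gamma model, and baseline diabetes status from the calibrated
    prevalence-by-age curve; prevalent diabetics are split across the care
    cascade by the baseline occupancy proportions. Deterministic given
    (n, quintiles, params, seed).
    """
    if n < 1:
        raise ValueError(f"n={n}: need at least one individual")
    quintiles = tuple(sorted(set(int(q) for q in np.atleast_1d(list(quintiles)))))
    if not quintiles or any(q < 1 or q > 5 for q in quintiles):
        raise ValueError(f"quintiles {quintiles} must be a non-empty subset of 1..5")

    pop = params.population
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    # ages: draw band by pyramid weight, then uniformly within band
    ages_all = np.arange(pop.age_min, pop.age_max + 1)
    if pop.age_pyramid is None:
        age_w = np.ones(len(ages_all))
    else:
        from .parameters import age_band_index
        age_w = np.asarray(pop.age_pyramid, dtype=float)[age_band_index(ages_all)]
    age_w = age_w / age_w.sum()
    age = rng.choice(ages_all, size=n, p=age_w)

    sex = (rng.random(n) >= pop.female_share).astype(np.int8)  # 0 female
    quintile = rng.choice(np.asarray(quintiles), size=n)

    income = np.empty(n)
    for q in quintiles:
        mask = quintile == q
        income[mask] = sample_income(q, params.income, rng, size=int(mask.sum()))

    # baseline diabetes status from the calibrated prevalence curves
    cascade = np.zeros(n, dtype=np.int8)
    prev_by_age = {q: baseline_prevalence_curve(params.strata, params, q)
                   for q in quintiles}
    u = rng.random(n)
    p_i = np.empty(n)
    for q in quintiles:
        mask = quintile == q
        p_i[mask] = prev_by_age[q][age[mask] - 25, sex[mask]]
    diabetic = u < p_i

    split = params.cascade_split_normalized
    order = np.array([HealthState.UNDIAGNOSED, HealthState.DIAGNOSED_UNTREATED,
                      HealthState.ORAL_THERAPY, HealthState.INSULIN_THERAPY,
                      HealthState.COMBINATION_THERAPY], dtype=np.int8)
    draws = rng.choice(order, size=int(diabetic.sum()), p=split)
    cascade[diabetic] = draws

    scale = params.econ.population_per_quintile * len(quintiles) / n
    return Cohort(
        ids=np.arange(n, dtype=np.int64),
        age=age.astype(np.int16),
        sex=sex,
        quintile=quintile.astype(np.int8),
        income=income,
        cascade=cascade,
        alive=np.ones(n, dtype=bool),
        seed=int(seed),
        quintiles=quintiles,
        scale_factor=scale,
    )
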