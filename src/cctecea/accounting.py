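"""Cost, transfer and DALY accrual.

Accrues, per individual and cycle: discounted health-system costs (state
direct medical costs plus CCT outlays and any administrative loading),
discounted out-of-pocket (OOP) costs gross and net of transfers received,
discounted transfers, and DALYs (disability weights applied to the year
spent in each state, with death contributing weight 1 for the death year and
every remaining horizon year as years of life lost, discounted and truncated
at the horizon). Catastrophic-health-expenditure flags are evaluated on the
undiscounted annual OOP of each cycle against the individual's capacity to
pay.

The incremental cost-effectiveness analysis takes a health-system
perspective: OOP costs never enter ``hs_cost`` and feed only the
financial-risk-protection outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = ["discount_factor", "yll_factors", "Ledger", "disburse_cct", "accrue_cycle"]

#: Floor for capacity to pay, keeping the CHE ratio defined for incomes at
#: the subsistence line.
CTP_EPSILON = 1e-6


def discount_factor(year: int, rate: float):
    """Present-value multiplier (1 + rate)^(-year) for a cycle index >= 0."""
    year_arr = np.asarray(year)
    if np.any(year_arr < 0):
        raise ValueError("year must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = (1.0 + rate) ** (-year_arr.astype(float))
    return float(out) if out.ndim == 0 else out


def yll_factors(horizon: int, rate: float, discount: bool = True) -> np.ndarray:
    """Years-of-life-lost multiplier per death cycle: the (discounted) number
    of horizon years remaining from that cycle onwards, inclusive."""
    df = discount_factor(np.arange(horizon), rate) if discount else np.ones(horizon)
    return np.cumsum(df[::-1])[::-1]


@dataclass
class Ledger:
    """Per-individual accumulating ledgers (all discounted except CHE)."""

    hs_cost: np.ndarray
    oop_gross: np.ndarray
    oop_net: np.ndarray
    cct: np.ndarray
    dalys: np.ndarray
    treated_years: np.ndarray
    che_years: np.ndarray  # (n, n_thresholds), undiscounted person-year counts
    che_ever: np.ndarray

    @classmethod
    def zeros(cls, n: int, n_thresholds: int) -> "Ledger":
        return cls(
            hs_cost=np.zeros(n), oop_gross=np.zeros(n), oop_net=np.zeros(n),
            cct=np.zeros(n), dalys=np.zeros(n), treated_years=np.zeros(n),
            che_years=np.zeros((n, n_thresholds), dtype=np.int16),
            che_ever=np.zeros((n, n_thresholds), dtype=bool),
        )


def disburse_cct(cohort, events, strategy, params: ParameterSet) -> np.ndarray:
    """Undiscounted transfer amounts per individual for this cycle.

    The one-off diagnosis transfer goes to eligible people attending
    screening/diagnosis services in diagnosis-covering arms (every screening
    attendance when ``econ.screening_cct`` is on, else only attendances that
    yield a diagnosis); the annual treatment transfer (four payments totalling
    the configured amount) goes to eligible people spending the cycle in a
    treated state in treatment-covering arms. Annual resolution: a treatment
    year is paid in full, with no pro-rating.
    """
    econ = params.econ
    eligible = strategy.eligible_mask(cohort.quintile)
    cct = np.zeros(cohort.n)
    if strategy.covers_diagnosis:
        visits = events.screened if econ.screening_cct else events.diagnosed
        cct[visits & eligible] += econ.cct_diagnosis_amount
    if strategy.covers_treatment:
        cct[events.treated_cycle & eligible] += econ.cct_treatment_amount
    return cct


def accrue_cycle(ledger: Ledger, cohort, events, strategy,
                 params: ParameterSet, cycle: int) -> Ledger:
    """Add one cycle's costs, transfers, DALYs and CHE flags to the ledger."""
    econ = params.econ
    df = discount_factor(cycle, econ.discount_rate)
    df_daly = df if econ.discount_dalys else 1.0

    cost_vec, oop_vec, weight_vec = params.econ_vectors()
    alive = events.alive_end
    occ = events.occupied_state

    direct = np.where(alive, cost_vec[occ], 0.0)
    oop = np.where(alive, oop_vec[occ], 0.0)
    cct = disburse_cct(cohort, events, strategy, params)

    ledger.hs_cost += (direct + cct * (1.0 + econ.admin_cost_fraction)) * df
    ledger.cct += cct * df
    ledger.oop_gross += oop * df
    oop_net_annual = np.maximum(oop - cct, 0.0) if econ.che_net_of_cct else oop
    ledger.oop_net += oop_net_annual * df
    ledger.treated_years += events.treated_cycle * df

    # disability: state weights for survivors; deaths this cycle start the
    # years-of-life-lost stream (weight 1 for this and all remaining years)
    ledger.dalys += np.where(alive, weight_vec[occ], 0.0) * df_daly
    died = events.died_other | events.died_diabetes
    if died.any():
        yll = yll_factors(params.horizon_years, econ.discount_rate,
                          econ.discount_dalys)
        ledger.dalys[died] += yll[cycle]

    capacity = np.maximum(cohort.income - econ.food_poverty_line, CTP_EPSILON)
    for k, thr in enumerate(econ.che_thresholds):
        flag = alive & (oop_net_annual > thr * capacity)
        ledger.che_years[:, k] += flag
        ledger.che_ever[:, k] |= flag
    return ledger
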