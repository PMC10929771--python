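"""Incremental cost-effectiveness analysis.

Computes, for each CCT arm against the paired no-programme run: incremental
health-system cost and DALYs averted (population totals and per eligible
person), the incremental cost-effectiveness ratio (ICER), the incremental
net monetary benefit (INMB = threshold x DALYs averted per person - cost per
person), incremental OOP averted, and CHE cases averted, disaggregated by
sex or income quintile. Per-person denominators are the represented eligible
population (simulated count x scale factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import frp
from .engine import RunResult
from .parameters import ParameterSet
from .population import SEX_LABELS

__all__ = ["IcerOutcome", "icer", "inmb", "EconSummary", "summarize",
           "results_table"]


@dataclass(frozen=True)
class IcerOutcome:
    """ICER with its cost-effectiveness-plane classification.

    ``value`` is cost per DALY averted for the ordinary north-east /
    south-west quadrants; dominant (cheaper and better) and dominated (dearer
    and worse) arms carry a flag instead of a bare ratio, and a zero health
    difference yields the 'undefined' signal with value NaN.
    """

    value: float
    classification: str  # 'ratio' | 'dominant' | 'dominated' | 'undefined'

    def __float__(self) -> float:
        return self.value


def icer(delta_cost: float, delta_daly: float) -> IcerOutcome:
    """Incremental cost per DALY averted (positive delta_daly = health gain)."""
    if delta_daly == 0:
        return IcerOutcome(math.nan, "undefined")
    if delta_daly > 0 and delta_cost <= 0:
        return IcerOutcome(delta_cost / delta_daly, "dominant")
    if delta_daly < 0 and delta_cost >= 0:
        return IcerOutcome(delta_cost / delta_daly, "dominated")
    return IcerOutcome(delta_cost / delta_daly, "ratio")


def inmb(delta_cost_pp: float, delta_daly_pp: float, threshold: float) -> float:
    """Incremental net monetary benefit per person:
    threshold x DALYs averted - incremental cost."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return threshold * delta_daly_pp - delta_cost_pp


@dataclass
class GroupIncrements:
    """Incremental outcomes for one (sub)group of the eligible population."""

    eligible: float
    delta_cost_total: float
    delta_daly_total: float
    delta_cost_pp: float
    delta_daly_pp: float
    inmb: float
    oop_averted_total: float
    cct_outlay_total: float
    cct_outlay_pp: float


@dataclass
class EconSummary:
    """Incremental analysis of one arm versus the paired no-programme run."""

    arm: str
    eligibility: tuple[int, ...]
    overall: GroupIncrements
    icer: IcerOutcome
    che_averted: dict[float, float]
    groups: dict[str, GroupIncrements] = field(default_factory=dict)

    @property
    def inmb(self) -> float:
        return self.overall.inmb


def _increments(base: RunResult, arm: RunResult, params: ParameterSet,
                mask: np.ndarray | None = None) -> GroupIncrements:
    scale = base.scale_factor
    sel = slice(None) if mask is None else mask
    n_sel = base.n if mask is None else int(np.sum(mask))
    eligible = n_sel * scale
    d_cost = float(arm.hs_cost[sel].sum() - base.hs_cost[sel].sum()) * scale
    d_daly = float(base.dalys[sel].sum() - arm.dalys[sel].sum()) * scale
    d_oop = float(base.oop_net[sel].sum() - arm.oop_net[sel].sum()) * scale
    cct_total = float(arm.cct[sel].sum()) * scale
    d_cost_pp = d_cost / eligible
    d_daly_pp = d_daly / eligible
    return GroupIncrements(
        eligible=eligible,
        delta_cost_total=d_cost,
        delta_daly_total=d_daly,
        delta_cost_pp=d_cost_pp,
        delta_daly_pp=d_daly_pp,
        inmb=inmb(d_cost_pp, d_daly_pp, params.econ.ce_threshold),
        oop_averted_total=d_oop,
        cct_outlay_total=cct_total,
        cct_outlay_pp=cct_total / eligible,
    )


def summarize(base: RunResult, arm: RunResult, params: ParameterSet,
              groupby: str = "none") -> EconSummary:
    """Incremental summary of one arm versus the no-programme run.

    ``groupby`` adds subgroup increments by 'sex' or 'quintile' (per-person
    figures use subgroup-specific eligible counts).
    """
    frp._check_paired(base, arm)
    overall = _increments(base, arm, params)
    groups: dict[str, GroupIncrements] = {}
    if groupby == "sex":
        for s, label in enumerate(SEX_LABELS):
            groups[label] = _increments(base, arm, params, base.sex == s)
    elif groupby == "quintile":
        for q in sorted(set(base.quintiles)):
            groups[f"q{q}"] = _increments(base, arm, params, base.quintile == q)
    elif groupby != "none":
        raise ValueError(f"groupby must be 'none', 'sex' or 'quintile', got {groupby!r}")
    che = {thr: frp.che_cases_averted(base, arm, params, thr)
           for thr in params.econ.che_thresholds}
    return EconSummary(
        arm=arm.strategy.name,
        eligibility=tuple(sorted(arm.strategy.eligible_quintiles)),
        overall=overall,
        icer=icer(overall.delta_cost_total, overall.delta_daly_total),
        che_averted=che,
        groups=groups,
    )


def results_table(base: RunResult, arms: dict[str, RunResult],
                  params: ParameterSet) -> pd.DataFrame:
    """Results table mirroring the printed layout: one row per arm with
    incremental cost (total, per person), DALYs averted, INMB overall and by
    sex, OOP averted and CHE cases averted per threshold."""
    rows = []
    for name, arm in arms.items():
        s = summarize(base, arm, params, groupby="sex")
        row = {
            "eligibility": "+".join(str(q) for q in s.eligibility),
            "strategy": name,
            "incremental_cost_total": s.overall.delta_cost_total,
            "incremental_cost_pp": s.overall.delta_cost_pp,
            "incremental_dalys_total": s.overall.delta_daly_total,
            "incremental_dalys_pp": s.overall.delta_daly_pp,
            "icer": s.icer.value,
            "icer_class": s.icer.classification,
            "inmb": s.overall.inmb,
            "inmb_female": s.groups["female"].inmb,
            "inmb_male": s.groups["male"].inmb,
            "oop_averted_total": s.overall.oop_averted_total,
        }
        for thr, averted in s.che_averted.items():
            row[f"che_averted_{int(round(thr * 100))}pct"] = averted
        rows.append(row)
    return pd.DataFrame(rows)
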