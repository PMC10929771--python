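"""Financial risk protection: catastrophic health expenditure (CHE).

A CHE case is a person-year in which annual out-of-pocket health spending
(net of transfers received, under the default accounting) exceeds a
threshold fraction of the individual's capacity to pay, defined as income
minus subsistence spending (the food poverty line). Cases averted compare a
CCT arm against the paired no-programme run under common random numbers and
are reported on the represented-population scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accounting import CTP_EPSILON
from .engine import RunResult
from .population import SEX_LABELS

__all__ = ["is_che", "che_cases", "che_cases_averted", "frp_summary",
           "ComparisonError"]


class ComparisonError(ValueError):
    """Arm results are not paired (different cohort, seed or scale)."""


def is_che(annual_oop, income, fpl: float, threshold: float):
    """True iff annual OOP spending strictly exceeds threshold x capacity to
    pay, with capacity = max(income - fpl, epsilon)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    income_arr = np.asarray(income, dtype=float)
    if np.any(income_arr <= 0):
        raise ValueError("income must be > 0")
    capacity = np.maximum(income_arr - fpl, CTP_EPSILON)
    out = np.asarray(annual_oop, dtype=float) > threshold * capacity
    return bool(out) if out.ndim == 0 else out


def _threshold_index(result: RunResult, params, threshold: float) -> int:
    thresholds = tuple(params.econ.che_thresholds)
    for k, t in enumerate(thresholds):
        if abs(t - threshold) < 1e-12:
            return k
    raise ValueError(f"threshold {threshold} not among configured {thresholds}")


def _check_paired(base: RunResult, arm: RunResult) -> None:
    if not base.comparable_with(arm):
        raise ComparisonError(
            "base and arm runs must share cohort, seed and scale for "
            "incremental comparison"
        )


def che_cases(result: RunResult, params, threshold: float,
              mask: np.ndarray | None = None) -> float:
    """CHE cases (population-scaled) in one run at one threshold.

    The accounting unit follows ``econ.che_unit``: person-years in CHE
    (default) or persons ever in CHE over the horizon.
    """
    k = _threshold_index(result, params, threshold)
    cases = (result.che_years[:, k] if params.econ.che_unit == "person_year"
             else result.che_ever[:, k])
    cases = np.asarray(cases, dtype=float)
    if mask is not None:
        cases = cases[mask]
    return float(cases.sum()) * result.scale_factor


def che_cases_averted(base: RunResult, arm: RunResult, params,
                      threshold: float, mask: np.ndarray | None = None) -> float:
    """CHE cases averted by the arm versus the paired no-programme run."""
    _check_paired(base, arm)
    return (che_cases(base, params, threshold, mask)
            - che_cases(arm, params, threshold, mask))


def frp_summary(base: RunResult, arms: dict[str, RunResult], params,
                ) -> pd.DataFrame:
    """Tidy FRP table: arm x threshold x sex (plus 'all') cases and averted."""
    rows = []
    for name, arm in arms.items():
        _check_paired(base, arm)
        for thr in params.econ.che_thresholds:
            for sex_label in ("all", *SEX_LABELS):
                mask = (None if sex_label == "all"
                        else base.sex == SEX_LABELS.index(sex_label))
                rows.append({
                    "arm": name,
                    "eligibility": "+".join(str(q) for q in sorted(arm.strategy.eligible_quintiles)),
                    "threshold": thr,
                    "sex": sex_label,
                    "cases": che_cases(arm, params, thr, mask),
                    "cases_averted": che_cases_averted(base, arm, params, thr, mask),
                })
    return pd.DataFrame(rows)
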