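"""Sensitivity analyses: probabilistic (PSA), population replicates, one-way.

PSA samples parameter sets from uncertainty distributions (gamma for costs,
log-normal for the intervention odds ratio matched to its 95% CI,
method-of-moments beta for probabilities), re-runs every arm on a common
cohort per draw, and summarizes cost-effectiveness acceptability curves
(CEAC). Population replicates regenerate the cohort at fixed parameters to
isolate sampling variability. One-way analyses move a single parameter
between bounds and report the INMB swing per arm (tornado entries).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import econ as econ_mod
from .engine import StrategyConfig, run_study
from .parameters import (
    COMPLICATION_STATES,
    ComplicationProfile,
    ParameterSet,
    StateEconomics,
)

__all__ = [
    "PsaDraw", "CeacCurve", "sample_odds_ratio", "sample_parameter_set",
    "run_psa", "ceac", "one_way", "builtin_one_way_scenarios",
    "population_replicates", "valid_one_way_parameters",
]

_PSA_STREAM = 104729
_POP_STREAM = 15485863
_MAX_SEED = 2**31 - 1


@dataclass
class PsaDraw:
    """One PSA draw: sampled overrides and the per-arm incremental results."""

    index: int
    overrides: dict[str, float]
    results: dict[str, dict[str, float]]  # arm -> {delta_cost_pp, delta_daly_pp, inmb}


@dataclass
class CeacCurve:
    """P(arm maximizes net monetary benefit) over a willingness-to-pay grid."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # index = wtp, columns = arms (incl. no_programme)

    def to_frame(self) -> pd.DataFrame:
        long = self.probabilities.reset_index().melt(
            id_vars="wtp", var_name="arm", value_name="probability"
        )
        return long


def _gamma_around(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean <= 0 or cv <= 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _beta_around(rng: np.random.Generator, p: float, cv: float, name: str) -> float:
    if p <= 0 or p >= 1 or cv <= 0:
        return p
    var = (cv * p) ** 2
    if var >= p * (1 - p):
        raise ValueError(
            f"beta moment matching infeasible for {name}: mean {p}, cv {cv}"
        )
    nu = p * (1 - p) / var - 1.0
    return float(rng.beta(p * nu, (1 - p) * nu))


def sample_odds_ratio(effect, rng: np.random.Generator, size: int | None = None):
    """Log-normal odds-ratio draws matched to the point estimate and 95% CI."""
    sigma = (np.log(effect.ci_high) - np.log(effect.ci_low)) / (2 * stats.norm.ppf(0.975))
    mu = np.log(effect.odds_ratio)
    if sigma <= 0:
        return effect.odds_ratio if size is None else np.full(size, effect.odds_ratio)
    draws = rng.lognormal(mu, sigma, size=size)
    return float(draws) if size is None else draws


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator,
                         ) -> tuple[ParameterSet, dict[str, float]]:
    """Draw one PSA parameter set: costs (gamma), cascade and complication
    probabilities (beta), intervention odds ratio (log-normal).

    Disability weights, strata tables and their prevalence calibration are
    held at point estimates across draws.
    """
    p = params.copy()
    overrides: dict[str, float] = {}
    ccv, pcv = p.psa.cost_cv, p.psa.probability_cv

    for s, e in list(p.state_economics.items()):
        new = StateEconomics(
            direct_medical_cost=_gamma_around(rng, e.direct_medical_cost, ccv),
            oop_cost=_gamma_around(rng, e.oop_cost, ccv),
            disability_weight=e.disability_weight,
        )
        p.state_economics[s] = new
        overrides[f"states.{s.key}.direct_medical_cost"] = new.direct_medical_cost
        overrides[f"states.{s.key}.oop_cost"] = new.oop_cost

    for c in COMPLICATION_STATES:
        prof = p.complications[c]
        new_inc = _beta_around(rng, prof.untreated_incidence, pcv,
                               f"complications.{c.key}.untreated_incidence")
        p.complications[c] = ComplicationProfile(new_inc, prof.therapy_effect)
        overrides[f"complications.{c.key}.untreated_incidence"] = new_inc

    for key in ("p_dx", "p_dt", "p_tna"):
        val = _beta_around(rng, getattr(p.cascade, key), pcv, f"cascade.{key}")
        setattr(p.cascade, key, val)
        overrides[f"cascade.{key}"] = val

    or_draw = sample_odds_ratio(p.effect, rng)
    p.effect.odds_ratio = or_draw
    p.effect.ci_low = min(p.effect.ci_low, or_draw)
    p.effect.ci_high = max(p.effect.ci_high, or_draw)
    overrides["effect.odds_ratio"] = or_draw
    p.validate()
    return p, overrides


def run_psa(n: int, quintiles, arms: dict[str, StrategyConfig],
            params: ParameterSet, n_draws: int, seed: int) -> list[PsaDraw]:
    """Probabilistic sensitivity analysis.

    Per draw: sample a parameter set, generate a fresh cohort, and run the
    no-programme arm plus every CCT arm on that common cohort (common random
    numbers within the draw). Deterministic given (seed, n_draws).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    draws = []
    for d in range(n_draws):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _PSA_STREAM, d]))
        params_d, overrides = sample_parameter_set(params, rng)
        cohort_seed = int(rng.integers(_MAX_SEED))
        base, results = run_study(n, quintiles, params_d, cohort_seed, arms)
        per_arm = {}
        for name, res in results.items():
            s = econ_mod.summarize(base, res, params_d)
            per_arm[name] = {
                "delta_cost_pp": s.overall.delta_cost_pp,
                "delta_daly_pp": s.overall.delta_daly_pp,
                "inmb": s.overall.inmb,
            }
        draws.append(PsaDraw(index=d, overrides=overrides, results=per_arm))
    return draws


def ceac(draws: list[PsaDraw], wtp_grid) -> CeacCurve:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    At each willingness-to-pay value, each arm's probability is the fraction
    of draws in which it attains the highest net monetary benefit among the
    CCT arms and the no-programme reference (NMB 0); probabilities across
    arms sum to 1 at every grid point.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if len(draws) < 2:
        raise ValueError("need at least two PSA draws")
    arm_names = list(draws[0].results.keys())
    cols = ["no_programme", *arm_names]
    counts = np.zeros((len(wtp), len(cols)))
    d_cost = np.array([[d.results[a]["delta_cost_pp"] for a in arm_names] for d in draws])
    d_daly = np.array([[d.results[a]["delta_daly_pp"] for a in arm_names] for d in draws])
    for i, w in enumerate(wtp):
        nmb = w * d_daly - d_cost  # (draws, arms)
        nmb_all = np.column_stack([np.zeros(len(draws)), nmb])
        winner = np.argmax(nmb_all, axis=1)
        for j in range(len(cols)):
            counts[i, j] = np.mean(winner == j)
    probs = pd.DataFrame(counts, columns=cols)
    probs.insert(0, "wtp", wtp)
    probs = probs.set_index("wtp")
    return CeacCurve(wtp=wtp, probabilities=probs)


# -- one-way (tornado) analyses ---------------------------------------------

_ONE_WAY_SECTIONS = ("cascade", "econ", "effect", "income", "population", "psa")


def valid_one_way_parameters(params: ParameterSet) -> list[str]:
    """Dotted identifiers accepted by :func:`one_way`."""
    out = []
    for section in _ONE_WAY_SECTIONS:
        obj = getattr(params, section)
        for f in dataclasses.fields(obj):
            if f.type in ("float", "int", "float | None", "bool"):
                out.append(f"{section}.{f.name}")
    return out


def _set_param(params: ParameterSet, dotted: str, value: float) -> ParameterSet:
    p = params.copy()
    try:
        section, name = dotted.split(".", 1)
        obj = getattr(p, section)
        if not hasattr(obj, name):
            raise AttributeError(name)
        setattr(obj, name, value)
    except (ValueError, AttributeError):
        raise KeyError(
            f"unknown parameter {dotted!r}; valid identifiers: "
            + ", ".join(valid_one_way_parameters(params))
        )
    p.validate()
    return p


def one_way(parameter: str, low: float, high: float,
            arms: dict[str, StrategyConfig], base_params: ParameterSet, *,
            n: int, quintiles, seed: int) -> pd.DataFrame:
    """One-way sensitivity analysis for one parameter.

    Runs every arm (against its paired no-programme run, common cohort seed)
    at the low and high parameter values and reports the INMB at each bound
    and the absolute swing — one tornado entry per arm.
    """
    if low > high:
        raise ValueError("low must be <= high")
    rows = []
    inmb_at = {}
    for bound, value in (("low", low), ("high", high)):
        p = _set_param(base_params, parameter, value)
        base, results = run_study(n, quintiles, p, seed, arms)
        inmb_at[bound] = {name: econ_mod.summarize(base, res, p).overall.inmb
                          for name, res in results.items()}
    for name in inmb_at["low"]:
        lo_v, hi_v = inmb_at["low"][name], inmb_at["high"][name]
        rows.append({
            "parameter": parameter, "arm": name, "low": low, "high": high,
            "inmb_low": lo_v, "inmb_high": hi_v, "swing": abs(hi_v - lo_v),
        })
    return pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)


def builtin_one_way_scenarios(params: ParameterSet) -> list[tuple[str, float, float]]:
    """The study's one-way scenarios: the effect odds ratio over its 95% CI
    applied to both channels, to diagnosis uptake only, to treatment uptake
    only; and administrative loading between 0 and 50% of transfer outlays."""
    lo, hi = params.effect.ci_low, params.effect.ci_high
    return [
        ("effect.odds_ratio", lo, hi),
        ("effect.or_diagnosis", lo, hi),
        ("effect.or_treatment", lo, hi),
        ("econ.admin_cost_fraction", 0.0, 0.50),
    ]


def population_replicates(n_pops: int, n: int, quintiles,
                          arms: dict[str, StrategyConfig],
                          params: ParameterSet, seed: int) -> pd.DataFrame:
    """Re-run the study on freshly generated cohorts at fixed parameters.

    Returns one row per (replicate, arm) with the per-person increments, to
    quantify outcome spread attributable to population sampling alone.
    """
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    rows = []
    for k in range(n_pops):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _POP_STREAM, k]))
        cohort_seed = int(rng.integers(_MAX_SEED))
        base, results = run_study(n, quintiles, params, cohort_seed, arms)
        for name, res in results.items():
            s = econ_mod.summarize(base, res, params)
            rows.append({
                "replicate": k, "cohort_seed": cohort_seed, "arm": name,
                "delta_cost_pp": s.overall.delta_cost_pp,
                "delta_daly_pp": s.overall.delta_daly_pp,
                "inmb": s.overall.inmb,
            })
    return pd.DataFrame(rows)
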