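# Methods

## Model

`cctecea` is an individual-level, annual-cycle Markov model of the diabetes
care cascade in South Africa, built to evaluate conditional cash transfer
(CCT) programmes that pay people in the poorest income quintiles for
attending diabetes diagnosis and/or treatment services. A cohort
representing the population aged 25–69 in the bottom one or two income
quintiles (about 6 million people per quintile) is simulated over a 45-year
horizon with one-year cycles.

Each person occupies one care-cascade state per cycle — healthy,
undiagnosed diabetes, diagnosed-untreated, or diagnosed-on-therapy (oral,
insulin, or combination) — plus transient one-cycle complication states
(nephropathy, retinopathy, neuropathy, angina, peripheral vascular disease,
myocardial infarction, stroke, heart failure, severe hyper- and
hypoglycaemia) and two absorbing death states (diabetes-related and
other-cause). Within a cycle, events resolve hierarchically, earlier events
pre-empting later ones:

1. other-cause death (age/sex background mortality),
2. diabetes death (age/sex/quintile diabetes mortality; multiplied by
   `treated_mortality_multiplier` while on therapy),
3. diabetes onset (healthy only),
4. screening attendance / diagnosis (probability `P_dx` per year for the
   undiagnosed; healthy attendees screen negative),
5. therapy initiation (probability `P_dt` at diagnosis; therapy assigned by
   the renormalized oral/insulin/combination shares 0.196/0.036/0.160),
6. non-adherence (probability `P_tna` per year for people on therapy; the
   newly initiated complete their first treatment-year),
7. complication draw (independent per complication at the untreated
   incidence times the therapy-effect risk ratio when on therapy; if several
   fire, the first in the fixed table order is occupied for the cycle, and
   the person returns to their cascade state the next cycle).

By default treatment is a single spell per diagnosis: decliners and
dropouts remain diagnosed-untreated (`cascade.allow_reinitiation` restores
per-cycle retries). This reflects the adherence-limited cascade the
programme targets — nationally only about one in five people with diabetes
achieves glycaemic control — and keeps the marginal value of extra
diagnoses distinct from the marginal value of better adherence.

### Intervention

The CCT effect is an odds ratio of 1.31 (95% CI 1.12–1.54) on service
utilization, identical for all strategies. A diagnosis-covering arm applies
it to `P_dx` (on the odds scale) for eligible quintiles; a
treatment-covering arm applies it to the adherence probability `1 − P_tna`
on the odds scale (mode `direct` divides `P_tna` instead). Transfers:
USD 13 per screening/diagnosis visit (by default paid for every screening
attendance by a not-yet-diagnosed eligible person, the reading consistent
with annual screening eligibility and the published per-person cost of the
diagnosis-only arm; `econ.screening_cct: false` restricts it to attendances
that yield a diagnosis) and USD 51 per adherent treatment-year, disbursed
as four quarterly transfers but accounted annually without pro-rating.

### Accounting

Costs and DALYs accrue per person-cycle and are discounted at 5% per year
(both; `econ.discount_dalys: false` leaves DALYs undiscounted). The state
occupied during the cycle contributes its annual direct medical cost to the
health-system ledger and its annual OOP (transport plus wage loss) to the
individual ledger; transfers enter the health-system ledger (plus
`admin_cost_fraction` as pure administrative loading) and are recorded as
received. Death in a cycle contributes disability weight 1 for that and
every remaining horizon year (years of life lost truncated at the horizon,
not at life expectancy — the simulation frame bounds the loss). The ICER
and INMB take the health-system perspective; OOP feeds only the
financial-risk-protection outcomes. Per-person denominators are the
represented eligible population (simulated n × scale factor).

Catastrophic health expenditure (CHE) is assessed per person-year: annual
OOP — net of transfers received that year, floored at zero — strictly
exceeding a threshold (10/25/40%) of capacity to pay, defined as income
minus the food poverty line (floored at a small epsilon). Netting is the
point of the transfer design: the USD 51 annual transfer exactly offsets
the treated-state OOP, which is how the programme averts CHE; gross-OOP
accounting is available (`econ.che_net_of_cct: false`) but makes treatment
expansion raise CHE at the 10% threshold. Cases averted are counted against
the paired no-programme run. The diagnosis-only arm's averted counts are
typically negative (newly diagnosed people face treated-state OOP with no
offsetting transfer) and are not threshold-monotone; the original study
likewise reports no CHE estimate for that arm.

### Common random numbers

All strategy arms run on the same cohort with randomness drawn from streams
keyed by (cohort seed, cycle) in a fixed slot order, independent of the
strategy. Paired arms therefore see identical draws and incremental
outcomes difference out shared Monte-Carlo noise; with the odds ratio set
to 1 the increments are exactly zero.

## Synthetic inputs and calibration

The survey-derived inputs of the original study (GBD/SANHANES strata rates,
income parameters, utilization probabilities, PSA distributions) are not
published; this package replaces them with documented synthetic defaults.

* **Strata rates.** Background mortality, diabetes mortality and diabetes
  incidence follow exponential-in-age curves on 5-year bands (held at the
  top band beyond 69 as the cohort ages). Diabetes incidence carries a
  female:male ratio of 1.3 and a per-quintile multiplier found by root
  search so that the expected baseline prevalence of a generated cohort
  (via a deterministic prevalence-by-age recursion) matches the published
  validation anchors: 17.5% (Q1) and 18.4% (Q2); Q3–Q5 use 19.5/20.5/21.5%,
  rising with income as the study discusses.
* **Baseline cascade.** Prevalent diabetics are split
  0.600/0.007/0.196/0.036/0.160 (undiagnosed/diagnosed-untreated/oral/
  insulin/combination; printed values sum to 0.999 and are renormalized),
  anchoring the ~40% diagnosed share.
* **Income.** Per-quintile gamma (shape 2, scale set so the mean sits at
  the band midpoint) rejected to placeholder band boundaries
  120/480/960/1800/3600/14400 USD-2020 per year; the food poverty line is
  40% of the Q1 mean (120 USD/year). Incomes are constant in real terms
  over the horizon.
* **Demography.** Uniform ages 25–69 (a CSV pyramid is configurable), sex
  50/50.
* **Utilization and mortality defaults.** `P_dx = 0.08`/year,
  `P_dt = 0.30`, `P_tna = 0.25`/year, `treated_mortality_multiplier = 0.25`,
  untreated diabetes excess mortality `0.016·exp(0.055·(age−25))`. The
  levels of these five unprinted parameters were calibrated jointly (grid
  search at desk scale) so the default parameterization reproduces the
  study's qualitative findings: treatment-covering strategies are clearly
  cost-effective at USD 3015/DALY and remain so under 50% administrative
  loading, while the diagnosis-only strategy is not. They sit at the
  plausible-but-aggressive end for an untreated, low-control setting and
  are the first knobs to vary in sensitivity analyses.

What the synthetic cohort does **not** emulate: household structure,
income dynamics and quintile mobility, secular trends in incidence or
mortality, complication-specific excess mortality, and the true SA age
pyramid. Passing tests therefore demonstrate internal consistency and
faithful mechanics, not forecasts for the real population.

### A structural note on strategy ordering

In this model the diagnosis and treatment effect channels are nearly
additive: the measured interaction (INMB of the combined arm minus the sum
of the single-service arms) is only about +1 to +2.5 USD per person,
arising solely from the adherence-extension of diagnosis-created treatment
spells. The published results imply a much larger interaction (the
diagnosis component costs ~18 USD per person alone but ~0.4 on top of the
treatment arm). Consequently the pair of inequalities "combined ≥
treatment-only" and "diagnosis-only < 0" can only hold jointly near the
margin: under the defaults both hold in expectation (diagnosis-only ≈ −2,
combined minus treatment ≈ +1 USD per person at n = 50 000) with a per-seed
standard deviation of about 3. The acceptance checks therefore average six
replicate cohorts (seeds 1–6) to compare expectations; single runs can land
on either side of the treatment/combined tie.

## Sensitivity machinery

* **PSA.** Per draw: costs sampled from gammas (mean at the point estimate,
  CV 0.2), cascade and complication probabilities from method-of-moments
  betas (CV 0.2), the odds ratio from the log-normal matched to its 95% CI;
  a fresh cohort per draw, all arms on that cohort. The strata tables and
  their calibration are held at point estimates across draws. Defaults of
  100 draws (and 1000 population replicates) mirror the study; tests and
  the CLI scale down (200 draws at n = 10 000 for the acceptance run).
  Distribution families are asserted, standard-CEA choices, not sourced
  from the unpublished supplement — CVs and families are configurable.
* **CEAC.** At each willingness-to-pay, the fraction of draws in which each
  arm (including no-programme at net benefit 0) attains the highest net
  monetary benefit.
* **One-way.** Dotted-parameter overrides with low/high bounds; built-in
  scenarios: the odds ratio over its CI applied to both channels, diagnosis
  only, treatment only; administrative loading 0 → 50%. Administrative
  loading leaves trajectories untouched, so its INMB effect equals
  admin_fraction × per-person transfer outlay exactly — a closed-form check
  on the machinery.

## Numerical choices and degenerate inputs

Probabilities are validated to [0, 1] at load with the offending key named;
the CHE capacity floor is 1e-6 USD; therapy assignment uses cumulative-share
inversion with the final share absorbing rounding; a zero prevalence target
zeroes the incidence cells; an infeasible calibration raises with the
closest achievable prevalence; ICERs with zero health difference return an
undefined signal rather than a ratio, and dominance is flagged instead of
reporting negative ratios. Money in human-readable CSVs is written at six
significant digits for byte-identical reruns.

## Known limitations

Annual cycles cannot represent within-year timing (no half-cycle
correction; full-year transfers to mid-year dropouts). One complication at
most per cycle, occupying the cycle alone. No complication-specific
mortality beyond stratum diabetes mortality. Horizon truncation
understates the value of late-life benefits. The calibrated mortality and
utilization defaults are identifiable only jointly — other combinations
reproduce the same anchors — so absolute magnitudes (total costs, DALYs,
CHE counts) are illustrative; incremental orderings and the arithmetic
identities are the reproducible content.
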