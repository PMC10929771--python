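"""Published point estimates from the South African CCT evaluation.

Per-person incremental costs and DALYs averted, INMB, totals and CHE cases
averted reported by the study this model family replicates, as printed
(USD 2020; DALYs per eligible person; counts on the represented-population
scale). Used as fixed inputs for arithmetic cross-checks (INMB identity,
denominator recovery), never as model outputs.
"""

from __future__ import annotations

__all__ = ["CE_THRESHOLD", "REFERENCE_ROWS", "ABSTRACT_BEST_INMB",
           "REPRESENTED_ELIGIBLE_MILLIONS"]

#: USD per DALY averted (South African supply-side threshold).
CE_THRESHOLD = 3015.0

#: Printed incremental outcomes per strategy and eligibility scenario.
#: Keys: (eligibility, strategy); eligibility "q1" = quintile 1 only,
#: "q1q2" = quintiles 1 and 2.
REFERENCE_ROWS: dict[tuple[str, str], dict[str, float]] = {
    ("q1", "diagnosis"): {
        "cost_total": 110_144_690.0, "cost_pp": 18.41,
        "dalys_total": 3_253.0, "dalys_pp": 0.000544,
        "inmb": -16.77, "inmb_female": -24.76, "inmb_male": -19.79,
    },
    ("q1", "diagnosis_treatment"): {
        "cost_total": 69_380_988.0, "cost_pp": 11.59,
        "dalys_total": 65_277.0, "dalys_pp": 0.0109,
        "inmb": 21.29, "inmb_female": 40.06, "inmb_male": 15.92,
        "oop_averted": 8_715_456.0,
        "che_averted": {0.10: 104_403.0, 0.25: 78_080.0, 0.40: 60_445.0},
    },
    ("q1", "treatment"): {
        "cost_total": 67_071_454.0, "cost_pp": 11.21,
        "dalys_total": 59_330.0, "dalys_pp": 0.00991,
        "inmb": 18.68, "inmb_female": 34.87, "inmb_male": 14.26,
        "oop_averted": 3_984_548.0,
        "che_averted": {0.10: 34_968.0, 0.25: 27_812.0, 0.40: 22_241.0},
    },
    ("q1q2", "diagnosis"): {
        "cost_total": 235_578_120.0, "cost_pp": 19.68,
        "dalys_total": 7_487.0, "dalys_pp": 0.000626,
        "inmb": -17.80, "inmb_female": -23.66, "inmb_male": -23.80,
    },
    ("q1q2", "diagnosis_treatment"): {
        "cost_total": 154_964_495.0, "cost_pp": 12.95,
        "dalys_total": 137_698.0, "dalys_pp": 0.0115,
        "inmb": 21.74, "inmb_female": 36.23, "inmb_male": 21.22,
        "oop_averted": 19_005_489.0,
        "che_averted": {0.10: 156_682.0, 0.25: 84_794.0, 0.40: 60_738.0},
    },
    ("q1q2", "treatment"): {
        "cost_total": 148_835_236.0, "cost_pp": 12.44,
        "dalys_total": 124_300.0, "dalys_pp": 0.0104,
        "inmb": 18.88, "inmb_female": 31.90, "inmb_male": 17.96,
        "oop_averted": 8_475_607.0,
        "che_averted": {0.10: 55_213.0, 0.25: 30_317.0, 0.40: 22_246.0},
    },
}

#: Headline best-strategy INMB per person as rounded in the study abstract.
ABSTRACT_BEST_INMB = 22.0

#: Approximate represented eligible population (millions) when both bottom
#: quintiles are covered.
REPRESENTED_ELIGIBLE_MILLIONS = 12.0
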