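"""Published summary counts from the RoMMa multi-institutional validation study.

These small tables are the desk-scale inputs for the concordance, outcome,
and cost analyses: cumulative band-agreement counts for the validation
population (620 cases) and the original test population (283 cases), the
2x2 contingency of amMs <= 18 against ODXRS < 26 over the combined
population (903 cases), recurrence counts by risk stratum and by
lymphovascular invasion from the outcome population, and the cost-scenario
defaults. Band-count rows are (group label, n ODX high, n ODX intermediate,
n ODX low); groups are cumulative and restricted to cases with an available
Ki-67.
"""

from __future__ import annotations

__all__ = [
    "VALIDATION_BAND_COUNTS",
    "ORIGINAL_BAND_COUNTS",
    "TOTAL_POPULATION_2X2",
    "LVI_RECURRENCE_COUNTS",
    "RECURRENCE_BY_STRATUM",
    "COST_DEFAULTS",
]

VALIDATION_BAND_COUNTS = [
    ("amMs <9", 0, 0, 4),
    ("amMs <=10", 0, 2, 22),
    ("amMs <=11", 0, 7, 45),
    ("amMs <=12", 0, 13, 84),
    ("amMs <=14", 0, 22, 125),
    ("amMs <=15", 1, 36, 206),
    ("amMs <18", 1, 63, 261),
    ("histologic low risk", 0, 11, 56),
    ("amMs >30", 17, 0, 0),
]

ORIGINAL_BAND_COUNTS = [
    ("amMs <9", 0, 0, 5),
    ("amMs <=10", 0, 2, 21),
    ("amMs <=11", 0, 5, 31),
    ("amMs <=12", 0, 9, 43),
    ("amMs <=14", 0, 12, 61),
    ("amMs <=15", 0, 26, 96),
    ("amMs <18", 0, 42, 116),
    ("histologic low risk", 0, 4, 34),
    ("amMs >30", 8, 0, 0),
]

#: Test rule amMs <= 18 against reference ODXRS < 26 over all 903 cases.
TOTAL_POPULATION_2X2 = {"tp": 524, "fp": 13, "fn": 233, "tn": 133}

#: Lymphovascular invasion among recurred vs non-recurred patients
#: (evaluable LVI status only).
LVI_RECURRENCE_COUNTS = {
    "recurred_with": 7,
    "recurred_total": 17,
    "not_recurred_with": 28,
    "not_recurred_total": 276,
}

#: (n recurred, n patients) per risk stratum in the outcome population.
RECURRENCE_BY_STRATUM = {
    "amms_le12_low_risk": (1, 55),
    "histologic_low_risk": (1, 38),
    "odx_lt11": (1, 49),
    "odx_11_17": (9, 117),
    "odx_18_30": (5, 112),
    "odx_lt26": (12, 258),
    "odx_gt30": (3, 23),
    "filtered_romma_low_risk": (1, 45),
    "filtered_odx_low_risk": (8, 116),
}

COST_DEFAULTS = {
    "list_price_usd": 4620,
    "n_avoided_institutional": 213,
    "cohort_n": 903,
    "frac_low": 0.208,
    "frac_high": 0.028,
    "national_reports": 126740,
    "breast_fraction": 0.85,
}
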