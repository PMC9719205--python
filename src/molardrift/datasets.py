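"""Bundled summary statistics of a clinical unopposed-molar cohort.

Tooth-level summaries (n = 68 unopposed molars, 59 patients, mean
observation 9.1 months) from a retrospective CBCT study of positional
change after antagonist extraction.  Only published summary statistics
are bundled — no patient-level data exist in this package — and they are
used by the worked example and the reproduction script to recompute the
derived quantities (percentages, t statistics) rather than restate them.
"""

from __future__ import annotations

N_TEETH = 68
N_PATIENTS = 59

#: outcome -> (mean, sd, min, max) at tooth level; OE in mm, tipping in degrees
OUTCOME_SUMMARY = {
    "OE_mean": {"mean": 0.432, "sd": 0.432, "min": -0.410, "max": 1.920, "unit": "mm"},
    "OE_max": {"mean": 0.753, "sd": 0.523, "min": 0.034, "max": 2.555, "unit": "mm"},
    "cMDT": {"mean": -0.487, "sd": 2.180, "min": -6.247, "max": 4.053, "unit": "deg"},
    "cBLT": {"mean": -1.717, "sd": 3.802, "min": -11.705, "max": 9.207, "unit": "deg"},
}

#: categorical counts at tooth level
CATEGORY_COUNTS = {
    "sex": {"male": 48, "female": 20},
    "arch": {"maxilla": 47, "mandible": 21},
    "molar_type": {
        "upper-first": 14,
        "upper-second": 33,
        "lower-first": 7,
        "lower-second": 14,
    },
}

#: continuous sample characteristics: mean, sd
SAMPLE_CHARACTERISTICS = {
    "age_years": {"mean": 48.8, "sd": 8.5},
    "t_n_months": {"mean": 9.1, "sd": 4.3},
}

#: reported duplicate-measurement repeatability of the method
METHOD_ERROR = {
    "dahlberg_mm": {"OE_mean": 0.074, "OE_max": 0.092},
    "icc": {"OE_mean": 0.965, "OE_max": 0.973},
    "n_subjects": 10,
}
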