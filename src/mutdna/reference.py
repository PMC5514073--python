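"""Published reference-cohort values the default scenario emulates.

These are the printed clinical quantities from the 17-patient
muscle-invasive bladder cancer NAC cohort that motivates this package's
defaults: the cycle-2 detection-vs-recurrence 2x2 table, the eight
time-to-recurrence values, and the pre-NAC per-fluid detection counts.
They serve as *inputs* to the verification command, which recomputes the
derived metrics from them and checks the arithmetic against the printed
summaries.
"""

from __future__ import annotations

#: Cycle-2 mutDNA presence vs recurrence among the 12 evaluable patients:
#: detected in 5/6 recurrers, 0/6 recurrence-free patients.
CYCLE2_COUNTS = {"tp": 5, "fp": 0, "fn": 1, "tn": 6}

#: Time to recurrence (days from initial resection) for the 8 recurrers.
RECURRENCE_DAYS = (264, 269, 283, 293, 378, 466, 472, 507)

#: Pre-NAC mutDNA detection per fluid: (detected, tested) over 17 patients.
PRE_NAC_DETECTED = {"PLS": (6, 17), "UCP": (8, 17), "USN": (9, 17)}

#: Printed summary values the verification command checks against.
EXPECTED = {
    "sensitivity_percent": 83.3,
    "specificity_percent": 100.0,
    "ppv_percent": 100.0,
    "npv_percent": 85.7,
    "sensitivity_ci_lower_percent": 36,
    "recurrence_median_days": 336,
    "recurrence_min_days": 264,
    "recurrence_max_days": 507,
    "prenac_PLS_percent": 35.3,
    "prenac_UCP_percent": 47.1,
    "prenac_USN_percent": 52.9,
}
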