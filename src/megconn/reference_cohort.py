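"""Published validation fixtures: demographics and cognitive-score summaries
of a BECTS MEG cohort (22 newly diagnosed patients, 18 matched healthy
controls).

The raw recordings behind this cohort are not public, but its printed
demographic table and WISC-IV group summaries are, and they pin down exact
expected values for the demographic summaries and the pooled two-sample t
statistic.  The printed t values for PSI and WMI are not consistent with the
printed means/SDs under either the pooled or the Welch formula (WMI's
recomputed value in fact matches PSI's printed one, suggesting a column
swap), so only VCI, PRI and FSIQ are usable as exact fixtures.
"""

from __future__ import annotations

import pandas as pd

# Per-patient clinical table: sex, age (years), epilepsy course (months),
# seizure count, spike lateralization, days since last seizure.
PATIENT_TABLE = pd.DataFrame(
    {
        "patient": range(1, 23),
        "sex": ["M", "M", "M", "F", "M", "M", "F", "F", "F", "M", "F",
                "F", "M", "F", "M", "F", "M", "M", "M", "F", "F", "F"],
        "age": [6, 10, 9, 8, 9, 11, 12, 6, 10, 10, 8,
                7, 8, 8, 7, 6, 6, 8, 6, 7, 9, 8],
        "course_months": [0.50, 0.90, 1.60, 0.90, 0.20, 0.70, 1.50, 0.90,
                          2.10, 0.80, 3.00, 2.20, 1.20, 1.50, 1.60, 0.70,
                          0.50, 0.70, 0.20, 0.20, 1.90, 2.10],
        "n_seizures": [1, 2, 2, 1, 1, 2, 2, 3, 2, 1, 3,
                       2, 2, 3, 3, 2, 2, 2, 1, 1, 3, 4],
        "spike_side": ["L", "L", "Both", "R", "R", "L", "L", "L", "R", "Both",
                       "L", "L", "R", "R", "Both", "Both", "Both", "L", "R",
                       "L", "R", "R"],
        "days_since_seizure": [5, 5, 3, 3, 3, 3, 3, 3, 5, 4, 3,
                               3, 5, 5, 3, 4, 3, 3, 4, 3, 4, 3],
    }
)

# Printed group demographics.
PATIENT_N = 22
CONTROL_N = 18
PATIENT_AGE_MEAN, PATIENT_AGE_SD = 8.14, 1.73
CONTROL_AGE_MEAN, CONTROL_AGE_SD = 7.94, 1.89
PATIENT_MALE, PATIENT_FEMALE = 11, 11
CONTROL_MALE, CONTROL_FEMALE = 10, 8

# WISC-IV group summaries: score -> (patient mean, patient SD,
#                                    control mean, control SD).
SCORE_SUMMARY = {
    "VCI": (83.86, 12.53, 111.89, 11.88),
    "PRI": (84.82, 12.63, 107.33, 12.53),
    "PSI": (88.41, 11.02, 101.44, 8.60),
    "WMI": (82.55, 8.42, 98.11, 11.74),
    "FSIQ": (84.64, 9.07, 109.22, 10.87),
}

# Printed pooled t values.  Only the consistent ones serve as exact fixtures.
PRINTED_T = {"VCI": -7.2, "PRI": -5.6, "PSI": -4.9, "WMI": -5.7, "FSIQ": -7.8}
CONSISTENT_T_SCORES = ("VCI", "PRI", "FSIQ")
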