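"""Reference clinical characteristics of a severe-preeclampsia cohort.

Published demographic/clinical summary of a 64-sample maternal-serum
lipidomics cohort (44 severe preeclampsia cases, 20 full-term controls).
These printed counts and group summaries serve two purposes: they are the
default confounder distributions of the synthetic cohort generator, and
they are the inputs for reproducing the cohort's contingency-table and
t-test statistics without access to the raw (undeposited) data.

Counts are stored as ``{level: (n_control, n_case)}``; continuous
variables as ``(mean, sd)`` per group.
"""

N_CONTROL = 20
N_CASE = 44

#: Continuous covariates: {variable: {"control": (mean, sd), "case": (mean, sd)}}
CONTINUOUS = {
    "maternal_age": {"control": (27.50, 6.52), "case": (29.27, 6.79)},
    "bmi": {"control": (29.37, 6.82), "case": (29.28, 7.06)},
    "gestational_age": {"control": (39.10, 0.85), "case": (35.82, 2.89)},
}

#: Categorical covariates: {variable: {level: (n_control, n_case)}}
CATEGORICAL = {
    "parity": {"0": (10, 20), "1": (1, 13), "2": (8, 5), "3+": (1, 6)},
    "smoker": {"yes": (0, 7), "no": (20, 37)},
    "ethnicity": {"asian": (13, 22), "caucasian": (2, 6),
                  "latin": (2, 1), "pacific_island": (3, 15)},
    "baby_gender": {"male": (8, 24), "female": (12, 20)},
    "gestational_diabetes": {"yes": (0, 11), "no": (20, 33)},
    "chronic_hypertension": {"yes": (1, 11), "no": (19, 33)},
    "membrane_rupture": {"yes": (9, 12), "no": (11, 32)},
    "abruption": {"yes": (0, 3), "no": (20, 41)},
    "neonatal_malformation": {"yes": (0, 3), "no": (20, 41)},
}

#: The ~15 lipid classes typical of an untargeted serum lipidomics panel,
#: with rough proportions of the 729 detected species.  OxPC/OxPE are the
#: oxidized phospholipid classes whose co-regulation differs by condition.
LIPID_CLASS_PROPORTIONS = {
    "TAG": 0.22, "PC": 0.16, "PE": 0.09, "LPC": 0.07, "LPE": 0.05,
    "OxPC": 0.07, "OxPE": 0.06, "DAG": 0.06, "CE": 0.05, "Cer": 0.05,
    "SM": 0.05, "PI": 0.03, "PG": 0.02, "PA": 0.01, "MAG": 0.01,
}


def categorical_table(variable: str):
    """Return the R x 2 count matrix (rows = levels, cols = control/case)."""
    levels = CATEGORICAL[variable]
    return [[c, k] for c, k in levels.values()], list(levels)
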