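"""Reference NTCP parameter sets for radiation-induced pericardial effusion.

Fitted values reported for a 229-patient oesophageal-cancer cohort treated
with definitive concurrent chemoradiotherapy (conventional fractionation),
for pericardial effusion of any grade (A-PCE) and symptomatic, CTCAE
grade >= 3, effusion (S-PCE).  They serve as truth models for the synthetic
cohort generator and as inputs to the reference TD/NTCP tables.
"""

from .models import LKBParameters, LogisticModel

# Logistic models (per-Gy MHD coefficient; HTN = hypertension indicator).
APCE_LOGISTIC = LogisticModel(intercept=-2.513, coefficients={"mhd": 0.073})
SPCE_LOGISTIC = LogisticModel(
    intercept=-7.240, coefficients={"mhd": 0.161, "hypertension": -1.858}
)

# MHD-based probit models (the n = 1 reduction of the LKB model).
APCE_MHD_PROBIT = LKBParameters(n=1.0, m=0.75, td50=34.3)
SPCE_MHD_PROBIT = LKBParameters(n=1.0, m=0.26, td50=56.5)

# Full gEUD-based LKB models.
APCE_LKB = LKBParameters(n=0.38, m=0.47, td50=41.0)
SPCE_LKB = LKBParameters(n=0.36, m=0.19, td50=57.7)

# Odds ratios as printed alongside the logistic coefficients.
PRINTED_ODDS_RATIOS = {
    ("any", "mhd"): 1.076,
    ("symptomatic", "mhd"): 1.174,
    ("symptomatic", "hypertension"): 0.156,
}

# Cohort-level summaries used as synthetic-generator targets.
COHORT_SIZE = 229
APCE_INCIDENCE = 0.437
SPCE_INCIDENCE = 0.079
HTN_PREVALENCE = 0.301
MHD_MEDIAN_GY = 32.2
MHD_RANGE_GY = (0.46, 56.9)

PROBIT_MODELS = {
    ("any", "mhd"): APCE_MHD_PROBIT,
    ("symptomatic", "mhd"): SPCE_MHD_PROBIT,
    ("any", "lkb"): APCE_LKB,
    ("symptomatic", "lkb"): SPCE_LKB,
}
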