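"""Column names, cognitive-domain map, and cohort-level default moments.

The cohort rectangle has one row per subject and a fixed, documented schema:
five neurovascular-unit (NVU) function measures, thirteen neuropsychological
test scores, five covariates, plus ``subject_id`` and an ``excluded`` artefact
flag.  All defaults are on the printed reporting scale of the source cohort
(e.g. Ki in 1e-4 min^-1, volume fractions in percent).

The cognitive battery spans three domains.  Note the battery is thirteen
tests: memory carries the three RAVLT scores, executive function six tests,
and psychomotor speed four.
"""

from __future__ import annotations

NVU_VARS: list[str] = ["ki", "vl", "f", "dstar", "f_int"]

MEMORY_TESTS: list[str] = [
    "ravlt_immediate",
    "ravlt_delayed",
    "ravlt_recognition",
]
EXECUTIVE_TESTS: list[str] = [
    "tmt_interference",
    "scwt_interference",
    "fluency_categories",
    "fluency_letters",
    "letter_number_sequencing",
    "digit_span_backward",
]
SPEED_TESTS: list[str] = [
    "tmt_a",
    "scwt_i",
    "scwt_ii",
    "symbol_substitution",
]

COG_VARS: list[str] = MEMORY_TESTS + EXECUTIVE_TESTS + SPEED_TESTS

DOMAIN_MAP: dict[str, str] = {
    **{t: "memory" for t in MEMORY_TESTS},
    **{t: "executive" for t in EXECUTIVE_TESTS},
    **{t: "speed" for t in SPEED_TESTS},
}
DOMAINS: list[str] = ["memory", "executive", "speed"]

#: Tests where a higher raw score means *worse* performance; these are negated
#: before entering any multivariate analysis so that every column reads
#: "higher = better".
INVERTED_VARS: list[str] = [
    "tmt_interference",
    "scwt_interference",
    "tmt_a",
    "scwt_i",
    "scwt_ii",
]

COVARIATES: list[str] = ["age", "sex", "education", "rel_brain_vol", "rel_wmh_vol"]

ADJUSTMENT_SETS: dict[str, list[str]] = {
    "none": [],
    "age_sex_edu": ["age", "sex", "education"],
    "age_sex_edu_brain_wmh": [
        "age",
        "sex",
        "education",
        "rel_brain_vol",
        "rel_wmh_vol",
    ],
}

# ---------------------------------------------------------------------------
# Marginal moments (mean, SD) of the reference cSVD cohort, reporting scale.
# NVU measures are ROI averages; "nawm" = normal-appearing white matter,
# "wmh" = white matter hyperintensities.
# ---------------------------------------------------------------------------

NVU_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "nawm": {
        "ki": (3.3, 1.6),        # BBB leakage rate, 1e-4 min^-1
        "vl": (35.7, 16.5),      # BBB leakage volume, %
        "f": (1.1, 0.1),         # perfusion volume fraction, %
        "dstar": (10.0, 0.1),    # microvascular diffusivity, 1e-2 mm^2/s
        "f_int": (9.3, 0.4),     # intermediate volume fraction, %
    },
    "wmh": {
        "ki": (3.6, 2.0),
        "vl": (42.0, 20.1),
        "f": (1.6, 0.2),
        "dstar": (9.4, 0.3),
        "f_int": (17.7, 2.9),
    },
}

COG_MARGINALS: dict[str, tuple[float, float]] = {
    "ravlt_immediate": (32.1, 10.3),
    "ravlt_delayed": (5.4, 3.5),
    "ravlt_recognition": (11.4, 3.2),
    "tmt_interference": (118.5, 100.8),
    "scwt_interference": (87.5, 53.0),
    "fluency_categories": (30.3, 10.6),
    "fluency_letters": (24.8, 12.6),
    "letter_number_sequencing": (6.7, 3.3),
    "digit_span_backward": (5.3, 1.7),
    "tmt_a": (66.1, 34.5),
    "scwt_i": (57.8, 14.8),
    "scwt_ii": (76.3, 20.1),
    "symbol_substitution": (42.5, 18.7),
}

#: Covariate generator settings (age in years, Verhage education 1-7,
#: relative volumes as fractions of intracranial volume).
COVARIATE_PARAMS: dict[str, dict[str, float]] = {
    "age": {"mean": 70.2, "sd": 10.8},
    "sex": {"p_female": 0.411},
    "education": {"mean": 4.5, "sd": 1.0, "lo": 1, "hi": 7},
    "rel_brain_vol": {"mean": 0.75, "sd": 0.04},
    "rel_wmh_vol": {"log_median": -4.68, "log_sd": 0.85},
}

# ---------------------------------------------------------------------------
# Default planted latent structure.
#
# NVU set: one common NVU-function factor with equal loadings c_x on all five
# measures.  With unit marginal variance the population variance extracted by
# the first canonical variate is (1 + 4 c_x^2)/5, so c_x = sqrt(0.05) plants
# variance extracted 24.0%.
#
# Cognition set: a general cognition factor (loading COG_G_LOADING on every
# test) correlated rho_1 with the NVU factor, plus three mutually independent
# domain factors (loading COG_DOMAIN_LOADING within each domain) that carry
# within-domain correlation but no cross-set correlation.  COG_G_LOADING was
# solved numerically so the population variance extracted by the first
# cognition variate is 23.1%.
# ---------------------------------------------------------------------------

NVU_G_LOADING: float = 0.223606797749979  # sqrt(0.05)
COG_G_LOADING: float = 0.42086221023042186
COG_DOMAIN_LOADING: float = 0.35

DEFAULT_RHO: tuple[float, ...] = (0.73, 0.0, 0.0, 0.0, 0.0)
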