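"""Printed headline values and cohort-table cell counts used as worked-example
inputs.

The underlying cohorts are access-restricted, but the published report prints
(a) per-cohort case/control counts for every outcome, (b) the 2x2 cross
tabulations of in-pregnancy insomnia against each outcome in the ALSPAC
multivariable-regression sample, and (c) combined MR odds ratios with 95%
CIs.  Those printed numbers are re-usable inputs: the tabulation and
meta-analysis machinery can be run against them and must get the printed
derived quantities back.

``synthetic_per_source_decomposition`` is a *synthetic* stand-in for the
per-source MR estimates (which live in restricted supplementary material):
it splits a printed combined estimate into per-study components whose
fixed-effects pooling recovers it, which exercises the pooling machinery but
is not a reproduction from raw per-source data.
"""

from __future__ import annotations

import numpy as np

from .meta import StudyEstimate

#: outcome case/control counts per cohort ("History of ..." rows use the
#: shared control pool of women with complete pregnancy history)
OUTCOME_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "UKB": {
        "stillbirth": (4_907, 139_034),
        "miscarriage": (42_717, 139_034),
        "gestational_diabetes": (726, 200_536),
        "hdp": (2_138, 206_002),
        "perinatal_depression": (5_178, 25_130),
        "preterm_birth": (556, 4_862),
        "low_birthweight": (13_429, 149_084),
        "high_birthweight": (2_716, 149_084),
    },
    "ALSPAC": {
        "stillbirth": (48, 4_546),
        "miscarriage": (1_378, 4_546),
        "gestational_diabetes": (34, 6_283),
        "hdp": (1_099, 5_698),
        "perinatal_depression": (423, 5_896),
        "preterm_birth": (285, 4_931),
        "low_birthweight": (337, 6_376),
        "high_birthweight": (113, 6_376),
    },
    "BiB": {
        "stillbirth": (31, 2_588),
        "miscarriage": (14, 2_588),
        "gestational_diabetes": (136, 2_657),
        "hdp": (347, 2_159),
        "perinatal_depression": (312, 2_245),
        "preterm_birth": (172, 2_706),
        "low_birthweight": (167, 2_725),
        "high_birthweight": (42, 2_725),
    },
    "MoBa": {
        "stillbirth": (51, 9_998),
        "miscarriage": (2_677, 9_998),
        "gestational_diabetes": (113, 14_375),
        "hdp": (1_892, 12_652),
        "perinatal_depression": (579, 13_865),
        "preterm_birth": (495, 12_846),
        "low_birthweight": (245, 13_690),
        "high_birthweight": (621, 13_690),
    },
    "FinnGen": {
        "miscarriage": (9_113, 89_340),
        "gestational_diabetes": (5_687, 117_892),
        "hdp": (4_255, 114_735),
        "preterm_birth": (5_480, 98_626),
    },
}

#: ALSPAC multivariable-regression sample (N = 10,540): 2x2 cells per outcome
#: as (cases_insomnia, cases_no_insomnia, controls_insomnia, controls_no_insomnia)
ALSPAC_2X2: dict[str, tuple[int, int, int, int]] = {
    "gestational_diabetes": (8, 36, 1_538, 8_210),
    "hdp": (295, 1_403, 1_393, 7_389),
    "perinatal_depression": (242, 460, 1_207, 7_759),
    "preterm_birth": (79, 369, 1_170, 6_324),
    "low_birthweight": (90, 421, 1_578, 8_263),
    "high_birthweight": (28, 160, 1_578, 8_263),
}

ALSPAC_REGRESSION_N = 10_540

#: combined (all-cohort) IVW odds ratios with 95% CIs, as printed
COMBINED_IVW_OR: dict[str, tuple[float, float, float]] = {
    "miscarriage": (1.60, 1.18, 2.17),
    "perinatal_depression": (3.56, 1.49, 8.54),
    "low_birthweight": (3.17, 1.69, 5.96),
    "gestational_diabetes": (1.20, 0.52, 2.77),
}

#: exposure-instrument strength as printed: 81 SNPs, 0.42% of insomnia
#: variance in 208,140 women, mean F-statistic 11, insomnia prevalence ~28%
N_INSTRUMENTS = 81
EXPOSURE_GWAS_N = 208_140
INSTRUMENT_TOTAL_R2 = 0.0042
EXPOSURE_PREVALENCE = 0.28

Z95 = 1.96


def estimate_from_or_ci(or_: float, ci_low: float, ci_high: float,
                        ) -> tuple[float, float]:
    """(log-OR, SE) implied by a printed OR with a symmetric 95% Wald CI."""
    beta = float(np.log(or_))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))
    return beta, se


def synthetic_per_source_decomposition(or_: float, ci_low: float,
                                       ci_high: float,
                                       labels: tuple[str, str] = ("UKB-split",
                                                                  "non-UKB"),
                                       weight_fraction: float = 0.6,
                                       spread: float = 0.5,
                                       ) -> list[StudyEstimate]:
    """Synthetic two-source split of a printed combined estimate.

    Divides the combined precision W = 1/se² into fractions (w, 1-w) and
    offsets the two component betas by ±spread·se/fraction so they differ
    while their inverse-variance-weighted mean equals the combined log-OR
    exactly.  Purely a stand-in for unavailable per-source estimates.
    """
    beta, se = estimate_from_or_ci(or_, ci_low, ci_high)
    w_total = 1.0 / se**2
    w1, w2 = weight_fraction * w_total, (1.0 - weight_fraction) * w_total
    delta = spread * se
    beta1 = beta + delta * w_total / (2.0 * w1)
    beta2 = beta - delta * w_total / (2.0 * w2)
    return [StudyEstimate(labels[0], beta1, w1 ** -0.5),
            StudyEstimate(labels[1], beta2, w2 ** -0.5)]
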