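"""Published marginal summaries of the motivating cohort.

The motivating application is a national English administrative cohort of
emergency admissions for acute appendicitis in adults with multiple long-term
conditions (MLTC, >=2 of 28 defined comorbidities), N = 24,312, comparing
non-emergency surgery strategies (NES: antibiotics and/or delayed surgery)
against emergency surgery (ES).  The record-level extract is not public; the
constants below are the published arm totals, baseline-characteristic counts
and comorbidity prevalences, used (a) to parameterise the synthetic cohort
generator so simulated cohorts share the study's marginals and (b) for the
rate arithmetic reproduced by the acceptance checks.

Counts are admissions; percentages in comments are as printed in the source
tables (rounded).
"""

from __future__ import annotations

# Arm totals
N_ES = 20_669
N_NES = 3_643
N_TOTAL = N_ES + N_NES  # 24,312

# Baseline characteristics: (ES count, NES count)
AGE_BAND_COUNTS = {
    "under_60": (11_337, 1_195),  # 55% / 33%
    "60_74": (6_089, 1_151),      # 29% / 32%
    "75_plus": (3_243, 1_297),    # 16% / 36%
}
FRAILTY_COUNTS = {"not_frail": (18_292, 3_132), "frail": (2_377, 511)}
SEX_COUNTS = {"male": (9_951, 1_766), "female": (10_718, 1_877)}
ETHNICITY_COUNTS = {
    "unknown": (1_425, 178),
    "white": (17_630, 3_149),
    "black": (392, 91),
    "asian": (833, 171),
    "other": (389, 54),
}
IMD_COUNTS = {  # quintile 1 = most deprived
    1: (3_689, 633),
    2: (4_010, 725),
    3: (4_151, 710),
    4: (4_231, 728),
    5: (4_363, 810),
}

# 28 MLTC-defining comorbidities: carrier count and % NES among carriers,
# plus whether clinicians rated the item at least medium priority ("selected")
# in the expert survey of the motivating study.
COMORBIDITY_TABLE = {
    # name: (carriers, pct_nes, clinically_selected)
    "alcohol_misuse": (1_847, 11, False),
    "asthma": (6_569, 11, False),
    "atrial_fibrillation": (170, 24, False),
    "cancer": (734, 25, True),
    "chronic_heart_failure": (1_104, 34, True),
    "chronic_kidney_disease": (3_665, 23, True),
    "chronic_pain": (2_725, 14, False),
    "chronic_pulmonary_disease": (2_948, 21, True),
    "chronic_viral_hepatitis_b": (194, 28, False),
    "cirrhosis": (938, 8, True),
    "dementia": (405, 42, True),
    "depression": (5_213, 10, False),
    "diabetes": (6_383, 19, True),
    "epilepsy": (1_042, 12, False),
    "hypertension": (13_046, 17, False),
    "hypothyroidism": (3_369, 13, False),
    "inflammatory_bowel_disease": (702, 16, True),
    "irritable_bowel_syndrome": (1, 0, False),
    "multiple_sclerosis": (200, 9, False),
    "myocardial_infarction": (74, 12, False),
    "parkinsons_disease": (170, 25, False),
    "peptic_ulcer_disease": (142, 20, False),
    "peripheral_vascular_disease": (2_168, 17, False),
    "psoriasis": (381, 12, False),
    "rheumatoid_arthritis": (1_065, 17, False),
    "schizophrenia": (300, 13, False),
    "severe_constipation": (2_559, 13, False),
    "stroke": (42, 14, True),
}

COMORBIDITIES = tuple(COMORBIDITY_TABLE)


def comorbidity_prevalences() -> dict[str, float]:
    """Carrier share of each comorbidity in the published cohort."""
    return {k: v[0] / N_TOTAL for k, v in COMORBIDITY_TABLE.items()}


def clinically_selected() -> list[str]:
    """Comorbidities the expert panel rated at least medium priority."""
    return [k for k, v in COMORBIDITY_TABLE.items() if v[2]]


def _probs(counts: dict) -> dict:
    tot = sum(e + n for e, n in counts.values())
    return {k: (e + n) / tot for k, (e, n) in counts.items()}


def age_band_probs() -> tuple[float, float, float]:
    p = _probs(AGE_BAND_COUNTS)
    return (p["under_60"], p["60_74"], p["75_plus"])


def female_prob() -> float:
    return _probs(SEX_COUNTS)["female"]


def frailty_prob() -> float:
    return _probs(FRAILTY_COUNTS)["frail"]


def ethnicity_probs() -> tuple[float, ...]:
    return tuple(_probs(ETHNICITY_COUNTS).values())


def imd_probs() -> tuple[float, ...]:
    return tuple(_probs(IMD_COUNTS).values())


def nes_share() -> float:
    """Overall share of admissions managed with NES strategies (~0.15)."""
    return N_NES / N_TOTAL


def arm_percentages() -> dict[str, float]:
    """Within-arm percentage composition of the published cohort.

    Recomputes, from the raw counts, the percentages printed alongside them:
    e.g. the share of ES admissions aged under 60, or the NES share overall.
    Keys are '<arm>_<characteristic>_pct' plus 'nes_share_pct'.
    """
    out = {"nes_share_pct": 100.0 * N_NES / N_TOTAL}
    for band, (es, nes) in AGE_BAND_COUNTS.items():
        out[f"es_age_{band}_pct"] = 100.0 * es / N_ES
        out[f"nes_age_{band}_pct"] = 100.0 * nes / N_NES
    for level, (es, nes) in FRAILTY_COUNTS.items():
        out[f"es_{level}_pct"] = 100.0 * es / N_ES
        out[f"nes_{level}_pct"] = 100.0 * nes / N_NES
    for level, (es, nes) in SEX_COUNTS.items():
        out[f"es_{level}_pct"] = 100.0 * es / N_ES
        out[f"nes_{level}_pct"] = 100.0 * nes / N_NES
    return out
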