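"""Published marginal composition of the 2016-22 NDIS applicant and
participant cohorts.

These tables hold the publicly reported counts (and the percentages printed
alongside them) for the eligibility-analysis cohort (485 676 applicants) and
the plan-size/spending cohort (312 268 active participants, split by gender
and by area socio-economic disadvantage).  They serve two purposes:

* calibration targets for the deterministic synthetic-data mode, so the
  cohort filters can be exercised against the exact published flow; and
* a consistency check that percentages recomputed from the counts agree
  with the printed values at printed precision (one decimal place).

Percentages recorded as "< 0.1" in the source tables are stored as the
string ``"<0.1"``; suppressed small cells (count below 15) are omitted.
"""

from __future__ import annotations

import pandas as pd

# ---------------------------------------------------------------------------
# Access-decision flow for the eligibility analysis (applications, age >= 7)
# ---------------------------------------------------------------------------

TOTAL_APPLICATIONS = 705_594
CANCELLED_OR_WITHDRAWN = 136_199
IN_PROGRESS = 52_584
REVOKED_OR_CEASED = 30_444
INCOMPLETE_DEMOGRAPHICS = 691
INCLUDED_APPLICANTS = 485_676
ELIGIBLE = 393_152
INELIGIBLE = 92_524

# Active participants in the plan-size / spending analysis
PARTICIPANTS_WOMEN_GIRLS = 127_125
PARTICIPANTS_OTHER = 185_143
PARTICIPANTS_TOTAL = 312_268
PARTICIPANTS_LOW_SES = 93_341
PARTICIPANTS_OTHER_AREAS = 218_927


def results_flow_targets() -> pd.DataFrame:
    """Exact-count calibration targets reproducing the published access flow.

    The combined cancelled-or-withdrawn line (136 199) is split into an
    arbitrary deterministic pair; the cohort filter removes both types in a
    single step so the combined count is what matters.  The 691 decided
    records with incomplete socio-demographic data are excluded before any
    eligibility tally, so their decision type is immaterial.
    """
    rows = [
        {"decision_type": "access_met", "count": ELIGIBLE},
        {"decision_type": "access_not_met", "count": INELIGIBLE},
        {
            "decision_type": "access_met",
            "count": INCOMPLETE_DEMOGRAPHICS,
            "demographics_complete": False,
        },
        {"decision_type": "cancelled", "count": 90_000},
        {"decision_type": "withdrawn", "count": CANCELLED_OR_WITHDRAWN - 90_000},
        {"decision_type": "in_progress", "count": IN_PROGRESS},
        {"decision_type": "revoked_ceased", "count": REVOKED_OR_CEASED},
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Applicant cohort composition (denominator: 485 676 included applicants)
# ---------------------------------------------------------------------------

APPLICANT_DENOMINATOR = INCLUDED_APPLICANTS

# (section, characteristic, count, printed percent)
APPLICANT_COMPOSITION: list[tuple[str, str, int, float | str]] = [
    ("age_band", "7-14", 126_268, 26.0),
    ("age_band", "15-18", 41_647, 8.6),
    ("age_band", "19-24", 36_463, 7.5),
    ("age_band", "25-34", 50_967, 10.5),
    ("age_band", "35-44", 56_232, 11.6),
    ("age_band", "45-54", 73_712, 15.2),
    ("age_band", "55-64", 100_387, 20.7),
    ("sociodemographic", "women_girls", 210_274, 43.3),
    ("sociodemographic", "indigenous", 32_866, 6.8),
    ("sociodemographic", "low_ses", 150_472, 31.0),
    ("sociodemographic", "regional_remote", 159_416, 32.8),
    ("disability_group", "sensory", 36_197, 7.5),
    ("disability_code", "hearing_impairment", 22_042, 4.5),
    ("disability_code", "visual_impairment", 10_433, 2.1),
    ("disability_code", "other_sensory_speech", 3_722, 0.8),
    ("disability_group", "autism", 125_916, 25.9),
    ("disability_group", "intellectual_other", 91_542, 18.8),
    ("disability_code", "developmental_delay", 337, 0.1),
    ("disability_code", "global_developmental_delay", 155, "<0.1"),
    ("disability_code", "trisomy_21", 9_369, 1.9),
    ("disability_code", "intellectual_disability", 81_681, 16.8),
    ("disability_group", "physical", 66_449, 13.7),
    ("disability_code", "cerebral_palsy", 13_751, 2.8),
    ("disability_code", "spinal_cord_injury", 6_013, 1.2),
    ("disability_code", "other_physical", 46_685, 9.6),
    ("disability_group", "psychosocial", 82_525, 17.0),
    ("disability_group", "brain_injury_stroke", 28_164, 5.8),
    ("disability_code", "acquired_brain_injury", 18_248, 3.8),
    ("disability_code", "stroke", 9_916, 2.0),
    ("disability_group", "other", 54_883, 11.3),
    ("disability_code", "multiple_sclerosis", 10_929, 2.3),
    ("disability_code", "other_neurological", 26_377, 5.4),
    ("disability_code", "other", 17_577, 3.6),
    ("prior_support", "australian_gov", 37_478, 7.7),
    ("prior_support", "state_gov", 161_822, 33.3),
    ("prior_support", "none", 286_376, 59.0),
]


# ---------------------------------------------------------------------------
# Participant cohort composition, by column (four published columns)
# ---------------------------------------------------------------------------

PARTICIPANT_DENOMINATORS = {
    "women_girls": PARTICIPANTS_WOMEN_GIRLS,
    "other_gender": PARTICIPANTS_OTHER,
    "low_ses": PARTICIPANTS_LOW_SES,
    "other_areas": PARTICIPANTS_OTHER_AREAS,
}

# characteristic -> {column: (count, printed percent)}
PARTICIPANT_COMPOSITION: dict[str, dict[str, tuple[int, float]]] = {
    "age_7-14": {
        "women_girls": (20_258, 15.9),
        "other_gender": (45_478, 24.6),
        "low_ses": (18_298, 19.6),
        "other_areas": (47_438, 21.7),
    },
    "age_15-18": {
        "women_girls": (10_174, 8.0),
        "other_gender": (20_333, 11.0),
        "low_ses": (8_978, 9.6),
        "other_areas": (21_529, 9.8),
    },
    "age_19-24": {
        "women_girls": (11_983, 9.4),
        "other_gender": (21_291, 11.5),
        "low_ses": (10_200, 10.9),
        "other_areas": (23_074, 10.5),
    },
    "age_25-34": {
        "women_girls": (15_594, 12.3),
        "other_gender": (22_011, 11.9),
        "low_ses": (11_425, 12.2),
        "other_areas": (26_180, 12.0),
    },
    "age_35-44": {
        "women_girls": (16_648, 13.1),
        "other_gender": (19_759, 10.7),
        "low_ses": (11_098, 11.9),
        "other_areas": (25_309, 11.6),
    },
    "age_45-54": {
        "women_girls": (21_445, 16.9),
        "other_gender": (23_344, 12.6),
        "low_ses": (13_771, 14.8),
        "other_areas": (31_018, 14.2),
    },
    "age_55-64": {
        "women_girls": (31_023, 24.4),
        "other_gender": (32_927, 17.8),
        "low_ses": (19_571, 21.0),
        "other_areas": (44_379, 20.3),
    },
    "gender_women_girls": {
        "low_ses": (37_663, 40.3),
        "other_areas": (89_462, 40.9),
    },
    "indigenous": {
        "women_girls": (7_616, 6.0),
        "other_gender": (12_247, 6.6),
        "low_ses": (8_810, 9.4),
        "other_areas": (11_053, 5.0),
    },
    "low_ses_area": {
        "women_girls": (37_663, 29.6),
        "other_gender": (55_678, 30.1),
    },
    "regional_remote": {
        "women_girls": (41_124, 32.3),
        "other_gender": (60_162, 32.5),
        "low_ses": (46_692, 50.0),
        "other_areas": (54_594, 24.9),
    },
    "group_sensory": {
        "women_girls": (10_499, 8.3),
        "other_gender": (10_061, 5.4),
        "low_ses": (5_887, 6.3),
        "other_areas": (14_673, 6.7),
    },
    "group_autism": {
        "women_girls": (23_800, 18.7),
        "other_gender": (64_809, 35.0),
        "low_ses": (24_158, 25.9),
        "other_areas": (64_451, 29.4),
    },
    "group_intellectual_other": {
        "women_girls": (33_125, 26.1),
        "other_gender": (43_123, 23.3),
        "low_ses": (25_534, 27.4),
        "other_areas": (50_714, 23.2),
    },
    "group_physical": {
        "women_girls": (14_751, 11.6),
        "other_gender": (18_184, 9.8),
        "low_ses": (9_898, 10.6),
        "other_areas": (23_037, 10.5),
    },
    "group_psychosocial": {
        "women_girls": (21_977, 17.3),
        "other_gender": (23_079, 12.5),
        "low_ses": (13_465, 14.4),
        "other_areas": (31_591, 14.4),
    },
    "group_brain_injury_stroke": {
        "women_girls": (7_563, 5.9),
        "other_gender": (12_913, 7.0),
        "low_ses": (6_631, 7.1),
        "other_areas": (13_845, 6.3),
    },
    "group_other": {
        "women_girls": (15_410, 12.1),
        "other_gender": (12_974, 7.0),
        "low_ses": (7_768, 8.3),
        "other_areas": (20_616, 9.4),
    },
    "prior_australian_gov": {
        "women_girls": (11_175, 8.8),
        "other_gender": (17_307, 9.3),
        "low_ses": (8_898, 9.5),
        "other_areas": (19_584, 8.9),
    },
    "prior_state_gov": {
        "women_girls": (58_441, 46.0),
        "other_gender": (85_004, 45.9),
        "low_ses": (43_448, 46.5),
        "other_areas": (99_997, 45.7),
    },
    "prior_none": {
        "women_girls": (57_509, 45.2),
        "other_gender": (82_832, 44.7),
        "low_ses": (40_995, 43.9),
        "other_areas": (99_346, 45.4),
    },
    "severity_1-5": {
        "women_girls": (19_209, 15.1),
        "other_gender": (27_438, 14.8),
        "low_ses": (13_277, 14.2),
        "other_areas": (33_370, 15.2),
    },
    "severity_6-10": {
        "women_girls": (61_643, 48.5),
        "other_gender": (98_393, 53.1),
        "low_ses": (48_710, 52.2),
        "other_areas": (111_326, 50.9),
    },
    "severity_11-15": {
        "women_girls": (46_273, 36.4),
        "other_gender": (59_312, 32.0),
        "low_ses": (31_354, 33.6),
        "other_areas": (74_231, 33.9),
    },
    "years_<=1": {
        "women_girls": (43_333, 34.1),
        "other_gender": (61_004, 32.9),
        "low_ses": (30_756, 33.0),
        "other_areas": (73_581, 33.6),
    },
    "years_1-2": {
        "women_girls": (29_572, 23.3),
        "other_gender": (43_318, 23.4),
        "low_ses": (21_210, 22.7),
        "other_areas": (51_680, 23.6),
    },
    "years_2-3": {
        "women_girls": (26_240, 20.6),
        "other_gender": (38_589, 20.8),
        "low_ses": (19_875, 21.3),
        "other_areas": (44_954, 20.5),
    },
    "years_3-4": {
        "women_girls": (19_090, 15.0),
        "other_gender": (29_163, 15.8),
        "low_ses": (15_170, 16.3),
        "other_areas": (33_083, 15.1),
    },
    "years_>4": {
        "women_girls": (8_890, 7.0),
        "other_gender": (13_069, 7.1),
        "low_ses": (6_330, 6.8),
        "other_areas": (15_629, 7.1),
    },
    "ypirac": {
        "women_girls": (2_420, 1.9),
        "other_gender": (2_911, 1.6),
        "low_ses": (1_583, 1.7),
        "other_areas": (3_748, 1.7),
    },
    "sil": {
        "women_girls": (12_444, 9.8),
        "other_gender": (18_649, 10.1),
        "low_ses": (8_898, 9.5),
        "other_areas": (22_195, 10.1),
    },
    "sda": {
        "women_girls": (9_740, 7.7),
        "other_gender": (14_097, 7.6),
        "low_ses": (6_715, 7.2),
        "other_areas": (17_122, 7.8),
    },
    "trial_plan": {
        "women_girls": (6_712, 5.3),
        "other_gender": (10_770, 5.8),
        "low_ses": (4_163, 4.5),
        "other_areas": (13_319, 6.1),
    },
}


def recompute_applicant_percentages() -> pd.DataFrame:
    """Percentages recomputed from the applicant counts, next to printed ones."""
    rows = []
    for section, name, count, printed in APPLICANT_COMPOSITION:
        computed = 100.0 * count / APPLICANT_DENOMINATOR
        rows.append(
            {
                "section": section,
                "characteristic": name,
                "count": count,
                "computed_pct": computed,
                "printed_pct": printed,
            }
        )
    return pd.DataFrame(rows)


def recompute_participant_percentages() -> pd.DataFrame:
    """Percentages recomputed from the participant counts, next to printed ones."""
    rows = []
    for name, cols in PARTICIPANT_COMPOSITION.items():
        for col, (count, printed) in cols.items():
            computed = 100.0 * count / PARTICIPANT_DENOMINATORS[col]
            rows.append(
                {
                    "characteristic": name,
                    "column": col,
                    "count": count,
                    "computed_pct": computed,
                    "printed_pct": printed,
                }
            )
    return pd.DataFrame(rows)
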