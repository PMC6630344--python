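"""Published descriptive statistics of the reference hospital cohort.

These are the printed summary counts of the original cross-sectional study
of computer-vision syndrome (CVS) in health personnel at two Spanish public
hospitals: stratified prevalence counts, sampling/exclusion accounting, and
the variable-inclusion percentages reported for the 1000-replica feature
selection run.  The raw subject-level data were never deposited, so these
aggregate tables are the only exact anchors available; they are shipped as
constants to test reporting code paths, never recomputed.
"""

from __future__ import annotations

import pandas as pd

# Sampling frame and exclusion accounting
ELIGIBLE_WORKERS = 668
RESPONDENTS = 539
FINAL_SAMPLE = 343
CVS_CASES = 195

#: Exclusion rules in the order they were applied; a subject is attributed
#: to the first rule it trips.
EXCLUSION_COUNTS = {
    "ocular_disease": 66,
    "non_computer_user": 116,
    "out_of_scope_occupation": 13,
    "missing_seniority": 1,
}

#: Ocular-disease sub-reasons; they sum to 91 > 66 because subjects may
#: report several comorbid conditions yet count once under the rule.
OCULAR_DISEASE_SUBREASONS = {
    "dry_eye": 35,
    "amblyopia": 6,
    "squint": 1,
    "conjunctivitis": 22,
    "corneal_ulcers": 5,
    "uncontrolled_cataracts": 5,
    "glaucoma": 1,
    "blepharitis": 2,
    "keratitis": 1,
    "uveitis": 1,
    "vitreous_disorders": 8,
    "retinal_disease": 4,
}

#: Stratified prevalence table: (grouping variable, stratum, n subjects,
#: n symptomatic).  Subject counts per grouping variable sum to 343.
PREVALENCE_STRATA = (
    ("sex", "male", 78, 37),
    ("sex", "female", 265, 158),
    ("age_band", "<=30", 32, 16),
    ("age_band", "31-40", 73, 42),
    ("age_band", "41-50", 93, 62),
    ("age_band", "51-60", 107, 60),
    ("age_band", ">60", 38, 15),
    ("hospital", "HMN", 141, 85),
    ("hospital", "HUCA", 202, 110),
    ("ophthalmic_lens", "no", 101, 49),
    ("ophthalmic_lens", "yes", 242, 146),
    ("contact_lens", "no", 290, 155),
    ("contact_lens", "yes", 53, 40),
    ("ocular_surgery", "no", 309, 173),
    ("ocular_surgery", "yes", 34, 22),
    ("occupational_group", "physicians_and_surgeons", 128, 63),
    ("occupational_group", "nurses", 164, 104),
    ("occupational_group", "nursing_assistants", 51, 28),
    ("work_schedule", "morning", 133, 71),
    ("work_schedule", "evening", 3, 0),
    ("work_schedule", "rotating_without_nights", 24, 14),
    ("work_schedule", "rotating_with_nights", 100, 66),
    ("work_schedule", "morning_plus_on_call", 83, 44),
    ("easy_software", "no", 74, 39),
    ("easy_software", "yes", 269, 156),
    ("vdt_hours_at_work", "<2", 27, 13),
    ("vdt_hours_at_work", "2-4", 112, 67),
    ("vdt_hours_at_work", ">4", 204, 115),
    ("computer_outside_work", "no", 55, 24),
    ("computer_outside_work", "yes", 288, 171),
)

#: Percentage of resampling replicas whose selected feature mask included
#: each variable (the study's importance measure; 30 variables reported,
#: out of 255 encoded predictors).
INCLUSION_PERCENTAGES = (
    ("occupational_seniority_years", 97.20),
    ("vdt_hours_at_work", 96.90),
    ("hospital_unit_seniority_years", 96.30),
    ("conjunctivitis_history", 88.50),
    ("eye_drop_use", 79.80),
    ("rotating_shifts_with_nights", 74.60),
    ("refractive_surgery", 74.20),
    ("vdt_worker_over_2_years", 74.10),
    ("ocular_surgery", 69.40),
    ("ophthalmic_lens_wearer", 64.10),
    ("geriatric_department", 60.70),
    ("vdt_hours_outside_work", 60.60),
    ("total_vdt_hours", 60.10),
    ("morning_shifts_plus_on_call", 57.20),
    ("sterilization_unit", 53.40),
    ("contact_lens_wearer", 50.30),
    ("surgery_unit", 48.60),
    ("ocular_herpes_history", 46.10),
    ("age", 42.40),
    ("blood_bank_department", 41.10),
    ("anatomical_pathology_department", 40.90),
    ("endocrinology_unit", 40.70),
    ("morning_shifts", 40.50),
    ("sex", 40.20),
    ("traumatology_unit", 39.90),
    ("nephrology_unit", 39.70),
    ("easy_software_application", 39.60),
    ("keratitis_history", 39.30),
    ("anesthesiology_department", 34.60),
    ("evening_shifts", 34.20),
)

TOTAL_ENCODED_PREDICTORS = 255


def prevalence_fixture() -> pd.DataFrame:
    """Stratified prevalence counts as a fresh DataFrame.

    Columns: variable, stratum, n_subjects, n_cases.  A new frame is built
    on every call so callers cannot mutate the packaged constants.
    """
    return pd.DataFrame(
        PREVALENCE_STRATA, columns=["variable", "stratum", "n_subjects", "n_cases"]
    )


def inclusion_fixture() -> pd.DataFrame:
    """Reported inclusion percentages as a fresh DataFrame (variable, percent)."""
    return pd.DataFrame(INCLUSION_PERCENTAGES, columns=["variable", "percent"])
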