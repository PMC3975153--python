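"""Regenerate the packaged registries and the ILLUSTRATIVE default matrix.

The default prior matrix shipped with the package is authored from
clinical plausibility on the quantized semi-qualitative scale, not
elicited from experts or fitted to data.  This script is the single
source of those numbers: it writes src/intersamm/data/{indicators.csv,
causes.csv, default_matrix.csv}.

Construction:
* every (indicator, cause) cell not explicitly graded defaults to the
  largest scale grade not exceeding the indicator's baseline reporting
  rate among uncomplicated women, so that unrelated indicators mildly
  argue against morbidity rather than for it;
* P(I|SAMM) is the cause-prior-weighted mixture of the P(I|C) column;
* P(I) is rebuilt by total probability from P(I|SAMM), P(SAMM) and the
  uncomplicated baseline, making the file internally coherent.

Run from the repository root:  python scripts/build_default_matrix.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from intersamm.model_registry import (  # noqa: E402
    DEFAULT_SCALE,
    CauseCategory,
    CauseRegistry,
    Indicator,
    IndicatorRegistry,
    PriorMatrix,
    RESERVED_CAUSE_CODES,
    save_matrix,
)

DATA = ROOT / "src" / "intersamm" / "data"

# (code, label, baseline reporting rate among uncomplicated deliveries)
INDICATORS = [
    ("age_lt20", "aged under 20 yrs", 0.15),
    ("age_20_34", "aged 20 to 34 yrs", 0.65),
    ("age_ge35", "aged 35 yrs or more", 0.20),
    ("first_pregnancy", "was this her first pregnancy", 0.30),
    ("parity_2_4", "has she had 2 to 4 pregnancies", 0.50),
    ("parity_gt4", "were there >4 previous pregnancies", 0.20),
    ("multiple_pregnancy", "was this a multiple pregnancy", 0.015),
    ("attempted_termination", "any attempt to terminate this pregnancy", 0.01),
    ("pregnancy_end_lt5m", "was she <5 months pregnant at end of pregnancy", 0.01),
    ("iv_antibiotics", "any IV or IM antibiotics required", 0.02),
    ("transfusion_required", "any blood transfusion required", 0.005),
    ("transfusion_received", "any blood transfusion received", 0.004),
    ("bedbound_gt1d_pp", "was she bedbound for more than 1 day postpartum", 0.03),
    ("breathless_ap", "breathless carrying out normal activities antepartum", 0.05),
    ("breathless_pp", "breathless carrying out normal activities postpartum", 0.03),
    ("loss_of_consciousness", "any loss of consciousness", 0.005),
    ("acute_fever_ap", "any acute fever before pregnancy end", 0.04),
    ("acute_fever_pp", "any acute fever after pregnancy end", 0.04),
    ("recurrent_fever", "any recurrent fever", 0.02),
    ("fever_shivering", "any shivering with fever", 0.03),
    ("fits_ever", "did she ever have fits", 0.01),
    ("epilepsy_diagnosis", "did she have a diagnosis of epilepsy", 0.005),
    ("hysterectomy", "any hysterectomy", 0.002),
    ("hb_lt8", "haemoglobin less than 8g/dl", 0.02),
    ("anaemia_diagnosis", "any diagnosis of anaemia", 0.08),
    ("pallor", "any pallor", 0.06),
    ("jaundice", "any jaundice or yellow eyes", 0.01),
    ("cyanosis", "any cyanosis or blue lips", 0.003),
    ("baby_born_alive", "was baby delivered alive", 0.95),
    ("baby_born_dead", "was baby delivered dead", 0.02),
    ("abnormal_position", "was baby's position abnormal", 0.02),
    ("bleeding_first_3m", "major bleeding in 1st 3 months of pregnancy", 0.03),
    ("bleeding_late_pregnancy", "major bleeding >3m & before labour", 0.01),
    ("bleeding_during_labour", "major bleeding during labour", 0.02),
    ("bleeding_after_delivery", "major bleeding after delivery", 0.04),
    ("raised_bp_pregnancy", "was blood pressure raised during pregnancy", 0.04),
    ("forceps_ventouse", "was delivery by forceps/ventouse", 0.02),
    ("caesarean", "was delivery by Caesarean", 0.05),
    ("delivery_home", "was delivery at home", 0.50),
    ("delivery_facility", "was delivery at a health facility", 0.50),
    ("fits_pregnancy_only", "were fits only pregnancy related", 0.004),
    ("labour_gt24h", "was labour prolonged >24 hrs", 0.04),
    ("labour_gt48h", "was labour prolonged >48 hrs", 0.01),
    ("delayed_placenta", "was delivery of the placenta delayed", 0.02),
    ("manual_removal_placenta", "was there manual removal of the placenta", 0.01),
    ("professional_assistance", "had professional assistance at delivery", 0.55),
    ("intended_facility_delivery", "intention to deliver at health facility", 0.55),
    ("proteinuria", "abnormal proteinuria reported", 0.02),
    ("visited_multiple_facilities", "did she visit more than one health facility", 0.02),
    ("intended_home_delivery", "intent to deliver at home", 0.40),
    ("intended_home_delivered_facility",
     "intend to deliver at home but delivered in facility", 0.05),
    ("abdominal_pain_before_labour", "any acute abdominal pain before labour", 0.05),
    ("abdominal_pain_after_delivery", "any acute abdominal pain after delivery", 0.05),
    ("previous_caesarean", "any previous c-section", 0.03),
    ("genital_infection_discharge",
     "genital infection/foul smelling discharge postpartum", 0.03),
    ("leaking_membranes", "leaking membranes before labour start", 0.03),
    ("labour_augmentation", "any augmentation of labour", 0.05),
    ("persistent_fever_gt3wk", "any persistent fever >3 wks", 0.01),
    ("swollen_glands", "any swollen glands", 0.01),
    ("iron_injections", "did she require iron injections", 0.03),
    ("facial_swelling", "any swelling of face", 0.03),
    ("blurred_vision", "any blurred vision", 0.03),
    ("severe_headache_before_labour", "any severe headache before labour", 0.05),
    ("severe_headache_after_delivery", "any severe headache after delivery", 0.05),
    ("migraine_history", "any history of migraine", 0.05),
    ("haemorrhage_diagnosis", "any diagnosis of haemorrhage", 0.02),
    ("hypertension_diagnosis", "any diagnosis of hypertension", 0.03),
    ("malaria_diagnosis", "any diagnosis of malaria", 0.05),
    ("infection_diagnosis", "any diagnosis of infection", 0.02),
    ("rupture_diagnosis", "any diagnosis of rupture", 0.002),
    ("delivery_uncomplicated", "was delivery said to be uncomplicated", 0.80),
    ("self_reported_complication", "self-reported delivery complication", 0.15),
]

# (code, label, unconditional prior P(C))
CAUSES = [
    ("puerperal_infection", "Puerperal Infection", 0.012),
    ("antepartum_haemorrhage", "Antepartum Haemorrhage", 0.004),
    ("postpartum_haemorrhage", "Postpartum Haemorrhage", 0.012),
    ("preeclampsia", "Pre-eclampsia", 0.010),
    ("eclampsia", "Eclampsia", 0.004),
    ("obstructed_labour", "Obstructed Labour", 0.010),
    ("uterine_rupture", "Uterine Rupture/Pre-rupture", 0.002),
    ("anaemia", "Anaemia", 0.012),
    ("malaria", "Malaria", 0.008),
    ("other_infection", "Other infections", 0.005),
]

PRIOR_SAMM = 0.05

# Clinically motivated grade overrides: cause -> {indicator code: grade}.
# Grades: I near-certain (~1), A 0.5, B 0.1, C 0.02, D 0.005, E 0.001.
GRADES: dict[str, dict[str, str]] = {
    "puerperal_infection": {
        "acute_fever_pp": "A", "fever_shivering": "A", "recurrent_fever": "B",
        "genital_infection_discharge": "A", "abdominal_pain_after_delivery": "A",
        "iv_antibiotics": "B", "persistent_fever_gt3wk": "B",
        "infection_diagnosis": "A", "leaking_membranes": "B",
        "bedbound_gt1d_pp": "B", "caesarean": "B",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "antepartum_haemorrhage": {
        "bleeding_late_pregnancy": "A", "bleeding_first_3m": "B",
        "bleeding_during_labour": "B", "transfusion_required": "B",
        "transfusion_received": "B", "pallor": "B",
        "haemorrhage_diagnosis": "A", "baby_born_dead": "B", "caesarean": "B",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "postpartum_haemorrhage": {
        "bleeding_after_delivery": "A", "delayed_placenta": "B",
        "manual_removal_placenta": "B", "transfusion_required": "A",
        "transfusion_received": "B", "pallor": "B",
        "haemorrhage_diagnosis": "A", "hysterectomy": "B",
        "loss_of_consciousness": "B", "bedbound_gt1d_pp": "B",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "preeclampsia": {
        "raised_bp_pregnancy": "A", "proteinuria": "A", "facial_swelling": "A",
        "blurred_vision": "B", "severe_headache_before_labour": "B",
        "severe_headache_after_delivery": "B", "hypertension_diagnosis": "A",
        "caesarean": "B", "self_reported_complication": "B",
        "delivery_uncomplicated": "D",
    },
    "eclampsia": {
        "fits_pregnancy_only": "A", "fits_ever": "A",
        "loss_of_consciousness": "A", "raised_bp_pregnancy": "A",
        "proteinuria": "B", "blurred_vision": "B",
        "severe_headache_before_labour": "A", "facial_swelling": "B",
        "hypertension_diagnosis": "B", "caesarean": "B", "baby_born_dead": "B",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "obstructed_labour": {
        "labour_gt24h": "A", "labour_gt48h": "A", "abnormal_position": "B",
        "forceps_ventouse": "B", "caesarean": "A", "labour_augmentation": "B",
        "baby_born_dead": "B", "visited_multiple_facilities": "B",
        "abdominal_pain_before_labour": "B", "first_pregnancy": "A",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "uterine_rupture": {
        "rupture_diagnosis": "A", "hysterectomy": "A", "labour_gt48h": "A",
        "labour_gt24h": "A", "bleeding_during_labour": "A",
        "loss_of_consciousness": "B", "baby_born_dead": "A",
        "transfusion_required": "A", "previous_caesarean": "A",
        "abnormal_position": "B", "caesarean": "A",
        "self_reported_complication": "A", "delivery_uncomplicated": "E",
    },
    "anaemia": {
        "hb_lt8": "A", "anaemia_diagnosis": "A", "pallor": "A",
        "breathless_ap": "A", "breathless_pp": "B", "iron_injections": "B",
        "transfusion_received": "B", "self_reported_complication": "B",
        "delivery_uncomplicated": "D",
    },
    "malaria": {
        "malaria_diagnosis": "A", "acute_fever_ap": "A", "recurrent_fever": "A",
        "fever_shivering": "A", "jaundice": "B", "anaemia_diagnosis": "B",
        "pallor": "B", "severe_headache_before_labour": "B",
        "self_reported_complication": "B", "delivery_uncomplicated": "D",
    },
    "other_infection": {
        "acute_fever_ap": "B", "acute_fever_pp": "B",
        "persistent_fever_gt3wk": "A", "swollen_glands": "A",
        "recurrent_fever": "B", "jaundice": "B", "iv_antibiotics": "B",
        "infection_diagnosis": "B", "self_reported_complication": "B",
        "delivery_uncomplicated": "D",
    },
}


def build() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    ind_frame = pd.DataFrame(
        [{"code": c, "label": l, "index": i + 1}
         for i, (c, l, _) in enumerate(INDICATORS)]
    )
    with (DATA / "indicators.csv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("# Canonical registry of the 72 self-reported sign/symptom/"
                 "care-event indicators.\n")
        ind_frame.to_csv(fh, index=False)

    cause_frame = pd.DataFrame(
        [{"code": c, "label": l, "index": i + 1}
         for i, (c, l, _) in enumerate(CAUSES)]
    )
    with (DATA / "causes.csv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("# Canonical registry of the 10 direct/indirect morbidity "
                 "cause categories.\n")
        cause_frame.to_csv(fh, index=False)

    indicators = IndicatorRegistry(
        Indicator(c, l, i + 1) for i, (c, l, _) in enumerate(INDICATORS)
    )
    causes = CauseRegistry(
        [CauseCategory(c, l) for c, l, _ in CAUSES]
        + [CauseCategory(c, c, kind="reserved") for c in RESERVED_CAUSE_CODES]
    )
    baselines = np.array([b for _, _, b in INDICATORS])
    prior_cause = np.array([p for _, _, p in CAUSES])

    n_ind, n_cause = len(INDICATORS), len(CAUSES)
    conditional = np.empty((n_ind, n_cause))
    for i, (icode, _, b) in enumerate(INDICATORS):
        floor = DEFAULT_SCALE.floor(b)
        for c, (ccode, _, _) in enumerate(CAUSES):
            grade = GRADES[ccode].get(icode)
            conditional[i, c] = DEFAULT_SCALE[grade] if grade else floor

    weights = prior_cause / prior_cause.sum()
    cond_samm = conditional @ weights
    p_i = cond_samm * PRIOR_SAMM + baselines * (1.0 - PRIOR_SAMM)

    matrix = PriorMatrix(
        indicators=indicators,
        causes=causes,
        prior_samm=PRIOR_SAMM,
        prior_cause=prior_cause,
        baseline_indicator=p_i,
        conditional=conditional,
        conditional_samm=cond_samm,
    )
    save_matrix(
        matrix, DATA / "default_matrix.csv",
        header_comment=(
            "ILLUSTRATIVE default prior matrix.\n"
            "Authored from clinical plausibility on the quantized scale "
            "{I~1, A=0.5, B=0.1, C=0.02, D=0.005, E=0.001};\n"
            "NOT elicited from experts and NOT fitted to any dataset. "
            "Regenerate with scripts/build_default_matrix.py."
        ),
    )
    print(f"wrote registries and {n_ind}x{n_cause} matrix under {DATA}")


if __name__ == "__main__":
    build()
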