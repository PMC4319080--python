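"""Bundled coding vocabularies for the synthetic HIE world.

A small fixed ICD-9-CM-style diagnosis vocabulary keyed to six chapter
families (endocrine/immune, circulatory, nervous/sense-organ, respiratory,
digestive, other), each code flagged chronic or non-chronic.  This stands in
for the AHRQ Chronic Condition Indicator: the real CCI table maps every
ICD-9-CM code to the same dichotomy, and downstream code only ever consumes
the (family, chronic?) pair.
"""

from __future__ import annotations

CHAPTER_FAMILIES = (
    "endocrine_immune",
    "circulatory",
    "nervous_sense",
    "respiratory",
    "digestive",
    "other",
)

# code -> (chapter family, chronic?)
DIAGNOSIS_LOOKUP: dict[str, tuple[str, bool]] = {
    # endocrine, nutritional, metabolic and immunity
    "250.00": ("endocrine_immune", True),   # diabetes mellitus type II
    "272.4": ("endocrine_immune", True),    # hyperlipidemia
    "244.9": ("endocrine_immune", True),    # hypothyroidism
    "276.51": ("endocrine_immune", False),  # dehydration
    # circulatory system
    "401.9": ("circulatory", True),         # essential hypertension
    "428.0": ("circulatory", True),         # congestive heart failure
    "427.31": ("circulatory", True),        # atrial fibrillation
    "785.1": ("circulatory", False),        # palpitations
    # nervous system and sense organs
    "345.90": ("nervous_sense", True),      # epilepsy
    "340": ("nervous_sense", True),         # multiple sclerosis
    "365.9": ("nervous_sense", True),       # glaucoma
    "388.70": ("nervous_sense", False),     # otalgia
    # respiratory system
    "493.90": ("respiratory", True),        # asthma
    "496": ("respiratory", True),           # COPD
    "460": ("respiratory", False),          # acute nasopharyngitis
    "486": ("respiratory", False),          # pneumonia, organism unspecified
    # digestive system
    "571.5": ("digestive", True),           # cirrhosis of liver
    "555.9": ("digestive", True),           # Crohn's disease
    "558.9": ("digestive", False),          # gastroenteritis
    "530.81": ("digestive", True),          # esophageal reflux
    # everything else
    "714.0": ("other", True),               # rheumatoid arthritis
    "311": ("other", True),                 # depressive disorder
    "845.00": ("other", False),             # ankle sprain
    "780.60": ("other", False),             # fever
    "789.00": ("other", False),             # abdominal pain
    "959.9": ("other", False),              # injury, unspecified
}

CHRONIC_CODES: tuple[str, ...] = tuple(
    sorted(c for c, (_, chronic) in DIAGNOSIS_LOOKUP.items() if chronic)
)
ACUTE_CODES: tuple[str, ...] = tuple(
    sorted(c for c, (_, chronic) in DIAGNOSIS_LOOKUP.items() if not chronic)
)

CHRONIC_CODES_BY_FAMILY: dict[str, tuple[str, ...]] = {
    fam: tuple(
        sorted(
            c
            for c, (f, chronic) in DIAGNOSIS_LOOKUP.items()
            if f == fam and chronic
        )
    )
    for fam in CHAPTER_FAMILIES
}

LAB_NAMES = (
    "cbc", "bmp", "hba1c", "lipid_panel", "tsh", "urinalysis",
    "troponin", "bnp", "liver_panel", "crp", "inr", "glucose",
)
LAB_RESULTS = ("normal", "abnormal")

RADIOLOGY_MODALITIES = ("xray", "ct", "mri")

MEDICATION_CLASSES = (
    "antihypertensive", "statin", "insulin", "oral_hypoglycemic",
    "bronchodilator", "inhaled_steroid", "antidepressant", "anticoagulant",
    "opioid_analgesic", "nsaid", "antibiotic", "ppi", "anticonvulsant",
    "diuretic",
)

ENCOUNTER_TYPE_CODES = {
    "ED": ("ED",),
    "inpatient": ("inpatient_acute", "inpatient_observation"),
    "outpatient": ("outpatient_clinic", "outpatient_specialty",
                   "outpatient_urgent_care"),
}

AGE_GROUPS = ("0-18", "19-34", "35-49", "50+")
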