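"""Inventory of the published prevalence table's "< 0.001" cells.

Restricted to cells whose feature is a patient-record field and whose
denominator is the disease's full patient count (the malignant-sequel
sub-rows use subgroup denominators and are excluded).

Five of these printed "< 0.001" entries are arithmetically inconsistent
with their own printed counts under the one-vs-rest Pearson chi-square
that reproduces every other printed p-value in the table to printed
precision; they are listed separately with the p actually implied by
the printed counts.
"""

from fibralg import DiseaseLabel as D

PRINTED_LT_001 = [
    (D.UIP_IPF, "lower_lobe_predominance"),
    (D.UIP_IPF, "ground_glass"),
    (D.UIP_IPF, "traction_bronchiectasis"),
    (D.UIP_IPF, "honeycombing"),
    (D.UIP_IPF, "pulmonary_hypertension"),
    (D.FIBROSING_NSIP, "lower_lobe_predominance"),
    (D.FIBROSING_NSIP, "ground_glass"),
    (D.FIBROSING_NSIP, "rheumatologic_history"),
    (D.CHRONIC_HP, "lower_lobe_predominance"),
    (D.CHRONIC_HP, "peripheral_subpleural"),
    (D.CHRONIC_HP, "peribronchovascular"),
    (D.CHRONIC_HP, "ground_glass"),
    (D.CHRONIC_HP, "air_trapping"),
    (D.CHRONIC_HP, "head_cheese_sign"),
    (D.CHRONIC_HP, "traction_bronchiectasis"),
    (D.CHRONIC_HP, "crazy_paving"),
    (D.CHRONIC_HP, "centrilobular_nodules"),
    (D.CHRONIC_HP, "allergen_exposure"),
    (D.CHRONIC_HP, "blood_eosinophilia"),
    (D.CHRONIC_HP, "bal_lymphocytosis"),
    (D.PPFE, "platy_thorax"),
    (D.SARCOIDOSIS, "upper_lobe_predominance"),
    (D.SARCOIDOSIS, "peripheral_subpleural"),
    (D.SARCOIDOSIS, "peribronchovascular"),
    (D.SARCOIDOSIS, "ground_glass"),
    (D.SARCOIDOSIS, "centrilobular_nodules"),
    (D.SARCOIDOSIS, "perilymphatic_nodules"),
    (D.SARCOIDOSIS, "consolidation_calcification"),
    (D.SARCOIDOSIS, "lymphadenopathy_gt_1cm"),
    (D.PMF, "upper_lobe_predominance"),
    (D.PMF, "peribronchovascular"),
    (D.PMF, "consolidation_calcification"),
    (D.PMF, "occupational_dust_exposure"),
    (D.POST_TB, "upper_lobe_predominance"),
    (D.POST_TB, "air_trapping"),
    (D.POST_TB, "traction_bronchiectasis"),
    (D.POST_TB, "calcific_random_nodules"),
    (D.POST_TB, "consolidation_calcification"),
    (D.POST_TB, "cavitation"),
    (D.POST_TB, "lymphadenopathy_gt_1cm"),
    (D.POST_TB, "tuberculin_positive"),
    (D.POST_IRRADIATION, "upper_lobe_predominance"),
    (D.POST_IRRADIATION, "lower_lobe_predominance"),
    (D.POST_IRRADIATION, "peripheral_subpleural"),
    (D.POST_IRRADIATION, "ground_glass"),
    (D.POST_IRRADIATION, "air_trapping"),
    (D.POST_IRRADIATION, "traction_bronchiectasis"),
    (D.POST_IRRADIATION, "crazy_paving"),
    (D.POST_IRRADIATION, "malignancy_irradiation_history"),
]

#: (disease, feature) -> p implied by the printed counts (print defects).
PRINT_DEFECT_P = {
    (D.CHRONIC_HP, "ground_glass"): 0.0024,
    (D.POST_IRRADIATION, "peripheral_subpleural"): 0.0117,
    (D.POST_IRRADIATION, "ground_glass"): 0.0054,
    (D.POST_IRRADIATION, "traction_bronchiectasis"): 0.0086,
    (D.POST_TB, "traction_bronchiectasis"): 0.0606,
}

CONSISTENT_LT_001 = [c for c in PRINTED_LT_001 if c not in PRINT_DEFECT_P]
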