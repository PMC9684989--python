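"""Rule engine: canonical profiles, confounders, overlay, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibralg import (
    ClassifierConfig,
    DiseaseLabel,
    MalignancyFlag,
    PatientRecord,
    RecordValidationError,
    StepwiseDiagnosisClassifier,
    TriState,
    canonical_record,
    classify,
    classify_cohort,
)
from fibralg.patient_model import DIAGNOSABLE_LABELS, cohort_to_frame

SUPPORTIVE_FIELDS = (
    "rheumatologic_history",
    "skin_erythema",
    "arthralgia",
    "lymphadenopathy_gt_1cm",
    "consolidation_calcification",
)


def test_each_canonical_profile_classifies_to_its_own_disease():
    """8/8 self-consistency of the textbook disease profiles."""
    for label in DIAGNOSABLE_LABELS:
        trace = classify(canonical_record(label))
        assert trace.final_label is label, label


def test_all_negative_record_is_indeterminate():
    trace = classify(PatientRecord(patient_id="blank"))
    assert trace.final_label is DiseaseLabel.INDETERMINATE
    assert trace.fired_rule is None
    assert not any(step.fired for step in trace.steps)


def test_no_lobar_predominance_routes_to_indeterminate():
    record = canonical_record(DiseaseLabel.UIP_IPF).copy(
        lower_lobe_predominance=False
    )
    assert classify(record).final_label is DiseaseLabel.INDETERMINATE


def test_exactly_one_terminal_rule_fires(step2_records):
    for _, trace in classify_cohort(step2_records):
        assert sum(step.fired for step in trace.steps) <= 1
        if trace.final_label is not DiseaseLabel.INDETERMINATE:
            assert trace.fired_rule is not None


def test_hp_confounder_is_misread_as_nsip():
    """NSIP-like chronic HP: no head-cheese, no crazy paving, traction
    bronchiectasis with ground glass, supportive labs unrevealing."""
    record = canonical_record(DiseaseLabel.CHRONIC_HP).copy(
        head_cheese_sign=False,
        crazy_paving=False,
        traction_bronchiectasis=True,
        allergen_exposure=False,
        blood_eosinophilia=TriState.NOT_DONE,
        bal_lymphocytosis=TriState.NOT_DONE,
    )
    assert classify(record).final_label is DiseaseLabel.FIBROSING_NSIP


def test_nsip_confounder_with_head_cheese_is_misread_as_hp():
    record = canonical_record(DiseaseLabel.FIBROSING_NSIP).copy(
        head_cheese_sign=True
    )
    assert classify(record).final_label is DiseaseLabel.CHRONIC_HP


def test_post_tb_confounder_with_platy_thorax_is_misread_as_ppfe():
    record = canonical_record(DiseaseLabel.POST_TB).copy(
        platy_thorax=True,
        calcific_random_nodules=False,
        tree_in_bud=False,
        cavitation=False,
        tuberculin_positive=TriState.NOT_DONE,
        t2_hyperintense=TriState.NOT_DONE,
        dwi_restriction=TriState.NOT_DONE,
    )
    assert classify(record).final_label is DiseaseLabel.PPFE


def test_crazy_paving_alone_is_not_enough_for_hp():
    """The crazy-paving route needs at least one supportive exposure or
    laboratory result; head-cheese alone is sufficient."""
    base = PatientRecord(
        patient_id="p", lower_lobe_predominance=True, crazy_paving=True
    )
    assert classify(base).final_label is DiseaseLabel.INDETERMINATE
    assert (
        classify(base.copy(allergen_exposure=True)).final_label
        is DiseaseLabel.CHRONIC_HP
    )
    assert (
        classify(base.copy(bal_lymphocytosis=TriState.TRUE)).final_label
        is DiseaseLabel.CHRONIC_HP
    )


def test_irradiation_history_decides_before_lobar_logic():
    # a basal irradiation scar must not fall into the interstitial branch
    record = PatientRecord(
        patient_id="p",
        malignancy_irradiation_history=True,
        fibrosis_confined_to_radiation_field=True,
        lower_lobe_predominance=True,
        honeycombing=True,
    )
    trace = classify(record)
    assert trace.final_label is DiseaseLabel.POST_IRRADIATION
    assert trace.fired_rule == "R0"


@pytest.mark.parametrize(
    "changes, expected",
    [
        ({"t2_hyperintense": TriState.TRUE, "dwi_restriction": TriState.TRUE,
          "suv_max": 8.0}, MalignancyFlag.SCAR_CARCINOMA),
        ({"suv_max": 8.0}, MalignancyFlag.SCAR_CARCINOMA),  # SUV alone (OR rule)
        ({"t2_hyperintense": TriState.TRUE, "dwi_restriction": TriState.TRUE},
         MalignancyFlag.SCAR_CARCINOMA),  # MRI triad alone
        ({"t2_hyperintense": TriState.TRUE}, MalignancyFlag.NONE),  # incomplete
        ({"suv_max": 2.5}, MalignancyFlag.NONE),  # below threshold
    ],
)
def test_malignancy_overlay_on_post_tb(changes, expected):
    record = canonical_record(DiseaseLabel.POST_TB).copy(**changes)
    assert classify(record).malignancy is expected


def test_malignancy_overlay_subtype_follows_final_label():
    irr = canonical_record(DiseaseLabel.POST_IRRADIATION).copy(suv_max=5.0)
    assert classify(irr).malignancy is MalignancyFlag.METASTASIS


def test_malignancy_predictors_outside_tb_or_irradiation_warn_only():
    record = canonical_record(DiseaseLabel.UIP_IPF).copy(suv_max=9.0)
    trace = classify(record)
    assert trace.malignancy is MalignancyFlag.NONE
    assert any("review" in note for note in trace.notes)


def test_suv_threshold_is_configurable():
    record = canonical_record(DiseaseLabel.POST_TB).copy(suv_max=2.5)
    assert classify(record).malignancy is MalignancyFlag.NONE
    low = ClassifierConfig(suv_threshold=2.0)
    assert classify(record, low).malignancy is MalignancyFlag.SCAR_CARCINOMA


def test_supportive_evidence_changes_confidence_note_only():
    nsip = canonical_record(DiseaseLabel.FIBROSING_NSIP)
    without = classify(nsip.copy(rheumatologic_history=False))
    with_support = classify(nsip.copy(rheumatologic_history=True))
    assert without.final_label is with_support.final_label
    assert without.confidence_note == "required_only"
    assert with_support.confidence_note == "required_plus_supportive"
    assert "rheumatologic_history" in with_support.supportive


@settings(deadline=None, max_examples=150, derandomize=True)
@given(
    st.sampled_from(DIAGNOSABLE_LABELS),
    st.sampled_from(SUPPORTIVE_FIELDS),
)
def test_supportive_fields_never_change_the_label(label, support_field):
    """Monotone evidence: flipping a supportive-only field true leaves
    the final label unchanged."""
    base = canonical_record(label)
    flipped = base.copy(**{support_field: True})
    assert classify(base).final_label is classify(flipped).final_label


def test_evidence_lists_only_fields_true_in_the_record(step2_records):
    for rec, (_, trace) in zip(step2_records, classify_cohort(step2_records)):
        for step in trace.steps:
            for name in step.evidence:
                value = getattr(rec, name)
                assert value is True or value is TriState.TRUE


def test_classifier_is_deterministic(step2_records):
    first = classify_cohort(step2_records)
    second = classify_cohort(step2_records)
    assert first == second


def test_ground_truth_fields_are_never_consulted(step2_records):
    """Leakage guard: wiping or swapping the truth labels changes nothing."""
    stripped = [
        r.copy(true_label=None, true_malignancy=None) for r in step2_records
    ]
    swapped = [
        r.copy(true_label=DiseaseLabel.PMF, true_malignancy=MalignancyFlag.NONE)
        for r in step2_records
    ]
    reference = [t.final_label for _, t in classify_cohort(step2_records)]
    assert [t.final_label for _, t in classify_cohort(stripped)] == reference
    assert [t.final_label for _, t in classify_cohort(swapped)] == reference


def test_invalid_record_raises_with_patient_id():
    bad = PatientRecord(patient_id="oops", suv_max=-3.0)
    with pytest.raises(RecordValidationError, match="oops"):
        classify(bad)


def test_empty_cohort_classifies_to_empty():
    assert classify_cohort([]) == []


def test_config_rejects_nonpositive_threshold_and_reordering():
    with pytest.raises(ValueError):
        ClassifierConfig(suv_threshold=0.0)
    with pytest.raises(ValueError):
        ClassifierConfig(rule_order=("R1a", "R0"))


class TestEstimatorFacade:
    def test_fit_predict_on_records(self, step2_records):
        clf = StepwiseDiagnosisClassifier().fit(step2_records)
        predictions = clf.predict(step2_records)
        expected = [
            t.final_label.value for _, t in classify_cohort(step2_records)
        ]
        assert list(predictions) == expected
        assert set(clf.classes_) >= set(predictions)

    def test_predict_on_schema_dataframe(self, step2_records):
        frame = cohort_to_frame(step2_records)
        clf = StepwiseDiagnosisClassifier()
        assert list(clf.predict(frame)) == list(clf.predict(step2_records))

    def test_score_matches_documented_accuracy(self, step2_records):
        clf = StepwiseDiagnosisClassifier()
        truth = [r.true_label for r in step2_records]
        assert clf.score(step2_records, truth) == pytest.approx(0.94)

    def test_get_set_params_round_trip(self):
        clf = StepwiseDiagnosisClassifier(suv_threshold=4.0)
        assert clf.get_params() == {"suv_threshold": 4.0}
        clf.set_params(suv_threshold=2.0)
        assert clf.suv_threshold == 2.0
        with pytest.raises(ValueError):
            clf.set_params(bogus=1)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = StepwiseDiagnosisClassifier(suv_threshold=4.5)
        assert clone(clf).get_params() == clf.get_params()
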