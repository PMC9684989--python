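"""Deterministic stepwise rule engine for fibrosing lung disease diagnosis.

The engine encodes the study's multi-disciplinary decision algorithm as
an ordered list of terminal rules evaluated first-match-wins:

* R0 — irradiation history with fibrosis confined to the radiation
  field decides post-irradiation fibrosis before any lobar logic (a
  minority of irradiation scars are basal).
* R1 (lower-lobe predominant, the interstitial branch):
  R1a honeycombing -> UIP/IPF; R1b the "head cheese" sign — or crazy
  paving backed by at least one HP-supportive exposure/laboratory
  result — -> chronic HP; R1c traction bronchiectasis with ground
  glass and no honeycombing -> fibrosing NSIP.
* R2 (upper-lobe predominant, the non-interstitial branch):
  R2a peripheral fibrosis with any TB stigma (calcific nodules,
  tree-in-bud, cavitation, positive tuberculin) -> post-TB;
  R2b peribronchovascular fibrosis with perilymphatic nodules ->
  sarcoidosis; R2c peribronchovascular fibrosis with occupational dust
  exposure -> PMF; R2d peripheral fibrosis with "platy-thorax" -> PPFE.
  TB stigmata are tested before platy-thorax so the sign only decides
  when TB evidence is absent (the algorithm's known PPFE/post-TB
  confusion direction).
* R3 — no rule fires (including no lobar predominance) -> INDETERMINATE.

Independently of the terminal rule, the malignancy overlay flags scar
carcinoma (on post-TB) or metastasis (on post-irradiation) when the MRI
triad (T2 hyperintensity with DWI restriction) or a PET SUVmax above
threshold (default 3.0) is present.

``not_done`` laboratory results never satisfy a criterion and are never
evidence against one.  The engine never reads ground-truth fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .patient_model import (
    Course,
    DiseaseLabel,
    MalignancyFlag,
    PatientRecord,
    RecordValidationError,
    TriState,
    records_from_frame,
    validate_record,
)

RULE_ORDER: tuple[str, ...] = ("R0", "R1a", "R1b", "R1c", "R2a", "R2b", "R2c", "R2d")


@dataclass
class ClassifierConfig:
    """Tunable thresholds; imaging booleans arrive pre-thresholded.

    ``nodal_short_axis_threshold_cm`` documents the cut behind the
    lymphadenopathy flag and is not re-applied.
    """

    suv_threshold: float = 3.0
    nodal_short_axis_threshold_cm: float = 1.0
    rule_order: tuple[str, ...] = RULE_ORDER

    def __post_init__(self):
        if self.suv_threshold <= 0:
            raise ValueError("suv_threshold must be positive")
        if tuple(self.rule_order) != RULE_ORDER:
            raise ValueError("rule_order is fixed; reordering is not supported")


@dataclass
class RuleStep:
    name: str
    fired: bool
    evidence: list[str] = field(default_factory=list)


@dataclass
class RuleTrace:
    """Audit trail of one classification."""

    steps: list[RuleStep]
    final_label: DiseaseLabel
    malignancy: MalignancyFlag
    confidence_note: str  # required_only | required_plus_supportive
    supportive: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def fired_rule(self) -> str | None:
        for step in self.steps:
            if step.fired:
                return step.name
        return None


def _tri(value: TriState) -> bool:
    return value is TriState.TRUE


def _rule_r0(r: PatientRecord):
    ev = []
    if r.malignancy_irradiation_history:
        ev.append("malignancy_irradiation_history")
    if r.fibrosis_confined_to_radiation_field:
        ev.append("fibrosis_confined_to_radiation_field")
    return len(ev) == 2, ev


def _rule_r1a(r: PatientRecord):
    fired = r.lower_lobe_predominance and r.honeycombing
    return fired, ["lower_lobe_predominance", "honeycombing"] if fired else []


def _rule_r1b(r: PatientRecord):
    if not r.lower_lobe_predominance:
        return False, []
    if r.head_cheese_sign:
        return True, ["lower_lobe_predominance", "head_cheese_sign"]
    labs = [
        name
        for name, ok in (
            ("allergen_exposure", r.allergen_exposure),
            ("blood_eosinophilia", _tri(r.blood_eosinophilia)),
            ("bal_lymphocytosis", _tri(r.bal_lymphocytosis)),
        )
        if ok
    ]
    if r.crazy_paving and labs:
        return True, ["lower_lobe_predominance", "crazy_paving", *labs]
    return False, []


def _rule_r1c(r: PatientRecord):
    fired = (
        r.lower_lobe_predominance
        and r.traction_bronchiectasis
        and r.ground_glass
        and not r.honeycombing
    )
    ev = ["lower_lobe_predominance", "traction_bronchiectasis", "ground_glass"]
    return fired, ev if fired else []


def _rule_r2a(r: PatientRecord):
    if not (r.upper_lobe_predominance and r.peripheral_subpleural):
        return False, []
    stigmata = [
        name
        for name, ok in (
            ("calcific_random_nodules", r.calcific_random_nodules),
            ("tree_in_bud", r.tree_in_bud),
            ("cavitation", r.cavitation),
            ("tuberculin_positive", _tri(r.tuberculin_positive)),
        )
        if ok
    ]
    if stigmata:
        return True, ["upper_lobe_predominance", "peripheral_subpleural", *stigmata]
    return False, []


def _rule_r2b(r: PatientRecord):
    fired = (
        r.upper_lobe_predominance
        and r.peribronchovascular
        and r.perilymphatic_nodules
    )
    ev = ["upper_lobe_predominance", "peribronchovascular", "perilymphatic_nodules"]
    return fired, ev if fired else []


def _rule_r2c(r: PatientRecord):
    fired = (
        r.upper_lobe_predominance
        and r.peribronchovascular
        and r.occupational_dust_exposure
    )
    ev = ["upper_lobe_predominance", "peribronchovascular", "occupational_dust_exposure"]
    return fired, ev if fired else []


def _rule_r2d(r: PatientRecord):
    fired = (
        r.upper_lobe_predominance and r.peripheral_subpleural and r.platy_thorax
    )
    ev = ["upper_lobe_predominance", "peripheral_subpleural", "platy_thorax"]
    return fired, ev if fired else []


_RULES = {
    "R0": (_rule_r0, DiseaseLabel.POST_IRRADIATION),
    "R1a": (_rule_r1a, DiseaseLabel.UIP_IPF),
    "R1b": (_rule_r1b, DiseaseLabel.CHRONIC_HP),
    "R1c": (_rule_r1c, DiseaseLabel.FIBROSING_NSIP),
    "R2a": (_rule_r2a, DiseaseLabel.POST_TB),
    "R2b": (_rule_r2b, DiseaseLabel.SARCOIDOSIS),
    "R2c": (_rule_r2c, DiseaseLabel.PMF),
    "R2d": (_rule_r2d, DiseaseLabel.PPFE),
}


def _supportive_evidence(rule: str | None, r: PatientRecord) -> list[str]:
    if rule == "R1c" and r.rheumatologic_history:
        return ["rheumatologic_history"]
    if rule == "R2b":
        return [
            name
            for name, ok in (
                ("skin_erythema", r.skin_erythema),
                ("arthralgia", r.arthralgia),
                ("lymphadenopathy_gt_1cm", r.lymphadenopathy_gt_1cm),
            )
            if ok
        ]
    if rule == "R2c" and r.consolidation_calcification:
        return ["consolidation_calcification"]
    if rule == "R2d" and r.course is Course.RAPIDLY_PROGRESSIVE:
        return ["course=rapidly_progressive"]
    return []


def classify(
    record: PatientRecord, config: ClassifierConfig | None = None
) -> RuleTrace:
    """Classify one record; raises :class:`RecordValidationError` if invalid.

    Pure and total on valid records: exactly one terminal rule fires,
    or none and the label is INDETERMINATE.
    """
    config = config or ClassifierConfig()
    violations = validate_record(record)
    if violations:
        raise RecordValidationError(record.patient_id, violations)

    steps: list[RuleStep] = []
    final_label = DiseaseLabel.INDETERMINATE
    fired_rule: str | None = None
    for name in config.rule_order:
        predicate, label = _RULES[name]
        if fired_rule is None:
            fired, evidence = predicate(record)
        else:
            fired, evidence = False, []  # first match wins; rest recorded unfired
        steps.append(RuleStep(name, fired, evidence))
        if fired:
            fired_rule, final_label = name, label

    notes: list[str] = []
    malignancy = MalignancyFlag.NONE
    mri_triad = _tri(record.t2_hyperintense) and _tri(record.dwi_restriction)
    suv_high = record.suv_max is not None and record.suv_max > config.suv_threshold
    if mri_triad or suv_high:
        if final_label is DiseaseLabel.POST_TB:
            malignancy = MalignancyFlag.SCAR_CARCINOMA
        elif final_label is DiseaseLabel.POST_IRRADIATION:
            malignancy = MalignancyFlag.METASTASIS
        else:
            notes.append(
                "malignancy predictors present "
                f"({'MRI triad' if mri_triad else ''}"
                f"{' and ' if mri_triad and suv_high else ''}"
                f"{'high SUV' if suv_high else ''}) but final label is "
                f"{final_label.value}; recommend review"
            )

    supportive = _supportive_evidence(fired_rule, record)
    confidence = "required_plus_supportive" if supportive else "required_only"
    return RuleTrace(
        steps=steps,
        final_label=final_label,
        malignancy=malignancy,
        confidence_note=confidence,
        supportive=supportive,
        notes=notes,
    )


def classify_cohort(
    records: Iterable[PatientRecord], config: ClassifierConfig | None = None
) -> list[tuple[str, RuleTrace]]:
    """Element-wise :func:`classify`, order preserved, deterministic."""
    config = config or ClassifierConfig()
    return [(rec.patient_id, classify(rec, config)) for rec in records]


class StepwiseDiagnosisClassifier:
    """sklearn-style estimator facade over the rule engine.

    The rules are fixed by design, so ``fit`` only validates input and
    records ``classes_``; ``predict`` runs the stepwise algorithm.  X
    may be a sequence of :class:`PatientRecord` or a DataFrame in the
    serialized cohort schema (as written by ``write_cohort`` /
    ``cohort_to_frame``).
    """

    def __init__(self, suv_threshold: float = 3.0):
        self.suv_threshold = suv_threshold

    # -- minimal get/set_params so the estimator composes with sklearn tools
    def get_params(self, deep: bool = True) -> dict:
        return {"suv_threshold": self.suv_threshold}

    def set_params(self, **params) -> "StepwiseDiagnosisClassifier":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(suv_threshold=self.suv_threshold)

    @staticmethod
    def _to_records(X) -> list[PatientRecord]:
        if hasattr(X, "to_dict"):  # DataFrame in serialized schema
            return records_from_frame(X, lenient=True)
        records = list(X)
        if records and not isinstance(records[0], PatientRecord):
            raise TypeError("X must be PatientRecords or a schema DataFrame")
        return records

    def fit(self, X, y=None) -> "StepwiseDiagnosisClassifier":
        records = self._to_records(X)
        for rec in records:
            violations = validate_record(rec)
            if violations:
                raise RecordValidationError(rec.patient_id, violations)
        self.classes_ = np.array([label.value for label in DiseaseLabel])
        self.n_features_in_ = len(records)
        return self

    def predict(self, X) -> np.ndarray:
        config = self._config()
        return np.array(
            [classify(r, config).final_label.value for r in self._to_records(X)]
        )

    def predict_traces(self, X) -> list[RuleTrace]:
        config = self._config()
        return [classify(r, config) for r in self._to_records(X)]

    def predict_malignancy(self, X) -> np.ndarray:
        config = self._config()
        return np.array(
            [classify(r, config).malignancy.value for r in self._to_records(X)]
        )

    def score(self, X, y) -> float:
        """Plain label accuracy against ground truth ``y``."""
        y = [label.value if isinstance(label, DiseaseLabel) else label for label in y]
        predictions = self.predict(X)
        return float(np.mean([p == t for p, t in zip(predictions, y)]))
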