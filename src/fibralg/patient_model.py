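"""Patient feature schema, label vocabulary, record validation and cohort I/O.

One :class:`PatientRecord` holds a single patient's clinical history,
laboratory results and thin-slice CT / MRI / PET feature flags, plus an
optional ground-truth diagnosis used only by the significance and
validation stages (never by the classifier).

Laboratory and MRI/PET fields that are frequently not performed in
practice are tri-state (:class:`TriState`): ``not_done`` is preserved
explicitly and is never coerced to ``false``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class DiseaseLabel(str, Enum):
    """The eight fibrosing lung disease diagnoses plus an abstention label.

    ``INDETERMINATE`` is a legal *prediction* (the rule engine abstains)
    but never a legal ground-truth label.
    """

    UIP_IPF = "UIP_IPF"
    FIBROSING_NSIP = "FIBROSING_NSIP"
    CHRONIC_HP = "CHRONIC_HP"
    PPFE = "PPFE"
    POST_TB = "POST_TB"
    POST_IRRADIATION = "POST_IRRADIATION"
    SARCOIDOSIS = "SARCOIDOSIS"
    PMF = "PMF"
    INDETERMINATE = "INDETERMINATE"


#: The eight diagnosable diseases, in reporting order (interstitial first).
DIAGNOSABLE_LABELS: tuple[DiseaseLabel, ...] = (
    DiseaseLabel.UIP_IPF,
    DiseaseLabel.FIBROSING_NSIP,
    DiseaseLabel.CHRONIC_HP,
    DiseaseLabel.PPFE,
    DiseaseLabel.POST_TB,
    DiseaseLabel.POST_IRRADIATION,
    DiseaseLabel.SARCOIDOSIS,
    DiseaseLabel.PMF,
)


class MalignancyFlag(str, Enum):
    """Malignant complication of lung fibrosis.

    Scar carcinoma arises in chronic (post-tuberculous) scarring;
    metastatic spread complicates irradiated lung.
    """

    NONE = "NONE"
    SCAR_CARCINOMA = "SCAR_CARCINOMA"
    METASTASIS = "METASTASIS"


class TriState(str, Enum):
    """Result of a test that may not have been performed."""

    TRUE = "true"
    FALSE = "false"
    NOT_DONE = "not_done"

    @property
    def is_true(self) -> bool:
        return self is TriState.TRUE


class Sex(str, Enum):
    M = "M"
    F = "F"


class Course(str, Enum):
    INSIDIOUS = "insidious"
    RAPIDLY_PROGRESSIVE = "rapidly_progressive"


class SchemaError(ValueError):
    """A cohort file does not conform to the documented column schema."""


class RecordValidationError(ValueError):
    """A record violates schema invariants; carries the violation list."""

    def __init__(self, patient_id: str, violations: Sequence[str]):
        self.patient_id = patient_id
        self.violations = list(violations)
        super().__init__(f"invalid record {patient_id!r}: " + "; ".join(violations))


@dataclass
class PatientRecord:
    """One patient's feature vector.

    Boolean fields encode 'sign present'; tri-state fields encode
    laboratory / MRI results that may not have been performed;
    ``suv_max`` is the peak standardized uptake value on FDG-PET
    (``None`` when PET was not done).  ``true_label`` /
    ``true_malignancy`` are the pathologically proven diagnoses and are
    optional.
    """

    patient_id: str
    age_years: int = 60
    sex: Sex = Sex.M
    course: Course = Course.INSIDIOUS
    # clinical history
    smoking_history: bool = False
    allergen_exposure: bool = False
    occupational_dust_exposure: bool = False
    rheumatologic_history: bool = False
    malignancy_irradiation_history: bool = False
    skin_erythema: bool = False
    arthralgia: bool = False
    # laboratory
    blood_eosinophilia: TriState = TriState.NOT_DONE
    serum_ige_elevated: TriState = TriState.NOT_DONE
    tuberculin_positive: TriState = TriState.NOT_DONE
    bal_lymphocytosis: TriState = TriState.NOT_DONE
    # CT distribution
    upper_lobe_predominance: bool = False
    lower_lobe_predominance: bool = False
    peripheral_subpleural: bool = False
    peribronchovascular: bool = False
    # CT mosaic pattern
    ground_glass: bool = False
    air_trapping: bool = False
    head_cheese_sign: bool = False
    # CT reticular pattern
    traction_bronchiectasis: bool = False
    honeycombing: bool = False
    crazy_paving: bool = False
    # CT nodular pattern
    centrilobular_nodules: bool = False
    perilymphatic_nodules: bool = False
    calcific_random_nodules: bool = False
    tree_in_bud: bool = False
    # CT associated signs
    consolidation_calcification: bool = False
    cavitation: bool = False
    lymphadenopathy_gt_1cm: bool = False  # short axis > 1 cm
    pulmonary_hypertension: bool = False  # trunk > 3.3 cm or wider than aorta
    platy_thorax: bool = False
    fibrosis_confined_to_radiation_field: bool = False
    # MRI / PET
    t2_hyperintense: TriState = TriState.NOT_DONE
    dwi_restriction: TriState = TriState.NOT_DONE  # low ADC
    suv_max: float | None = None
    # ground truth (optional)
    true_label: DiseaseLabel | None = None
    true_malignancy: MalignancyFlag | None = None

    def copy(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


# --- column schema -----------------------------------------------------------

_ENUM_FIELDS = {"sex": Sex, "course": Course}
TRISTATE_FIELDS: tuple[str, ...] = (
    "blood_eosinophilia",
    "serum_ige_elevated",
    "tuberculin_positive",
    "bal_lymphocytosis",
    "t2_hyperintense",
    "dwi_restriction",
)
BOOLEAN_FIELDS: tuple[str, ...] = tuple(
    f.name
    for f in fields(PatientRecord)
    if f.type == "bool"
)
#: Fixed serialization column order.
COLUMN_ORDER: tuple[str, ...] = tuple(f.name for f in fields(PatientRecord))
_OPTIONAL_COLUMNS = ("true_label", "true_malignancy")
MANDATORY_COLUMNS: tuple[str, ...] = tuple(
    c for c in COLUMN_ORDER if c not in _OPTIONAL_COLUMNS
)

#: Feature columns eligible for prevalence/significance bookkeeping.
FEATURE_FIELDS: tuple[str, ...] = tuple(
    c for c in COLUMN_ORDER if c in BOOLEAN_FIELDS or c in TRISTATE_FIELDS
)


def validate_record(record: PatientRecord) -> list[str]:
    """Check every schema invariant; return violations (empty iff valid).

    Pure function: violations are returned, never raised.
    """
    v: list[str] = []
    if record.upper_lobe_predominance and record.lower_lobe_predominance:
        v.append(
            "upper_lobe_predominance and lower_lobe_predominance are mutually exclusive"
        )
    if not 18 <= record.age_years <= 110:
        v.append(f"age_years {record.age_years} outside [18, 110]")
    if record.suv_max is not None and record.suv_max < 0:
        v.append(f"suv_max {record.suv_max} is negative")
    if record.true_label is DiseaseLabel.INDETERMINATE:
        v.append("true_label may not be INDETERMINATE (prediction-only label)")
    if record.true_malignancy is MalignancyFlag.SCAR_CARCINOMA and (
        record.true_label is not None and record.true_label is not DiseaseLabel.POST_TB
    ):
        v.append("true_malignancy SCAR_CARCINOMA requires true_label POST_TB")
    if record.true_malignancy is MalignancyFlag.METASTASIS and (
        record.true_label is not None
        and record.true_label is not DiseaseLabel.POST_IRRADIATION
    ):
        v.append("true_malignancy METASTASIS requires true_label POST_IRRADIATION")
    for name in BOOLEAN_FIELDS:
        if not isinstance(getattr(record, name), bool):
            v.append(f"{name} must be a boolean")
    for name in TRISTATE_FIELDS:
        if not isinstance(getattr(record, name), TriState):
            v.append(f"{name} must be a TriState")
    return v


# --- serialization -----------------------------------------------------------


def _serialize_value(name: str, value) -> str:
    if name in BOOLEAN_FIELDS:
        return "true" if value else "false"
    if name in TRISTATE_FIELDS:
        return value.value
    if name == "suv_max":
        return "not_done" if value is None else format(value, "g")
    if name in ("true_label", "true_malignancy"):
        return "" if value is None else value.value
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_value(name: str, token: str, row: int):
    token = token.strip()
    try:
        if name in BOOLEAN_FIELDS:
            if token not in ("true", "false"):
                raise ValueError(f"expected true/false, got {token!r}")
            return token == "true"
        if name in TRISTATE_FIELDS:
            return TriState(token)
        if name == "suv_max":
            return None if token in ("", "not_done") else float(token)
        if name == "age_years":
            return int(token)
        if name == "true_label":
            return None if token == "" else DiseaseLabel(token)
        if name == "true_malignancy":
            return None if token == "" else MalignancyFlag(token)
        if name in _ENUM_FIELDS:
            return _ENUM_FIELDS[name](token)
        return token
    except ValueError as exc:
        raise SchemaError(f"row {row}: field {name!r}: {exc}") from None


def record_to_dict(record: PatientRecord) -> dict[str, str]:
    """Serialize a record to string-valued fields in schema column order."""
    return {c: _serialize_value(c, getattr(record, c)) for c in COLUMN_ORDER}


def record_from_dict(data: dict, row: int = 0, *, lenient: bool = False) -> PatientRecord:
    unknown = set(data) - set(COLUMN_ORDER)
    if unknown and not lenient:
        raise SchemaError(f"row {row}: unknown columns {sorted(unknown)}")
    missing = [c for c in MANDATORY_COLUMNS if c not in data]
    if missing:
        raise SchemaError(f"row {row}: missing mandatory columns {missing}")
    kwargs = {
        c: _parse_value(c, str(data[c]), row)
        for c in COLUMN_ORDER
        if c in data
    }
    return PatientRecord(**kwargs)


def write_cohort(
    records: Iterable[PatientRecord],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write records to CSV or JSON with the fixed schema column order.

    Deterministic: the same records always produce byte-identical files.
    Raises :class:`RecordValidationError` on the first invalid record.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    records = list(records)
    for rec in records:
        violations = validate_record(rec)
        if violations:
            raise RecordValidationError(rec.patient_id, violations)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMN_ORDER)
            writer.writeheader()
            for rec in records:
                writer.writerow(record_to_dict(rec))
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([record_to_dict(r) for r in records], fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cohort(
    path: str | Path,
    format: str | None = None,
    *,
    lenient: bool = False,
) -> list[PatientRecord]:
    """Read a cohort file (CSV or JSON) into records.

    Unknown columns are rejected unless ``lenient=True``; a missing
    mandatory column or an unparseable token raises :class:`SchemaError`
    naming the column and row.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, header expected")
            rows = [
                record_from_dict(row, i, lenient=lenient)
                for i, row in enumerate(reader, start=1)
            ]
        return rows
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return [
            record_from_dict(obj, i, lenient=lenient)
            for i, obj in enumerate(data, start=1)
        ]
    raise ValueError(f"unknown format {fmt!r}")


def cohort_to_frame(records: Sequence[PatientRecord]):
    """Records as a pandas DataFrame of serialized string columns."""
    import pandas as pd

    return pd.DataFrame([record_to_dict(r) for r in records], columns=COLUMN_ORDER)


def records_from_frame(df, *, lenient: bool = False) -> list[PatientRecord]:
    """Parse a DataFrame (schema columns, serialized values) into records."""
    return [
        record_from_dict(
            {k: "" if v is None else v for k, v in row.items()}, i, lenient=lenient
        )
        for i, row in enumerate(df.to_dict(orient="records"), start=1)
    ]
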