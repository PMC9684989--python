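"""Synthetic generation of the two study cohorts.

Two builtin cohort specifications are packaged:

* the 150-patient retrospective *significance* cohort, whose per-disease
  feature counts reproduce the published prevalence table (counts are
  authoritative; percentages follow), and
* the 100-patient prospective *validation* cohort of canonical disease
  profiles plus the six documented atypical ("confounder") profiles and
  two malignancy-complicated patients.

Features are drawn independently within a disease profile (only the
marginal prevalences are known); the single forced dependence is the
malignancy overlay, which sets the MRI/PET triad (T2 hyperintensity,
DWI restriction, SUV > 3) together.  ``exact_counts`` mode allocates
exactly the published integer count of positives per feature — the seed
only permutes which patients carry them — so downstream prevalence and
significance numbers are deterministic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .patient_model import (
    COLUMN_ORDER,
    TRISTATE_FIELDS,
    Course,
    DiseaseLabel,
    MalignancyFlag,
    PatientRecord,
    Sex,
    TriState,
    validate_record,
)


class SpecError(ValueError):
    """A cohort specification is internally inconsistent."""


_NON_FEATURE_FIELDS = {"patient_id", "age_years", "sex", "course", "suv_max",
                       "true_label", "true_malignancy"}


@dataclass
class DiseaseProfile:
    """Generation parameters for one disease's patients.

    ``fixed_fields`` hold constants (features at 100% or 0% prevalence,
    laboratory defaults); ``feature_counts`` hold the authoritative
    integer count of positives for features with intermediate
    prevalence.  ``confounder_overrides`` are (count, field-override)
    pairs applied verbatim to the profile's trailing records;
    ``malignancy_overlay`` marks the profile's leading records as
    malignancy-complicated with the full MRI/PET triad.
    """

    label: DiseaseLabel
    n_patients: int
    feature_counts: dict[str, int] = field(default_factory=dict)
    fixed_fields: dict[str, object] = field(default_factory=dict)
    confounder_overrides: list[tuple[int, dict]] = field(default_factory=list)
    malignancy_overlay: tuple[int, MalignancyFlag] | None = None
    male_count: int | None = None
    age_range: tuple[int, int] = (33, 76)
    rapid_course_count: int = 0

    @property
    def feature_prevalence(self) -> dict[str, float]:
        """Marginal prevalence of each non-constant feature (documentation)."""
        return {k: v / self.n_patients for k, v in self.feature_counts.items()}

    def validate(self) -> list[str]:
        problems = []
        known = set(COLUMN_ORDER) - _NON_FEATURE_FIELDS
        for name in list(self.feature_counts) + list(self.fixed_fields):
            if name not in known:
                problems.append(f"{self.label.value}: unknown feature {name!r}")
        for name, count in self.feature_counts.items():
            if not 0 <= count <= self.n_patients:
                problems.append(
                    f"{self.label.value}: count {count} for {name!r} outside "
                    f"[0, {self.n_patients}]"
                )
        if self.fixed_fields.get("upper_lobe_predominance") and self.fixed_fields.get(
            "lower_lobe_predominance"
        ):
            problems.append(
                f"{self.label.value}: fixed_fields set both lobar predominance flags"
            )
        n_override = sum(k for k, _ in self.confounder_overrides)
        n_overlay = self.malignancy_overlay[0] if self.malignancy_overlay else 0
        if n_override + n_overlay > self.n_patients:
            problems.append(f"{self.label.value}: overrides exceed profile size")
        return problems


@dataclass
class CohortSpec:
    """A full cohort: disease profiles, generation mode, master seed."""

    profiles: list[DiseaseProfile]
    mode: str = "exact_counts"  # or "bernoulli"
    seed: int = 0
    name: str = "cohort"

    @property
    def n_total(self) -> int:
        return sum(p.n_patients for p in self.profiles)

    def validate(self) -> list[str]:
        problems = []
        if self.mode not in ("exact_counts", "bernoulli"):
            problems.append(f"unknown mode {self.mode!r}")
        for profile in self.profiles:
            problems.extend(profile.validate())
        return problems


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _profile_rng(seed: int, label: DiseaseLabel) -> np.random.Generator:
    # stable per-profile substream: adding a profile never perturbs others
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.value.encode())])


def _set_feature(record: PatientRecord, name: str, value: object) -> None:
    if name in TRISTATE_FIELDS and not isinstance(value, TriState):
        if isinstance(value, bool):
            value = TriState.TRUE if value else TriState.FALSE
        else:
            value = TriState(value)
    setattr(record, name, value)


def _feature_is_true(record: PatientRecord, name: str) -> bool:
    value = getattr(record, name)
    return value is True or value is TriState.TRUE


def _generate_profile(
    profile: DiseaseProfile, mode: str, seed: int
) -> list[PatientRecord]:
    n = profile.n_patients
    rng = _profile_rng(seed, profile.label)
    records = [
        PatientRecord(
            patient_id=f"{profile.label.value}_{i + 1:03d}",
            true_label=profile.label,
            true_malignancy=MalignancyFlag.NONE,
        )
        for i in range(n)
    ]
    for rec in records:
        for name, value in profile.fixed_fields.items():
            _set_feature(rec, name, value)

    # demographics (never inspected by the classifier)
    lo, hi = profile.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    n_male = (
        profile.male_count
        if profile.male_count is not None
        else _round_half_up(0.6 * n)
    )
    sexes = np.array([Sex.M] * n_male + [Sex.F] * (n - n_male), dtype=object)
    rng.shuffle(sexes)
    for rec, age, sex in zip(records, ages, sexes):
        rec.age_years = int(age)
        rec.sex = sex
    if profile.rapid_course_count:
        for i in rng.permutation(n)[: profile.rapid_course_count]:
            records[i].course = Course.RAPIDLY_PROGRESSIVE

    # prevalence features
    names = list(profile.feature_counts)
    if mode == "exact_counts":
        # allocate upper-lobe predominance before lower so the mutually
        # exclusive pair can share a profile (e.g. 27 upper + 4 lower of 31)
        names.sort(key=lambda s: (s != "upper_lobe_predominance",))
        for name in names:
            k = profile.feature_counts[name]
            if name == "lower_lobe_predominance":
                candidates = [
                    i for i, r in enumerate(records) if not r.upper_lobe_predominance
                ]
            elif name == "upper_lobe_predominance":
                candidates = [
                    i for i, r in enumerate(records) if not r.lower_lobe_predominance
                ]
            else:
                candidates = list(range(n))
            if k > len(candidates):
                raise SpecError(
                    f"{profile.label.value}: cannot place {k} positives of "
                    f"{name!r} among {len(candidates)} eligible patients"
                )
            chosen = rng.permutation(np.asarray(candidates, dtype=int))[:k]
            for i in range(n):
                _set_feature(records[i], name, bool(i in set(chosen.tolist())))
    else:  # bernoulli
        p_upper = profile.feature_counts.get("upper_lobe_predominance")
        p_lower = profile.feature_counts.get("lower_lobe_predominance")
        if p_upper is not None and p_lower is not None:
            pu, pl = p_upper / n, p_lower / n
            draws = rng.choice(3, size=n, p=[pu, pl, max(0.0, 1 - pu - pl)])
            for rec, d in zip(records, draws):
                rec.upper_lobe_predominance = bool(d == 0)
                rec.lower_lobe_predominance = bool(d == 1)
            names = [n_ for n_ in names if not n_.endswith("lobe_predominance")]
        for name in names:
            p = profile.feature_counts[name] / n
            for rec, u in zip(records, rng.random(n)):
                _set_feature(rec, name, bool(u < p))

    # malignancy overlay: leading records, forced MRI/PET triad
    if profile.malignancy_overlay is not None:
        k, flag = profile.malignancy_overlay
        suvs = np.round(rng.uniform(3.5, 12.0, size=k), 1)
        for rec, suv in zip(records[:k], suvs):
            rec.true_malignancy = flag
            rec.t2_hyperintense = TriState.TRUE
            rec.dwi_restriction = TriState.TRUE
            rec.suv_max = float(suv)

    # atypical (confounder) profiles: trailing records, applied verbatim
    tail = n
    for count, overrides in profile.confounder_overrides:
        for rec in records[tail - count : tail]:
            for name, value in overrides.items():
                _set_feature(rec, name, value)
        tail -= count
    return records


def generate(spec: CohortSpec, seed: int | None = None) -> list[PatientRecord]:
    """Generate a cohort from a spec; every emitted record is valid.

    ``seed`` overrides ``spec.seed``.  In ``exact_counts`` mode the
    per-feature marginal counts equal the profile counts exactly for
    any seed; ``bernoulli`` mode draws each feature independently with
    probability count/n.
    """
    problems = spec.validate()
    if problems:
        raise SpecError("; ".join(problems))
    use_seed = spec.seed if seed is None else seed
    records: list[PatientRecord] = []
    for profile in spec.profiles:
        records.extend(_generate_profile(profile, spec.mode, use_seed))
    for rec in records:
        violations = validate_record(rec)
        if violations:  # pragma: no cover - spec.validate guards this
            raise SpecError(f"generated record {rec.patient_id}: " + "; ".join(violations))
    return records


def canonical_record(label: DiseaseLabel) -> PatientRecord:
    """The textbook feature profile of one disease.

    Built from the disease's profile constants (features at 100%
    prevalence true, features at 0% false, everything else at default);
    each canonical record classifies to its own disease.
    """
    profile = next(
        p for p in builtin_step1_spec().profiles if p.label is label
    )
    rec = PatientRecord(
        patient_id=f"canonical_{label.value}",
        true_label=label,
        true_malignancy=MalignancyFlag.NONE,
    )
    for name, value in profile.fixed_fields.items():
        _set_feature(rec, name, value)
    return rec


# --- builtin study cohorts ---------------------------------------------------

_F = TriState.FALSE
_T = TriState.TRUE


def builtin_step1_spec(seed: int = 0, mode: str = "exact_counts") -> CohortSpec:
    """The 150-patient retrospective significance cohort.

    Disease sizes 34/19/16/2 (interstitial: UIP-IPF, fibrosing NSIP,
    chronic HP, PPFE) and 16/11/21/31 (sarcoidosis, PMF, post-TB,
    post-irradiation).  Per-feature positive counts are the published
    integers; features at 100%/0% prevalence are profile constants.
    Malignancy complicates 7/21 post-TB (scar carcinoma) and 8/31
    post-irradiation (metastasis) patients.
    """
    profiles = [
        DiseaseProfile(
            DiseaseLabel.UIP_IPF, 34,
            feature_counts={"air_trapping": 11, "pulmonary_hypertension": 15,
                            "smoking_history": 8},
            fixed_fields={"lower_lobe_predominance": True,
                          "peripheral_subpleural": True, "ground_glass": True,
                          "traction_bronchiectasis": True, "honeycombing": True},
            male_count=26,
        ),
        DiseaseProfile(
            DiseaseLabel.FIBROSING_NSIP, 19,
            feature_counts={"peribronchovascular": 12, "air_trapping": 11,
                            "head_cheese_sign": 3, "pulmonary_hypertension": 7,
                            "rheumatologic_history": 15, "smoking_history": 5},
            fixed_fields={"lower_lobe_predominance": True,
                          "peripheral_subpleural": True, "ground_glass": True,
                          "traction_bronchiectasis": True},
            male_count=9,
        ),
        DiseaseProfile(
            DiseaseLabel.CHRONIC_HP, 16,
            feature_counts={"peripheral_subpleural": 8,
                            "traction_bronchiectasis": 5,
                            "centrilobular_nodules": 6,
                            "pulmonary_hypertension": 4,
                            "allergen_exposure": 13, "blood_eosinophilia": 12,
                            "bal_lymphocytosis": 12, "smoking_history": 4},
            fixed_fields={"lower_lobe_predominance": True,
                          "peribronchovascular": True, "ground_glass": True,
                          "air_trapping": True, "head_cheese_sign": True,
                          "crazy_paving": True},
            male_count=3,
        ),
        DiseaseProfile(
            DiseaseLabel.PPFE, 2,
            fixed_fields={"upper_lobe_predominance": True,
                          "peripheral_subpleural": True,
                          "consolidation_calcification": True,
                          "platy_thorax": True},
            male_count=0, rapid_course_count=2,
        ),
        DiseaseProfile(
            DiseaseLabel.SARCOIDOSIS, 16,
            feature_counts={"peripheral_subpleural": 5, "ground_glass": 3,
                            "air_trapping": 3, "traction_bronchiectasis": 6,
                            "centrilobular_nodules": 5,
                            "consolidation_calcification": 14,
                            "lymphadenopathy_gt_1cm": 15,
                            "pulmonary_hypertension": 4, "skin_erythema": 12,
                            "arthralgia": 12, "smoking_history": 4},
            fixed_fields={"upper_lobe_predominance": True,
                          "peribronchovascular": True,
                          "perilymphatic_nodules": True},
            male_count=4,
        ),
        DiseaseProfile(
            DiseaseLabel.PMF, 11,
            feature_counts={"peripheral_subpleural": 9,
                            "traction_bronchiectasis": 5,
                            "calcific_random_nodules": 5,
                            "lymphadenopathy_gt_1cm": 1, "smoking_history": 3},
            fixed_fields={"upper_lobe_predominance": True,
                          "peribronchovascular": True, "air_trapping": True,
                          "consolidation_calcification": True,
                          "occupational_dust_exposure": True},
            male_count=11,
        ),
        DiseaseProfile(
            DiseaseLabel.POST_TB, 21,
            feature_counts={"peribronchovascular": 12,
                            "traction_bronchiectasis": 18,
                            "consolidation_calcification": 20, "cavitation": 5,
                            "tree_in_bud": 5, "tuberculin_positive": 5,
                            "smoking_history": 16},
            fixed_fields={"upper_lobe_predominance": True,
                          "peripheral_subpleural": True, "air_trapping": True,
                          "calcific_random_nodules": True,
                          "lymphadenopathy_gt_1cm": True,
                          "t2_hyperintense": _F, "dwi_restriction": _F},
            malignancy_overlay=(7, MalignancyFlag.SCAR_CARCINOMA),
            male_count=17,
        ),
        DiseaseProfile(
            DiseaseLabel.POST_IRRADIATION, 31,
            feature_counts={"upper_lobe_predominance": 27,
                            "lower_lobe_predominance": 4, "ground_glass": 27,
                            "air_trapping": 8, "traction_bronchiectasis": 15,
                            "crazy_paving": 16, "calcific_random_nodules": 7,
                            "lymphadenopathy_gt_1cm": 16, "smoking_history": 8},
            fixed_fields={"peripheral_subpleural": True,
                          "malignancy_irradiation_history": True,
                          "fibrosis_confined_to_radiation_field": True,
                          "t2_hyperintense": _F, "dwi_restriction": _F},
            malignancy_overlay=(8, MalignancyFlag.METASTASIS),
            male_count=22, rapid_course_count=3,
        ),
    ]
    return CohortSpec(profiles=profiles, mode=mode, seed=seed, name="step1")


def builtin_step2_spec(seed: int = 0, mode: str = "exact_counts") -> CohortSpec:
    """The 100-patient prospective validation cohort.

    True-label sizes 23/19/18/17/14/6/3; every patient carries the
    canonical profile of their disease except six atypical patients
    (3 NSIP-like chronic HP, 1 HP-like fibrosing NSIP, 2 PPFE-like
    post-TB) and two malignancy-complicated patients (one scar
    carcinoma on post-TB, one metastasis on post-irradiation scarring).
    """
    profiles = [
        DiseaseProfile(
            DiseaseLabel.UIP_IPF, 23,
            fixed_fields={"lower_lobe_predominance": True,
                          "peripheral_subpleural": True, "ground_glass": True,
                          "traction_bronchiectasis": True, "honeycombing": True},
            male_count=20, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.FIBROSING_NSIP, 19,
            fixed_fields={"lower_lobe_predominance": True,
                          "peripheral_subpleural": True, "ground_glass": True,
                          "traction_bronchiectasis": True,
                          "rheumatologic_history": True},
            confounder_overrides=[(1, {"head_cheese_sign": True})],
            male_count=10, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.CHRONIC_HP, 18,
            fixed_fields={"lower_lobe_predominance": True,
                          "peribronchovascular": True, "ground_glass": True,
                          "air_trapping": True, "head_cheese_sign": True,
                          "crazy_paving": True, "allergen_exposure": True,
                          "blood_eosinophilia": _T, "bal_lymphocytosis": _T},
            confounder_overrides=[(3, {
                "head_cheese_sign": False, "crazy_paving": False,
                "traction_bronchiectasis": True, "allergen_exposure": False,
                "blood_eosinophilia": TriState.NOT_DONE,
                "bal_lymphocytosis": TriState.NOT_DONE,
                "serum_ige_elevated": TriState.NOT_DONE,
            })],
            male_count=5, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.POST_TB, 17,
            fixed_fields={"upper_lobe_predominance": True,
                          "peripheral_subpleural": True, "air_trapping": True,
                          "calcific_random_nodules": True,
                          "consolidation_calcification": True,
                          "lymphadenopathy_gt_1cm": True,
                          "tuberculin_positive": _T,
                          "t2_hyperintense": _F, "dwi_restriction": _F},
            confounder_overrides=[(2, {
                "platy_thorax": True, "calcific_random_nodules": False,
                "tree_in_bud": False, "cavitation": False,
                "lymphadenopathy_gt_1cm": False,
                "tuberculin_positive": TriState.NOT_DONE,
            })],
            malignancy_overlay=(1, MalignancyFlag.SCAR_CARCINOMA),
            male_count=15, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.POST_IRRADIATION, 14,
            fixed_fields={"upper_lobe_predominance": True,
                          "peripheral_subpleural": True, "ground_glass": True,
                          "malignancy_irradiation_history": True,
                          "fibrosis_confined_to_radiation_field": True,
                          "t2_hyperintense": _F, "dwi_restriction": _F},
            malignancy_overlay=(1, MalignancyFlag.METASTASIS),
            male_count=11, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.SARCOIDOSIS, 6,
            fixed_fields={"upper_lobe_predominance": True,
                          "peribronchovascular": True,
                          "perilymphatic_nodules": True, "skin_erythema": True,
                          "arthralgia": True, "lymphadenopathy_gt_1cm": True,
                          "consolidation_calcification": True},
            male_count=2, age_range=(41, 73),
        ),
        DiseaseProfile(
            DiseaseLabel.PMF, 3,
            fixed_fields={"upper_lobe_predominance": True,
                          "peribronchovascular": True, "air_trapping": True,
                          "occupational_dust_exposure": True,
                          "consolidation_calcification": True},
            male_count=3, age_range=(41, 73),
        ),
    ]
    return CohortSpec(profiles=profiles, mode=mode, seed=seed, name="step2")
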